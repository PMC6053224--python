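"""Convenience drivers chaining the pipeline stages.

Thin orchestration only: every computation lives in the stage modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .records import SequenceRecord
from . import readprep, slfind


@dataclass
class PrepResult:
    reads: list[SequenceRecord]
    reports: list[readprep.FilterReport] = field(default_factory=list)


def prep_reads(
    reads: list[SequenceRecord],
    contaminant_refs: list[SequenceRecord] | None = None,
    proteins: list[SequenceRecord] | None = None,
    trim_spec: readprep.TrimSpec | None = None,
    min_len: int = 30,
) -> PrepResult:
    """Trim (optional), length-filter, screen contaminants, select
    protein-N-terminus-encoding reads (when a protein set is given)."""
    reports = []
    if trim_spec is not None:
        reads, rep = readprep.trim_adapters(reads, trim_spec)
        reports.append(rep)
    reads, rep = readprep.length_filter(reads, min_len)
    reports.append(rep)
    if contaminant_refs:
        reads, _, rep = readprep.screen_references(reads, refs=contaminant_refs)
        reports.append(rep)
    if proteins:
        reads, rep = readprep.select_protein_proximal(reads, proteins)
        reports.append(rep)
    return PrepResult(reads, reports)


def discover_leader(
    reads: list[SequenceRecord],
    cluster_min_len: int = 60,
    **detect_kwargs,
) -> tuple[list[slfind.ReadCluster], list[slfind.LeaderCandidate]]:
    """Cluster prepped reads by gene and detect shared-leader candidates.

    Reads shorter than ``cluster_min_len`` are set aside: they cannot carry
    enough body k-mers past the skipped 5' window to cluster reliably.
    """
    usable = [r for r in reads if len(r.seq) >= cluster_min_len]
    clusters = slfind.cluster_by_gene(usable)
    candidates = slfind.detect_leader(clusters, **detect_kwargs)
    return clusters, candidates
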