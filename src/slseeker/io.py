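"""Readers, writers, and run configuration shared by all stages.

FASTA/FASTQ parsing goes through Biopython's SeqIO; annotation output is
plain TSV or GFF3 (1-based, inclusive). Every writer's output is re-readable
by the corresponding reader here.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .records import SequenceRecord

log = logging.getLogger("slseeker")

_FORMATS = {"fasta", "fastq"}

GFF3_FEATURE_TYPES = {"SL_RNA_gene", "trans_splice_acceptor", "motif", "TSS"}


def _infer_format(path: str | Path) -> str:
    suffix = Path(path).suffix.lower()
    if suffix in {".fa", ".fasta", ".fna"}:
        return "fasta"
    if suffix in {".fq", ".fastq"}:
        return "fastq"
    raise ValueError(f"cannot infer sequence format from {path}")


def read_sequences(path: str | Path, format: str | None = None) -> list[SequenceRecord]:
    """Read FASTA/FASTQ into SequenceRecords, order preserving.

    Multi-line FASTA and CRLF line endings are tolerated; lowercase is
    upcased. A malformed record raises ValueError naming its index.
    """
    fmt = format or _infer_format(path)
    if fmt not in _FORMATS:
        raise ValueError(f"unsupported format {fmt!r}")
    out: list[SequenceRecord] = []
    try:
        for i, rec in enumerate(SeqIO.parse(str(path), fmt)):
            qual = None
            if fmt == "fastq":
                qual = list(rec.letter_annotations["phred_quality"])
            try:
                out.append(SequenceRecord(rec.id, str(rec.seq), qual))
            except ValueError as exc:
                raise ValueError(f"record {i} in {path}: {exc}") from exc
    except ValueError as exc:
        if "record" in str(exc):
            raise
        raise ValueError(
            f"malformed record near index {len(out)} in {path}: {exc}"
        ) from exc
    log.info("read %d records from %s", len(out), path)
    return out


def write_sequences(
    records: Iterable[SequenceRecord], path: str | Path, format: str | None = None
) -> None:
    fmt = format or _infer_format(path)
    bio = []
    for r in records:
        b = BioSeqRecord(Seq(r.seq), id=r.id, description="")
        if fmt == "fastq":
            b.letter_annotations["phred_quality"] = r.qual or [40] * len(r.seq)
        bio.append(b)
    count = SeqIO.write(bio, str(path), fmt)
    log.info("wrote %d records to %s", count, path)


def write_annotations(
    rows: Sequence[Mapping],
    path: str | Path,
    dialect: str = "tsv",
    columns: Sequence[str] | None = None,
) -> None:
    """Write annotation rows as TSV (with header) or GFF3.

    GFF3 rows need keys: seqid, source, type, start, end, score, strand,
    attributes (a mapping). Coordinates are 1-based inclusive; an interval
    with end < start is rejected.
    """
    path = Path(path)
    if dialect == "tsv":
        cols = list(columns) if columns is not None else (
            list(rows[0].keys()) if rows else []
        )
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(cols)
            for row in rows:
                writer.writerow([row.get(c, "") for c in cols])
    elif dialect == "gff3":
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for row in rows:
                start, end = int(row["start"]), int(row["end"])
                if end < start:
                    raise ValueError(f"interval end {end} < start {start}")
                attrs = row.get("attributes", {})
                attr_str = ";".join(f"{k}={v}" for k, v in attrs.items()) or "."
                fh.write(
                    "\t".join(
                        [
                            str(row["seqid"]),
                            str(row.get("source", "slseeker")),
                            str(row["type"]),
                            str(start),
                            str(end),
                            str(row.get("score", ".")),
                            str(row.get("strand", ".")),
                            str(row.get("phase", ".")),
                            attr_str,
                        ]
                    )
                    + "\n"
                )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    log.info("wrote %d annotation rows to %s", len(rows), path)


def read_annotations(path: str | Path) -> list[dict]:
    """Read back a TSV written by write_annotations."""
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        return [dict(row) for row in reader]


# ---------------------------------------------------------------------------
# Run configuration

_BOUNDS = {
    "min_read_len": (0, 10_000),
    "trim_max_mismatch": (0, 2),
    "screen_k": (5, 32),
    "screen_containment_min": (0.0, 1.0),
    "cluster_k": (5, 32),
    "cluster_share_min": (0.0, 1.0),
    "leader_window": (10, 200),
    "leader_kmer": (8, 32),
    "cluster_fraction_min": (0.0, 1.0),
    "min_clusters": (1, 10_000),
    "scan_max_mismatch": (0, 5),
    "downstream_window": (50, 5_000),
    "intron_prefix": (20, 500),
    "identity_min": (0.0, 1.0),
    "tss_min_identity": (0.0, 1.0),
    "tss_min_coverage": (0.0, 1.0),
    "upstream_window": (100, 100_000),
    "min_intron": (10, 10_000),
    "seed": (0, 2**31 - 1),
}


@dataclass
class RunConfig:
    """Stage parameters with the pipeline's documented defaults."""

    min_read_len: int = 30
    trim_max_mismatch: int = 1
    screen_k: int = 15
    screen_containment_min: float = 0.8
    cluster_k: int = 15
    cluster_share_min: float = 0.5
    leader_window: int = 40
    leader_kmer: int = 12
    cluster_fraction_min: float = 0.5
    min_clusters: int = 5
    scan_max_mismatch: int = 2
    downstream_window: int = 300
    intron_prefix: int = 60
    identity_min: float = 0.8
    tss_min_identity: float = 0.95
    tss_min_coverage: float = 0.9
    upstream_window: int = 5000
    min_intron: int = 40
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for name, (lo, hi) in _BOUNDS.items():
            val = getattr(self, name)
            if not (lo <= val <= hi):
                raise ValueError(f"parameter {name}={val} out of bounds [{lo}, {hi}]")


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load a YAML/JSON config file; keyword overrides beat file values.

    Unknown keys are rejected; every parameter is bounds-checked.
    """
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded:
            data.update(loaded)
    data.update(overrides)
    known = {f.name for f in fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**data)
    log.info("config loaded from %s with %d overrides", path, len(overrides))
    return cfg
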