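"""Read-filtering cascade for 5'-enriched cDNA reads.

Stages mirror a cap-trapper preprocessing workflow: linker/adapter trimming,
a minimum-length filter, contaminant/rRNA screening, and selection of reads
whose translation matches the N-terminus of a known protein. Each stage
returns a FilterReport so the whole cascade can be reconstructed from logs.

Screening is k-mer containment against reference sequences (or an external
hit table of read ids), not E-value-thresholded alignment: the decision it
makes — "this read is essentially a substring of a contaminant reference" —
is the same, and the table mode lets an external aligner's calls be slotted
in unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .records import SequenceRecord, revcomp

BLOSUM62 = substitution_matrices.load("BLOSUM62")


@dataclass
class TrimSpec:
    linker_5p: str
    adapter_3p: str
    max_mismatch: int = 1
    min_overlap: int = 6

    def __post_init__(self) -> None:
        if not self.linker_5p or not self.adapter_3p:
            raise ValueError("linker and adapter must be non-empty")
        if self.max_mismatch > 2:
            raise ValueError("max_mismatch must be <= 2")
        self.linker_5p = self.linker_5p.upper()
        self.adapter_3p = self.adapter_3p.upper()


@dataclass
class FilterReport:
    stage: str
    input_count: int = 0
    kept_count: int = 0
    discarded: dict[str, int] = field(default_factory=dict)

    def check(self) -> None:
        if self.input_count != self.kept_count + sum(self.discarded.values()):
            raise AssertionError(f"{self.stage}: counts do not chain")


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def trim_adapters(
    reads: list[SequenceRecord], spec: TrimSpec
) -> tuple[list[SequenceRecord], FilterReport]:
    """Strip the 5' linker from the read start and the 3' adapter from its
    first suffix occurrence; untouched reads pass through flagged."""
    report = FilterReport("trim_adapters", input_count=len(reads))
    out = []
    for r in reads:
        seq = r.seq
        trimmed_5 = trimmed_3 = False
        lk = spec.linker_5p
        if len(seq) >= len(lk) and _hamming(seq[: len(lk)], lk) <= spec.max_mismatch:
            seq = seq[len(lk) :]
            trimmed_5 = True
        seq, trimmed_3 = _trim_3p(seq, spec)
        meta = dict(r.meta)
        if not (trimmed_5 or trimmed_3):
            meta["untrimmed"] = "1"
        if seq:
            out.append(SequenceRecord(r.id, seq, r.qual[: len(seq)] if r.qual else None, meta))
        else:
            report.discarded["empty_after_trim"] = (
                report.discarded.get("empty_after_trim", 0) + 1
            )
    report.kept_count = len(out)
    report.check()
    return out, report


def _trim_3p(seq: str, spec: TrimSpec) -> tuple[str, bool]:
    ad = spec.adapter_3p
    # first full-adapter occurrence anywhere in the read
    for i in range(len(seq) - len(ad) + 1):
        if _hamming(seq[i : i + len(ad)], ad) <= spec.max_mismatch:
            return seq[:i], True
    # partial adapter hanging off the read's 3' end
    max_ov = min(len(ad) - 1, len(seq))
    for ov in range(max_ov, spec.min_overlap - 1, -1):
        if _hamming(seq[-ov:], ad[:ov]) <= spec.max_mismatch:
            return seq[:-ov], True
    return seq, False


def length_filter(
    reads: list[SequenceRecord], min_len: int = 30
) -> tuple[list[SequenceRecord], FilterReport]:
    """Discard reads shorter than ``min_len`` (default 30 nt)."""
    report = FilterReport("length_filter", input_count=len(reads))
    out = [r for r in reads if len(r.seq) >= min_len]
    report.kept_count = len(out)
    report.discarded["too_short"] = len(reads) - len(out)
    report.check()
    return out, report


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def screen_references(
    reads: list[SequenceRecord],
    refs: list[SequenceRecord] | None = None,
    hit_table: set[str] | None = None,
    k: int = 15,
    containment_min: float = 0.8,
    mode: str = "kmer",
) -> tuple[list[SequenceRecord], list[SequenceRecord], FilterReport]:
    """Remove reads highly similar to reference sequences.

    kmer mode: a read is removed when at least ``containment_min`` of its
    k-mers (on either strand) occur in the reference k-mer set. table mode:
    removed when its id is in ``hit_table``.
    """
    report = FilterReport("screen_references", input_count=len(reads))
    kept: list[SequenceRecord] = []
    removed: list[SequenceRecord] = []
    if mode == "table":
        if hit_table is None:
            raise ValueError("table mode requires hit_table")
        for r in reads:
            (removed if r.id in hit_table else kept).append(r)
    elif mode == "kmer":
        if refs is None:
            raise ValueError("kmer mode requires refs")
        ref_kmers: set[str] = set()
        for ref in refs:
            ref_kmers |= _kmer_set(ref.seq, k)
            ref_kmers |= _kmer_set(revcomp(ref.seq), k)
        for r in reads:
            if len(r.seq) < k:
                r.meta["screen_warning"] = "read shorter than k"
                kept.append(r)
                continue
            # containment = fraction of read bases covered by a k-mer found
            # in the reference set; an isolated sequencing error removes at
            # most one covered base, so the decision is error-tolerant
            covered = [False] * len(r.seq)
            for i in range(len(r.seq) - k + 1):
                if r.seq[i : i + k] in ref_kmers:
                    covered[i : i + k] = [True] * k
            if sum(covered) / len(r.seq) >= containment_min:
                removed.append(r)
            else:
                kept.append(r)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    report.kept_count = len(kept)
    report.discarded["reference_hit"] = len(removed)
    report.check()
    return kept, removed, report


# ---------------------------------------------------------------------------
# translated N-terminal screen


def _frames(seq: str) -> list[str]:
    """Six-frame translations, each split at stop codons."""
    peptides: list[str] = []
    for s in (seq, revcomp(seq)):
        for off in range(3):
            sub = s[off : off + 3 * ((len(s) - off) // 3)]
            if len(sub) < 3:
                continue
            aa = str(Seq(sub).translate())
            peptides.extend(p for p in aa.split("*") if p)
    return peptides


def _extend_score(pep: str, prot: str, pi: int, qi: int, seed_len: int) -> float:
    """Ungapped BLOSUM62 extension around an exact seed."""
    score = sum(BLOSUM62[pep[pi + j]][prot[qi + j]] for j in range(seed_len))
    best = score
    # extend right
    run = score
    i, j = pi + seed_len, qi + seed_len
    while i < len(pep) and j < len(prot):
        run += BLOSUM62[pep[i]][prot[j]]
        best = max(best, run)
        if run < best - 20:  # X-drop
            break
        i += 1
        j += 1
    # extend left from the best-right prefix
    run = best
    i, j = pi - 1, qi - 1
    while i >= 0 and j >= 0:
        run += BLOSUM62[pep[i]][prot[j]]
        best = max(best, run)
        if run < best - 20:
            break
        i -= 1
        j -= 1
    return best


def select_protein_proximal(
    reads: list[SequenceRecord],
    proteins: list[SequenceRecord],
    n_term_len: int = 50,
    seed_len: int = 8,
    min_score: float = 40.0,
) -> tuple[list[SequenceRecord], FilterReport]:
    """Keep reads whose six-frame translation matches a protein N-terminus.

    A read passes when any reading-frame peptide contains an exact
    ``seed_len``-aa word from the first ``n_term_len`` residues of any
    protein and ungapped BLOSUM62 extension reaches ``min_score``.
    """
    report = FilterReport("select_protein_proximal", input_count=len(reads))
    seeds: dict[str, list[tuple[int, int]]] = {}
    windows: list[str] = []
    for idx, p in enumerate(proteins):
        if len(p.seq) < seed_len:
            p.meta["skip_warning"] = "protein shorter than seed"
            windows.append("")
            continue
        win = p.seq[:n_term_len]
        windows.append(win)
        for i in range(len(win) - seed_len + 1):
            seeds.setdefault(win[i : i + seed_len], []).append((idx, i))
    kept: list[SequenceRecord] = []
    for r in reads:
        hit = False
        for pep in _frames(r.seq):
            if hit:
                break
            for i in range(len(pep) - seed_len + 1):
                for idx, qi in seeds.get(pep[i : i + seed_len], ()):
                    if _extend_score(pep, windows[idx], i, qi, seed_len) >= min_score:
                        hit = True
                        break
                if hit:
                    break
        if hit:
            kept.append(r)
        else:
            report.discarded["no_protein_match"] = (
                report.discarded.get("no_protein_match", 0) + 1
            )
    report.kept_count = len(kept)
    report.check()
    return kept, report
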