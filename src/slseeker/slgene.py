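"""Genome-wide SL RNA gene identification and characterization.

The locus scan searches both strands for the conserved leader core
immediately followed by the GT splice donor (the classic "leader + donor"
query); loci are then classified into subtypes by the identity of their
intron sequence just downstream of the donor, aligned to delimit the
conserved block, profiled for transcription start sites with capped reads,
and annotated for 3'-end motifs and polyadenylation cleavage sites.

Motif scanners and the secondary-structure folder live in
:mod:`slseeker.motifs` and :mod:`slseeker.fold`; they are re-exported here
so this module presents the full characterization surface.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import edlib

from .records import SequenceRecord, revcomp
from .fold import SecondaryStructure, StemLoop, find_stem_loops, fold  # noqa: F401
from .motifs import (  # noqa: F401
    MotifHit,
    find_3prime_box,
    find_canonical_sm,
    find_polya_signal,
    find_pyrimidine_terminator,
    find_relaxed_sm,
)


def build_query(core: str, donor: str = "GT") -> str:
    """The genome query: conserved leader core + 5' splice-donor motif."""
    return core.upper() + donor.upper()


@dataclass
class SLGeneLocus:
    locus_id: str
    contig: str
    strand: str
    match_start: int       # contig coords, stranded endpoints (start = 5' on
    match_end: int         # the locus strand; start > end numerically on '-')
    donor_pos: int         # first base of GT, stranded
    exon_seq: str          # matched leader segment, locus strand
    downstream: str        # sequence after the donor GT, locus strand
    upstream: str          # context 5' of the match, locus strand
    mismatches: int
    subtype: str | None = None
    truncated: bool = False

    def intron_prefix(self, n: int) -> str:
        return self.downstream[:n]


@dataclass
class TSSProfile:
    locus_id: str
    counts: dict[int, int] = field(default_factory=dict)  # exon-relative, +1 = exon start

    @property
    def modal_positions(self) -> list[int]:
        if not self.counts:
            return []
        mx = max(self.counts.values())
        return sorted(p for p, c in self.counts.items() if c >= 0.5 * mx)


# ---------------------------------------------------------------------------
# locus scan


def _approx_occurrences(hay: str, needle: str, max_mismatch: int):
    """(pos, mismatches) of approximate occurrences via pigeonhole seeding."""
    m = len(needle)
    nparts = max_mismatch + 1
    bounds = [round(i * m / nparts) for i in range(nparts + 1)]
    starts: set[int] = set()
    for p in range(nparts):
        part = needle[bounds[p] : bounds[p + 1]]
        i = hay.find(part)
        while i != -1:
            s = i - bounds[p]
            if 0 <= s <= len(hay) - m:
                starts.add(s)
            i = hay.find(part, i + 1)
    out = []
    for s in sorted(starts):
        mism = sum(a != b for a, b in zip(hay[s : s + m], needle))
        if mism <= max_mismatch:
            out.append((s, mism))
    return out


def scan_loci(
    contigs: list[SequenceRecord],
    leader_core: str,
    donor: str = "GT",
    max_mismatch: int = 2,
    downstream_window: int = 300,
    upstream_window: int = 60,
) -> list[SLGeneLocus]:
    """Scan both strands for core (+/- mismatches) followed by an exact donor.

    Overlapping placements on one strand are merged keeping the lowest
    mismatch count; ``truncated`` flags loci whose contig ends inside the
    downstream window.
    """
    if len(leader_core) < 12:
        raise ValueError("leader core must be >= 12 nt")
    core = leader_core.upper()
    m = len(core)
    loci: list[SLGeneLocus] = []
    for rec in contigs:
        L = len(rec.seq)
        for strand in "+-":
            seq = rec.seq if strand == "+" else revcomp(rec.seq)
            hits = []
            for s, mism in _approx_occurrences(seq, core, max_mismatch):
                if seq[s + m : s + m + 2] != donor:
                    continue
                hits.append((s, mism))
            # merge overlapping placements, lowest mismatch wins
            hits.sort(key=lambda t: (t[1], t[0]))
            chosen: list[tuple[int, int]] = []
            for s, mism in hits:
                if all(abs(s - s2) >= m for s2, _ in chosen):
                    chosen.append((s, mism))
            for s, mism in sorted(chosen):
                down = seq[s + m + 2 : s + m + 2 + downstream_window]
                up = seq[max(0, s - upstream_window) : s]
                if strand == "+":
                    match_start, match_end = s + 1, s + m
                    donor_pos = s + m + 1
                else:
                    match_start = L - s
                    match_end = L - (s + m) + 1
                    donor_pos = L - (s + m + 1) + 1
                loci.append(
                    SLGeneLocus(
                        locus_id=f"{rec.id}:{strand}:{s + 1}",
                        contig=rec.id,
                        strand=strand,
                        match_start=match_start,
                        match_end=match_end,
                        donor_pos=donor_pos,
                        exon_seq=seq[s : s + m],
                        downstream=down,
                        upstream=up,
                        mismatches=mism,
                        truncated=len(down) < downstream_window,
                    )
                )
    return loci


# ---------------------------------------------------------------------------
# subtype classification


def _identity(a: str, b: str) -> float:
    if not a or not b:
        return 0.0
    d = edlib.align(a, b, task="distance")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


def classify_subtypes(
    loci: list[SLGeneLocus], intron_prefix: int = 60, identity_min: float = 0.8
) -> dict[str, str]:
    """Single-linkage clustering of loci by intron-prefix identity.

    Clusters are named SL-I, SL-II, ... by descending size; singletons and
    loci with < 20 nt of downstream sequence are labelled 'unassigned'.
    """
    if len(loci) < 2:
        for lc in loci:
            lc.subtype = "unassigned"
        return {lc.locus_id: "unassigned" for lc in loci}
    usable = [lc for lc in loci if len(lc.downstream) >= 20]
    for lc in loci:
        if len(lc.downstream) < 20:
            lc.subtype = "unassigned"
    prefixes = [lc.intron_prefix(intron_prefix) for lc in usable]
    parent = list(range(len(usable)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(len(usable)):
        for j in range(i + 1, len(usable)):
            if _identity(prefixes[i], prefixes[j]) >= identity_min:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(len(usable)):
        groups.setdefault(find(i), []).append(i)
    ordered = sorted(groups.values(), key=lambda g: (-len(g), min(g)))
    roman = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X"]
    for rank, members in enumerate(ordered):
        label = (
            "unassigned"
            if len(members) == 1
            else f"SL-{roman[rank] if rank < len(roman) else rank + 1}"
        )
        for i in members:
            usable[i].subtype = label
    return {lc.locus_id: lc.subtype for lc in loci}


# ---------------------------------------------------------------------------
# progressive alignment and conserved block


def _nw_align(a: str, b: str, match: int = 1, mismatch: int = -1,
              gap: int = -2) -> tuple[str, str]:
    """Global alignment with linear gap cost; deterministic tie-breaking
    (diagonal > up > left)."""
    n, m = len(a), len(b)
    score = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        score[i][0] = i * gap
    for j in range(1, m + 1):
        score[0][j] = j * gap
    for i in range(1, n + 1):
        row, prev = score[i], score[i - 1]
        ai = a[i - 1]
        for j in range(1, m + 1):
            row[j] = max(
                prev[j - 1] + (match if ai == b[j - 1] else mismatch),
                prev[j] + gap,
                row[j - 1] + gap,
            )
    out_a, out_b = [], []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and score[i][j] == score[i - 1][j - 1] + (
            match if a[i - 1] == b[j - 1] else mismatch
        ):
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i -= 1
            j -= 1
        elif i > 0 and score[i][j] == score[i - 1][j] + gap:
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b))


def _column_conservation(rows: list[str]) -> list[float]:
    # modal residue fraction with gaps counting against: a column carried by
    # one or two rows must not score as perfectly conserved
    cons = []
    n = len(rows)
    for col in zip(*rows):
        residues = [c for c in col if c != "-"]
        if not residues:
            cons.append(0.0)
            continue
        cons.append(Counter(residues).most_common(1)[0][1] / n)
    return cons


def align_and_conserved_block(
    seqs: list[str], window: int = 10, conservation_min: float = 0.9,
    boundary_min: float = 0.7,
) -> tuple[list[str], tuple[int, int]]:
    """Progressive multiple alignment and the 5'-anchored conserved block.

    Sequences (locus-strand, starting at the exon +1) are added in
    pairwise-identity guide order; per-column conservation is the modal
    residue fraction over all rows; the conserved block is the maximal run
    of sliding windows with mean conservation >= ``conservation_min``,
    anchored at the first column, then trimmed of trailing columns whose
    own conservation is below ``boundary_min`` — a window straddling the
    boundary must not drag unconserved columns in, while a merely mutated
    column (conservation between the two thresholds) stays inside.
    """
    if len(seqs) < 3:
        raise ValueError("insufficient members: progressive alignment needs >= 3")
    # guide order: descending mean identity to the others
    ident = [[_identity(a, b) for b in seqs] for a in seqs]
    order = sorted(
        range(len(seqs)),
        key=lambda i: (-sum(ident[i]) / len(seqs), i),
    )
    rows = [seqs[order[0]]]
    for idx in order[1:]:
        consensus = _alignment_consensus(rows)
        al_cons, al_new = _nw_align(consensus, seqs[idx])
        # propagate gaps opened in the consensus into all existing rows
        new_rows = []
        for row in rows:
            rebuilt, p = [], 0
            for c in al_cons:
                if c == "-":
                    rebuilt.append("-")
                else:
                    rebuilt.append(row[p])
                    p += 1
            new_rows.append("".join(rebuilt))
        new_rows.append(al_new)
        rows = new_rows
    # undo the guide reordering
    unordered = [""] * len(seqs)
    for pos, idx in enumerate(order):
        unordered[idx] = rows[pos]
    # mask mostly-gap columns: an insertion carried by a minority of rows
    # (e.g. a tail base absorbed into a homopolymer run) carries no family
    # signal and must not interrupt the block
    n = len(unordered)
    ncol = len(unordered[0])
    keep = [j for j in range(ncol)
            if sum(r[j] != "-" for r in unordered) >= 0.5 * n]
    masked = ["".join(r[j] for j in keep) for r in unordered]
    cons = _column_conservation(masked)
    end = 0
    j = 0
    while j + window <= len(cons):
        if sum(cons[j : j + window]) / window >= conservation_min:
            end = j + window
            j += 1
        else:
            break
    # trim trailing columns dragged in by a window straddling the boundary
    while end > 0 and cons[end - 1] < boundary_min:
        end -= 1
    if end == 0:
        return unordered, (0, 0)
    # map the block end back to sequence coordinates (modal over rows, so
    # homopolymer boundary ambiguities in single rows cannot shift it)
    orig_col = keep[end - 1]
    positions = Counter(
        len(r[: orig_col + 1].replace("-", "")) for r in unordered
    )
    top = max(positions.values())
    end_seq = min(p for p, c in positions.items() if c == top)
    return unordered, (1, end_seq)


def _alignment_consensus(rows: list[str]) -> str:
    out = []
    for col in zip(*rows):
        residues = [c for c in col if c != "-"]
        out.append(Counter(residues).most_common(1)[0][0] if residues else "-")
    return "".join(out)


# ---------------------------------------------------------------------------
# TSS mapping


def _polyA_stripped(seq: str, min_run: int = 5) -> tuple[str, int]:
    n = len(seq)
    i = n
    while i > 0 and seq[i - 1] == "A":
        i -= 1
    if n - i >= min_run:
        return seq[:i], n - i
    return seq, 0


def map_tss(
    capped_reads: list[SequenceRecord],
    context: str,
    exon_offset: int,
    locus_id: str = "",
    min_identity: float = 0.95,
    min_coverage: float = 0.9,
) -> TSSProfile:
    """Map capped-read 5' ends onto a locus context.

    ``context`` is locus-strand sequence; ``exon_offset`` is the 1-based
    position of the exon +1 within it. A read is accepted when it aligns
    end-to-end (its terminal poly(A) run, a transcript feature absent from
    the genome, may be ignored) with identity >= ``min_identity`` over
    >= ``min_coverage`` of its length. The TSS is the context position of
    read base 1, reported exon-relative (+1 = exon start).
    """
    counts: Counter = Counter()
    for read in capped_reads:
        body, stripped = _polyA_stripped(read.seq)
        if len(body) < 20 or len(body) / len(read.seq) < min_coverage:
            continue
        max_dist = int(len(body) * (1 - min_identity))
        res = edlib.align(body, context, mode="HW", task="locations", k=max_dist)
        if res["editDistance"] == -1:
            continue
        start = res["locations"][0][0]
        counts[start + 1 - exon_offset + 1] += 1
    profile = TSSProfile(locus_id=locus_id, counts=dict(counts))
    return profile


# ---------------------------------------------------------------------------
# cleavage-site inference


def infer_cleavage_sites(
    context: str,
    signal_end: int,
    polyadenylated_cdnas: list[SequenceRecord],
    min_identity: float = 0.9,
    min_tail: int = 8,
) -> list[int]:
    """Cleavage offsets (last templated base − last base of the AATAAA).

    Each cDNA must end in a >= ``min_tail`` poly(A) run. The run is stripped
    — except for 3'-terminal A's that are templated in the locus, which are
    restored — and the remaining body is aligned to the context; the offset
    of its 3' end from ``signal_end`` (1-based context position of the
    hexamer's last base) is reported per cDNA.
    """
    offsets = []
    for cdna in polyadenylated_cdnas:
        body, stripped = _polyA_stripped(cdna.seq, min_run=min_tail)
        if stripped < min_tail:
            continue
        max_dist = int(len(body) * (1 - min_identity))
        res = edlib.align(body, context, mode="HW", task="locations", k=max_dist)
        if res["editDistance"] == -1:
            continue  # skipped with warning: cDNA does not align
        end = res["locations"][0][1]  # 0-based inclusive end in context
        # restore genomic-templated A's consumed by the tail strip
        while stripped > 0 and end + 1 < len(context) and context[end + 1] == "A":
            end += 1
            stripped -= 1
        offsets.append(end + 1 - signal_end)
    return offsets
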