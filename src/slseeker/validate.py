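"""Per-gene genomic validation of trans-splicing.

For a gene with genomic and mature-mRNA evidence, the validator locates the
trans-splice acceptor (the AG preceding the point where the leader-stripped
mRNA rejoins the genome), discriminates trans-splicing from long-range
cis-splicing (the leader must be absent from the genomic neighbourhood
upstream of the acceptor, and capped reads must show no transcription start
upstream of the outron's own starts), counts cis introns by spliced
alignment, and reproduces the diagnostic PCR pattern in silico: a primer in
the leader pairs with a downstream exon primer only on cDNA, while a primer
upstream of the TSS pairs only on genomic DNA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import pandas as pd

from .records import SequenceRecord, revcomp
from .motifs import MotifHit, find_pyrimidine_terminator


@dataclass
class GeneModel:
    """Genomic context of one gene with its ATG anchoring the coordinates.

    Positions are ATG-relative: the A of ATG is +1, upstream positions are
    negative, and there is no position 0.
    """

    genomic: SequenceRecord
    atg_index: int  # 1-based index of the A of ATG in genomic.seq
    mrna: SequenceRecord | None = None
    capped_reads: list[SequenceRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.genomic.seq[self.atg_index - 1 : self.atg_index + 2] != "ATG":
            raise ValueError("no ATG at the declared offset")

    def to_relative(self, index: int) -> int:
        rel = index - self.atg_index + 1
        return rel if rel > 0 else rel - 1

    def to_index(self, rel: int) -> int:
        if rel == 0:
            raise ValueError("position 0 does not exist")
        return self.atg_index + rel - 1 if rel > 0 else self.atg_index + rel


@dataclass
class TransSpliceCall:
    acceptor_index: int | None      # genomic index of the G of AG
    acceptor_rel: int | None        # ATG-relative
    leader_match_len: int
    outron: tuple[int, int] | None  # genomic interval searched as outron
    pyrimidine_tracts: list[MotifHit] = field(default_factory=list)
    verdict: str = "indeterminate"  # trans | cis_possible | indeterminate
    notes: list[str] = field(default_factory=list)


@dataclass
class AmpliconResult:
    pair_name: str
    template_name: str
    products: list[tuple[int, int, int]]  # (start, end, length), 1-based

    @property
    def present(self) -> bool:
        return bool(self.products)


def _suffix_match_len(leader: str, mrna: str, min_len: int = 12,
                      max_mismatch: int = 1) -> int | None:
    """Longest leader suffix matching the mRNA start within max_mismatch."""
    for L in range(min(len(leader), len(mrna)), min_len - 1, -1):
        mism = sum(a != b for a, b in zip(leader[-L:], mrna[:L]))
        if mism <= max_mismatch:
            return L
    return None


def locate_acceptor(
    model: GeneModel,
    leader: str,
    probe_len: int = 60,
    min_identity: float = 0.95,
    upstream_window: int = 5000,
) -> TransSpliceCall:
    """Strip the mRNA's leader, realign its 5' region to the genome, and
    call the acceptor AG immediately upstream of the rejoining point."""
    if model.mrna is None:
        raise ValueError("gene model has no mRNA")
    leader = leader.upper()
    L = _suffix_match_len(leader, model.mrna.seq)
    if L is None:
        raise ValueError("not leader-bearing: mRNA lacks a leader suffix >= 12 nt")
    call = TransSpliceCall(None, None, L, None)
    # a long probe can straddle the first cis intron and fail to align
    # contiguously; fall back to shorter probes before giving up
    res = None
    for plen in (probe_len, 40, 25, 20):
        probe = model.mrna.seq[L : L + plen]
        max_dist = int(len(probe) * (1 - min_identity))
        res = edlib.align(probe, model.genomic.seq, mode="HW",
                          task="locations", k=max_dist)
        if res["editDistance"] != -1:
            break
    if res is None or res["editDistance"] == -1:
        call.notes.append("mRNA 5' region does not align to the genome")
        return call
    locs = {loc[0] for loc in res["locations"]}
    if len(locs) > 1:
        call.verdict = "indeterminate"
        call.notes.append("alignment ambiguous: multiple equal placements")
        return call
    start0 = locs.pop()           # 0-based alignment start
    acceptor = start0             # 1-based index of the preceding base
    if acceptor < 2:
        call.notes.append("no genomic context upstream of the aligned start")
        return call
    call.acceptor_index = acceptor
    call.acceptor_rel = model.to_relative(acceptor)
    dinuc = model.genomic.seq[acceptor - 2 : acceptor]
    if dinuc != "AG":
        call.verdict = "indeterminate"
        call.notes.append(f"acceptor dinucleotide is {dinuc}, not AG")
        return call
    out_lo = max(1, acceptor - 200)
    call.outron = (out_lo, acceptor)
    call.pyrimidine_tracts = find_pyrimidine_terminator(
        model.genomic.seq[out_lo - 1 : acceptor], min_len=6
    )
    call.verdict = decide_cis_trans(
        model, leader, acceptor, upstream_window=upstream_window, notes=call.notes
    )
    return call


def decide_cis_trans(
    model: GeneModel,
    leader: str,
    acceptor: int,
    upstream_window: int = 5000,
    max_mismatch: int = 1,
    notes: list[str] | None = None,
) -> str:
    """trans requires the leader to be absent upstream of the acceptor and,
    when capped reads are given, no transcription start upstream of the
    outron's own start cluster."""
    notes = notes if notes is not None else []
    lo = max(0, acceptor - 1 - upstream_window)
    if lo == 0 and acceptor - 1 < upstream_window:
        notes.append("upstream window truncated at contig start")
    window = model.genomic.seq[lo : acceptor - 1]
    res = edlib.align(leader, window, mode="HW", task="distance", k=max_mismatch)
    if res["editDistance"] != -1:
        notes.append("leader-like sequence present upstream of the acceptor")
        return "cis_possible"
    if not model.capped_reads:
        notes.append("TSS evidence absent")
        return "trans"
    tss = _map_read_starts(model, acceptor)
    if not tss:
        notes.append("no capped read maps near the gene; TSS evidence absent")
        return "trans"
    outron_tss = [t for t in tss if t < acceptor]
    if not outron_tss:
        notes.append("capped reads map only downstream of the acceptor")
        return "indeterminate"
    cluster_min = min(
        t for t in outron_tss if t >= max(outron_tss) - 50
    )  # modal cluster: starts within 50 nt of the 3'-most outron start
    upstream_starts = [t for t in outron_tss if t < cluster_min - 50]
    if upstream_starts:
        notes.append("transcription starts detected upstream of the outron TSS cluster")
        return "indeterminate"
    return "trans"


def _map_read_starts(model: GeneModel, acceptor: int,
                     min_identity: float = 0.95) -> list[int]:
    starts = []
    for read in model.capped_reads:
        k = int(len(read.seq) * (1 - min_identity))
        res = edlib.align(read.seq, model.genomic.seq, mode="HW",
                          task="locations", k=k)
        if res["editDistance"] == -1:
            continue
        starts.append(res["locations"][0][0] + 1)
    return starts


# ---------------------------------------------------------------------------
# spliced alignment / intron counting


def count_introns(
    genomic: SequenceRecord,
    cdna: SequenceRecord,
    min_intron: int = 40,
    anchor_len: int = 20,
) -> list[tuple[int, int]]:
    """Intron intervals (1-based, genomic) from ordered exact-anchor chaining.

    Shared ``anchor_len``-mers unique in both sequences are chained by
    diagonal; genomic gaps >= ``min_intron`` between diagonals are introns,
    with boundaries slid within the ambiguity window to match GT...AG when
    possible (otherwise placed leftmost and the interval still reported).
    """
    g, c = genomic.seq, cdna.seq

    def unique_kmers(s: str) -> dict[str, int]:
        seen: dict[str, int] = {}
        dup: set[str] = set()
        for i in range(len(s) - anchor_len + 1):
            km = s[i : i + anchor_len]
            if km in seen:
                dup.add(km)
            else:
                seen[km] = i
        return {k: v for k, v in seen.items() if k not in dup}

    gk, ck = unique_kmers(g), unique_kmers(c)
    anchors = sorted(
        (ck[km], gk[km]) for km in gk.keys() & ck.keys()
    )
    if not anchors:
        raise ValueError("no alignment: cDNA shares no unique anchors with genomic")
    # collinear chain: keep anchors with nondecreasing genomic position
    chain: list[tuple[int, int]] = []
    for cp, gp in anchors:
        if not chain or gp > chain[-1][1]:
            chain.append((cp, gp))
    # group by diagonal
    diags: list[tuple[int, int, int]] = []  # (diag, c_lo, c_hi) 0-based
    for cp, gp in chain:
        d = gp - cp
        if diags and diags[-1][0] == d:
            diags[-1] = (d, diags[-1][1], cp + anchor_len - 1)
        else:
            diags.append((d, cp, cp + anchor_len - 1))
    introns: list[tuple[int, int]] = []
    for (d1, _, c_hi1), (d2, c_lo2, _) in zip(diags, diags[1:]):
        gap = d2 - d1
        if gap < min_intron:
            continue
        # maximal extension of each flank toward the junction
        hi = c_hi1
        while hi + 1 < len(c) and hi + 1 + d1 < len(g) and c[hi + 1] == g[hi + 1 + d1]:
            hi += 1
        lo = c_lo2
        while lo - 1 >= 0 and lo - 1 + d2 >= 0 and c[lo - 1] == g[lo - 1 + d2]:
            lo -= 1
        # candidate cut points: cDNA splits x in [lo-1, hi] (0-based last
        # exon1 base); intron = genomic (x+d1+1 .. x+d2) 0-based inclusive
        cut = None
        for x in range(lo - 1, hi + 1):
            i0, i1 = x + d1 + 1, x + d2
            if g[i0 : i0 + 2] == "GT" and g[i1 - 1 : i1 + 1] == "AG":
                cut = x
                break
        if cut is None:  # noncanonical: leftmost placement
            cut = lo - 1
        i0, i1 = cut + d1 + 1, cut + d2
        introns.append((i0 + 1, i1 + 1))
    return introns


def excise(genomic_seq: str, introns: list[tuple[int, int]]) -> str:
    """Genomic sequence with the given 1-based inclusive intervals removed."""
    out, cur = [], 1
    for s, e in sorted(introns):
        out.append(genomic_seq[cur - 1 : s - 1])
        cur = e + 1
    out.append(genomic_seq[cur - 1 :])
    return "".join(out)


# ---------------------------------------------------------------------------
# virtual PCR


def virtual_pcr(
    template: SequenceRecord,
    fwd: str,
    rev: str,
    pair_name: str = "pair",
    max_product: int = 5000,
    max_mismatch: int = 0,
) -> AmpliconResult:
    """All products bounded by a forward-strand match of ``fwd`` and a
    reverse-strand match of ``rev`` with the forward 5' end upstream."""
    if len(fwd) < 15 or len(rev) < 15:
        raise ValueError("primers must be >= 15 nt")
    seq = template.seq
    fwd, rev_rc = fwd.upper(), revcomp(rev.upper())

    def matches(pat: str) -> list[int]:
        out = []
        if max_mismatch == 0:
            i = seq.find(pat)
            while i != -1:
                out.append(i)
                i = seq.find(pat, i + 1)
        else:
            for i in range(len(seq) - len(pat) + 1):
                if sum(a != b for a, b in zip(seq[i : i + len(pat)], pat)) <= max_mismatch:
                    out.append(i)
        return out

    products = []
    rev_sites = matches(rev_rc)
    for f in matches(fwd):
        for r in rev_sites:
            start, end = f + 1, r + len(rev_rc)  # 1-based
            if start < end and (end - start + 1) <= max_product and f + len(fwd) <= end:
                products.append((start, end, end - start + 1))
    return AmpliconResult(pair_name, template.id, sorted(products))


# ---------------------------------------------------------------------------
# evidence report


def evidence_report(
    calls: dict[str, TransSpliceCall | None],
    introns: dict[str, list[tuple[int, int]]],
    amplicons: dict[str, list[AmpliconResult]],
) -> pd.DataFrame:
    """One row per gene merging acceptor call, verdict, intron count, and
    the virtual-PCR presence/absence table."""
    rows = []
    for gene in sorted(set(calls) | set(introns) | set(amplicons)):
        call = calls.get(gene)
        row = dict(
            gene=gene,
            verdict=call.verdict if call else "not_trans_spliced",
            acceptor_rel=call.acceptor_rel if call else "",
            leader_match_len=call.leader_match_len if call else 0,
            pyrimidine_tract=bool(call.pyrimidine_tracts) if call else False,
            n_introns=len(introns.get(gene, [])),
            notes="; ".join(call.notes) if call else "no leader-bearing mRNA",
        )
        for amp in amplicons.get(gene, []):
            row[f"pcr_{amp.pair_name}_{amp.template_name}"] = amp.present
        rows.append(row)
    return pd.DataFrame(rows)
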