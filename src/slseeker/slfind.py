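"""De novo detection of a shared 5' leader across genes.

A spliced leader betrays itself as a word shared by the 5' ends of reads
from many *unrelated* genes: per-gene read groups are formed first (greedy
k-mer clustering on read bodies, ignoring the first ``skip_5p`` bases so
the shared leader cannot glue unrelated genes together), then k-mer words
enriched across group representatives' 5' windows are chained into a
consensus. The leader is recovered as a shared word with a common 3' end
and ragged 5' starts — the signature of a trans-spliced leader donated by
an SL RNA with heterogeneous transcription start sites.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .records import SequenceRecord


@dataclass
class ReadCluster:
    cluster_id: str
    members: list[SequenceRecord]
    representative: SequenceRecord

    @property
    def member_ids(self) -> list[str]:
        return [m.id for m in self.members]


@dataclass
class LeaderCandidate:
    consensus: str
    support: int
    junctions: dict[str, int]  # cluster id -> 1-based read position of last leader base
    observed_lengths: Counter = field(default_factory=Counter)

    @property
    def has_uuu(self) -> bool:
        return "TTT" in self.consensus or "UUU" in self.consensus

    @property
    def terminal_g(self) -> bool:
        return self.consensus.endswith("G")

    @property
    def length_ok(self) -> bool:
        return 16 <= len(self.consensus) <= 52


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _greedy_cluster(
    items: list[tuple[SequenceRecord, str]], k: int, share_min: float, prefix: str
) -> list[ReadCluster]:
    """Greedy clustering: an item joins the first cluster whose
    representative shares >= share_min of the item's k-mers. Input is sorted
    by descending body length, then id, for determinism."""
    items = sorted(items, key=lambda t: (-len(t[1]), t[0].id))
    clusters: list[tuple[ReadCluster, set[str]]] = []
    for rec, body in items:
        km = _kmers(body, k)
        placed = False
        if km:
            for cl, rep_km in clusters:
                if len(km & rep_km) / len(km) >= share_min:
                    cl.members.append(rec)
                    placed = True
                    break
        if not placed:
            cl = ReadCluster(f"{prefix}{len(clusters):04d}", [rec], rec)
            clusters.append((cl, km))
    return [cl for cl, _ in clusters]


def cluster_by_gene(
    reads: list[SequenceRecord],
    skip_5p: int = 40,
    k: int = 15,
    share_min: float = 0.5,
) -> list[ReadCluster]:
    """Group reads by gene using k-mers of the read body past ``skip_5p``.

    The skipped 5' window covers any shared leader, so clusters approximate
    genes rather than leader-sharing classes.
    """
    items = [(r, r.seq[skip_5p:]) for r in reads]
    return _greedy_cluster(items, k, share_min, "cl")


def _match_end(read: str, consensus: str, window: int,
               max_mismatch: int = 1, min_len: int = 16) -> int | None:
    """1-based read position where the consensus (or, for reads starting
    mid-leader, a suffix of it) ends, allowing <= max_mismatch mismatches.

    The leader is 5'-anchored: a placement either starts at read base 1
    (with a consensus suffix) or contains the full consensus. Returns the
    placement with fewest mismatches, ties to the largest end position.
    """
    best: tuple[int, int] | None = None  # (mismatches, end)
    hi = min(window + len(consensus), len(read))
    for end in range(min(min_len, len(consensus)), hi + 1):
        m = min(end, len(consensus))
        seg, suf = read[end - m : end], consensus[-m:]
        mism = sum(a != b for a, b in zip(seg, suf))
        if mism <= max_mismatch:
            if best is None or (mism, -end) < (best[0], -best[1]):
                best = (mism, end)
    return None if best is None else best[1]


def detect_leader(
    clusters: list[ReadCluster],
    window: int = 40,
    kmer: int = 12,
    cluster_fraction_min: float = 0.5,
    min_clusters: int = 5,
) -> list[LeaderCandidate]:
    """Chain k-mer words enriched across cluster representatives' 5' windows
    into leader candidates, ranked by cluster support.

    Returns an empty list (not an error) when nothing reaches
    ``min_clusters`` support.
    """
    if len(clusters) < min_clusters:
        return []
    reps = [c.representative.seq[:window] for c in clusters]
    counts: Counter = Counter()
    for rep in reps:
        counts.update(_kmers(rep, kmer))
    need = cluster_fraction_min * len(clusters)
    enriched = {w: c for w, c in counts.items() if c >= need}

    candidates: list[LeaderCandidate] = []
    remaining = dict(enriched)
    while remaining:
        seed = min(remaining, key=lambda w: (-remaining[w], w))
        consensus = _chain(seed, remaining)
        for w in _kmers(consensus, kmer):
            remaining.pop(w, None)
        junctions: dict[str, int] = {}
        for cl, rep in zip(clusters, [c.representative.seq for c in clusters]):
            end = _match_end(rep, consensus, window)
            if end is not None:
                junctions[cl.cluster_id] = end
        if len(junctions) >= min_clusters:
            candidates.append(LeaderCandidate(consensus, len(junctions), junctions))
    candidates.sort(key=lambda c: (-c.support, -len(c.consensus), c.consensus))
    return candidates


def _chain(seed: str, enriched: dict[str, int]) -> str:
    """Extend a seed word left/right through (k-1)-overlapping enriched words."""
    k = len(seed)
    cons = seed
    max_len = 200
    while len(cons) < max_len:
        suffix = cons[-(k - 1) :]
        opts = [w for w in enriched if w[: k - 1] == suffix and w != cons[-k:]]
        if not opts:
            break
        w = min(opts, key=lambda x: (-enriched[x], x))
        cons += w[-1]
    while len(cons) < max_len:
        prefix = cons[: k - 1]
        opts = [w for w in enriched if w[1:] == prefix and w != cons[:k]]
        if not opts:
            break
        w = min(opts, key=lambda x: (-enriched[x], x))
        cons = w[0] + cons
    return cons


def leader_length_spectrum(
    candidate: LeaderCandidate, clusters: list[ReadCluster], window: int = 40
) -> Counter:
    """Observed attached-leader lengths across all supporting reads.

    For each read of a supporting cluster, the length of its 5' segment
    ending where the consensus match ends — i.e. the attached leader length,
    reflecting TSS heterogeneity on the SL donor gene.
    """
    spectrum: Counter = Counter()
    supported = set(candidate.junctions)
    for cl in clusters:
        if cl.cluster_id not in supported:
            continue
        for read in cl.members:
            end = _match_end(read.seq, candidate.consensus, window)
            if end is not None:
                spectrum[end] += 1
    candidate.observed_lengths = spectrum
    return spectrum


def collect_sl_reads(
    reads: list[SequenceRecord], core: str, max_mismatch: int = 0
) -> list[SequenceRecord]:
    """Reads containing the conserved leader core in forward orientation
    (5'-end reads are stranded); the match offset is recorded per read."""
    if len(core) < 12:
        raise ValueError("core must be >= 12 nt")
    core = core.upper()
    out = []
    for r in reads:
        off = _find_approx(r.seq, core, max_mismatch)
        if off is not None:
            r.meta["core_offset"] = str(off + 1)  # 1-based
            out.append(r)
    return out


def _find_approx(seq: str, pat: str, max_mismatch: int) -> int | None:
    if max_mismatch == 0:
        i = seq.find(pat)
        return None if i < 0 else i
    n, m = len(seq), len(pat)
    for i in range(n - m + 1):
        if sum(a != b for a, b in zip(seq[i : i + m], pat)) <= max_mismatch:
            return i
    return None


def group_sl_tails(
    sl_reads: list[SequenceRecord], core: str, k: int = 12, share_min: float = 0.5
) -> list[ReadCluster]:
    """Cluster leader-core-bearing reads by the sequence downstream of the
    core match, approximating per-gene contigs."""
    items = []
    for r in sl_reads:
        off = int(r.meta.get("core_offset", "0"))
        if off == 0:
            found = _find_approx(r.seq, core.upper(), 0)
            off = (found or 0) + 1
        tail = r.seq[off - 1 + len(core) :]
        items.append((r, tail))
    return _greedy_cluster(items, k, share_min, "slg")
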