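"""Motif scanners for SL RNA gene 3'-end and Sm-site characterization.

All scanners work on DNA or RNA (U and T are equivalent) and return
1-based inclusive intervals. N or other ambiguity codes count as
mismatches. Scanned motifs:

* poly(A) signal — exact AATAAA, reported with its offset downstream of a
  reference point (typically the end of the conserved region);
* pyrimidine-tract terminator — a >= 6 nt C/T stretch containing a poly(T)
  run, the SL RNA transcription terminator of several protist lineages;
* 3'-box — GTTTAAAACAAGC (<= 1 mismatch), the nematode SL RNA terminator
  element;
* canonical Sm site — AAU(3-6)GG/U, the trypanosome/nematode consensus;
* relaxed Sm site — a pyrimidine-rich single-stranded window sandwiched
  between A and G, the loosened rule that admits highly diverged Sm sites
  such as the Oikopleura dioica one.
"""

from __future__ import annotations

from dataclasses import dataclass

from .fold import SecondaryStructure

THREE_PRIME_BOX = "GTTTAAAACAAGC"

PYRIMIDINES = set("CTU")


@dataclass
class MotifHit:
    motif: str
    start: int           # 1-based inclusive
    end: int
    matched: str
    offset: int | None = None   # from a motif-specific reference point
    primary: bool = False

    def check_against(self, seq: str) -> None:
        if seq[self.start - 1 : self.end] != self.matched:
            raise AssertionError("matched sequence differs from interval")


def _norm(seq: str) -> str:
    return seq.upper().replace("U", "T")


def find_polya_signal(seq: str, search_start: int = 1) -> list[MotifHit]:
    """Exact AATAAA hexamers at or after ``search_start`` (1-based).

    ``offset`` = (first base of the hexamer) − ``search_start`` reference
    position; the first hit is flagged primary.
    """
    s = _norm(seq)
    hits = []
    i = s.find("AATAAA", max(0, search_start - 1))
    while i != -1:
        hits.append(
            MotifHit("polya_signal", i + 1, i + 6, seq[i : i + 6],
                     offset=i + 1 - search_start, primary=not hits)
        )
        i = s.find("AATAAA", i + 1)
    return hits


def find_pyrimidine_terminator(seq: str, min_len: int = 6,
                               min_polyT: int = 3) -> list[MotifHit]:
    """Maximal C/T runs of >= min_len containing >= min_polyT consecutive T."""
    s = _norm(seq)
    hits = []
    i = 0
    n = len(s)
    while i < n:
        if s[i] in "CT":
            j = i
            while j < n and s[j] in "CT":
                j += 1
            run = s[i:j]
            if len(run) >= min_len and "T" * min_polyT in run:
                hits.append(MotifHit("pyrimidine_terminator", i + 1, j,
                                     seq[i:j]))
            i = j
        else:
            i += 1
    return hits


def find_3prime_box(seq: str, max_mismatch: int = 1) -> list[MotifHit]:
    """The 13-nt 3'-box, exact or within max_mismatch substitutions."""
    s = _norm(seq)
    m = len(THREE_PRIME_BOX)
    hits = []
    for i in range(len(s) - m + 1):
        mism = sum(a != b for a, b in zip(s[i : i + m], THREE_PRIME_BOX))
        if mism <= max_mismatch:
            hits.append(MotifHit("three_prime_box", i + 1, i + m,
                                 seq[i : i + m]))
    return hits


def find_canonical_sm(seq: str) -> list[MotifHit]:
    """Canonical Sm binding sites: A A U{3,6} G (G|U)."""
    s = _norm(seq)
    hits = []
    for i in range(len(s) - 6):
        if s[i] != "A" or s[i + 1] != "A":
            continue
        for t in range(3, 7):
            end = i + 2 + t + 2
            if end > len(s):
                break
            if (
                all(c == "T" for c in s[i + 2 : i + 2 + t])
                and s[i + 2 + t] == "G"
                and s[i + 3 + t] in "GT"
            ):
                hits.append(MotifHit("sm_canonical", i + 1, end, seq[i:end]))
    return hits


def find_relaxed_sm(
    seq: str,
    structure: SecondaryStructure,
    pyrimidine_min_frac: float = 0.8,
    interior_min: int = 8,
    unpaired_min_frac: float = 0.8,
) -> list[MotifHit]:
    """Relaxed Sm sites: an A...G window with a pyrimidine-rich interior,
    mostly unpaired in the secondary structure; maximal windows only."""
    if len(structure.sequence) != len(seq):
        raise ValueError("structure/sequence length mismatch")
    s = _norm(seq)
    n = len(s)
    unpaired = structure.unpaired()
    pyr = [1 if c in "CT" else 0 for c in s]
    up = [1 if (i + 1) in unpaired else 0 for i in range(n)]
    cum_p = [0]
    cum_u = [0]
    for i in range(n):
        cum_p.append(cum_p[-1] + pyr[i])
        cum_u.append(cum_u[-1] + up[i])
    raw: list[tuple[int, int]] = []
    for i in range(n):
        if s[i] != "A":
            continue
        for j in range(i + interior_min + 1, n):
            if s[j] != "G":
                continue
            interior = j - i - 1
            if interior < interior_min:
                continue
            p_frac = (cum_p[j] - cum_p[i + 1]) / interior
            u_frac = (cum_u[j + 1] - cum_u[i]) / (j - i + 1)
            if p_frac >= pyrimidine_min_frac and u_frac >= unpaired_min_frac:
                raw.append((i, j))
    maximal = [
        (i, j)
        for (i, j) in raw
        if not any((a <= i and j <= b and (a, b) != (i, j)) for (a, b) in raw)
    ]
    return [
        MotifHit("sm_relaxed", i + 1, j + 1, seq[i : j + 1])
        for (i, j) in sorted(maximal)
    ]
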