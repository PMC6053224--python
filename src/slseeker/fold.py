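"""RNA secondary structure by base-pair maximization, and stem-loop parsing.

The folder is a Nussinov-style dynamic program over Watson-Crick (+ optional
GU wobble) pairs with a minimum hairpin loop, with a deterministic traceback
(prefer leaving i unpaired; otherwise pair i with the smallest admissible j).
It is a combinatorial approximation, not a thermodynamic fold; an externally
computed dot-bracket (e.g. from an MFE folder) can be supplied instead via
``SecondaryStructure(source="external")``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "U"), ("U", "G")}


@dataclass
class SecondaryStructure:
    sequence: str
    dotbracket: str
    pairs: list[tuple[int, int]]  # 1-based (i, j), i < j
    source: str = "internal_fold"

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.dotbracket):
            raise ValueError("structure/sequence length mismatch")
        depth = 0
        for ch in self.dotbracket:
            depth += {"(": 1, ")": -1}.get(ch, 0)
            if depth < 0:
                raise ValueError("unbalanced brackets")
        if depth != 0:
            raise ValueError("unbalanced brackets")

    def unpaired(self) -> set[int]:
        paired = {i for p in self.pairs for i in p}
        return {i for i in range(1, len(self.sequence) + 1) if i not in paired}

    @classmethod
    def from_dotbracket(cls, sequence: str, dotbracket: str,
                        source: str = "external") -> "SecondaryStructure":
        stack: list[int] = []
        pairs = []
        for i, ch in enumerate(dotbracket, start=1):
            if ch == "(":
                stack.append(i)
            elif ch == ")":
                pairs.append((stack.pop(), i))
        return cls(sequence, dotbracket, sorted(pairs), source)


def _pairable(a: str, b: str, allow_gu: bool) -> bool:
    return (a, b) in _WC or (allow_gu and (a, b) in _GU)


def fold(seq: str, min_loop: int = 3, allow_gu: bool = True) -> SecondaryStructure:
    """Maximize base pairs over seq (RNA or DNA; T is read as U).

    Hairpin loops are at least ``min_loop`` nt. Sequences up to 500 nt.
    """
    s = seq.upper().replace("T", "U")
    if set(s) - set("ACGUN"):
        raise ValueError(f"invalid characters in sequence: {set(s) - set('ACGUN')}")
    n = len(s)
    if n > 500:
        raise ValueError("fold limited to sequences <= 500 nt")
    # P[i, j] = i and j can pair
    P = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + min_loop + 1, n):
            P[i, j] = _pairable(s[i], s[j], allow_gu)
    dp = np.zeros((n + 2, n + 1), dtype=np.int32)  # dp[i, j], seq[i..j], padded
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = dp[i + 1, j]
            ks = np.flatnonzero(P[i, i : j + 1]) + i
            if ks.size:
                vals = dp[i + 1, ks - 1] + dp[ks + 1, j] + 1
                best = max(best, int(vals.max()))
            dp[i, j] = best
    # deterministic traceback: prefer i unpaired, else smallest partner j
    pairs: list[tuple[int, int]] = []
    stack = [(0, n - 1)] if n else []
    while stack:
        i, j = stack.pop()
        if i >= j:
            continue
        if dp[i, j] == dp[i + 1, j]:
            stack.append((i + 1, j))
            continue
        for k in range(i + min_loop + 1, j + 1):
            if P[i, k]:
                inner = dp[i + 1, k - 1] if k - 1 >= i + 1 else 0
                rest = dp[k + 1, j] if k + 1 <= j else 0
                if inner + rest + 1 == dp[i, j]:
                    pairs.append((i + 1, k + 1))
                    stack.append((i + 1, k - 1))
                    stack.append((k + 1, j))
                    break
    pairs.sort()
    db = ["."] * n
    for a, b in pairs:
        db[a - 1], db[b - 1] = "(", ")"
    return SecondaryStructure(seq, "".join(db), pairs)


def rnafold_structure(seq: str) -> SecondaryStructure:
    """MFE structure from the RNAfold command-line tool (external plug-in).

    Thermodynamic folding complements the internal pair-maximization; the
    result is wrapped as an external SecondaryStructure.
    """
    import subprocess

    rna = seq.upper().replace("T", "U")
    try:
        out = subprocess.run(
            ["RNAfold", "--noPS"], input=rna + "\n",
            capture_output=True, text=True, check=True,
        )
    except (FileNotFoundError, subprocess.CalledProcessError) as exc:
        raise RuntimeError("RNAfold is not available") from exc
    db = out.stdout.splitlines()[1].split()[0]
    return SecondaryStructure.from_dotbracket(seq, db, source="external")


@dataclass
class StemLoop:
    stem_outer: tuple[int, int]   # outermost pair, 1-based
    stem_length: int              # number of base pairs
    loop: tuple[int, int]
    bulges: list[tuple[int, int]] = field(default_factory=list)


def find_stem_loops(structure: SecondaryStructure,
                    max_bulge: int = 3) -> list[StemLoop]:
    """Hairpin stem-loops: innermost pairs enclosing a loop, with stems
    extended outward across bulges of <= ``max_bulge`` unpaired nt per side.
    Ordered 5'->3'; only stems of >= 3 bp are reported."""
    pairs = sorted(structure.pairs)
    paired = {i for p in pairs for i in p}
    # innermost pairs: no other pair strictly inside
    hairpins = [
        (i, j)
        for (i, j) in pairs
        if not any(i < a and b < j for (a, b) in pairs)
    ]
    out: list[StemLoop] = []
    # tightest strictly enclosing pair; gap validity is checked during
    # extension (both gap sides must be unpaired and <= max_bulge)
    enclosing: dict[tuple[int, int], tuple[int, int]] = {}
    for (a, b) in pairs:
        cands = [(x, y) for (x, y) in pairs if x < a and b < y]
        if cands:
            enclosing[(a, b)] = max(cands)
    for (i, j) in hairpins:
        loop = (i + 1, j - 1)
        stem_pairs = [(i, j)]
        bulges: list[tuple[int, int]] = []
        cur = (i, j)
        while cur in enclosing:
            (x, y) = enclosing[cur]
            g5 = cur[0] - x - 1
            g3 = y - cur[1] - 1
            if g5 > max_bulge or g3 > max_bulge:
                break
            if any(p in paired for p in range(x + 1, cur[0])) or any(
                p in paired for p in range(cur[1] + 1, y)
            ):
                break
            if g5:
                bulges.append((x + 1, cur[0] - 1))
            if g3:
                bulges.append((cur[1] + 1, y - 1))
            stem_pairs.append((x, y))
            cur = (x, y)
        if len(stem_pairs) >= 3:
            out.append(
                StemLoop(
                    stem_outer=cur,
                    stem_length=len(stem_pairs),
                    loop=loop,
                    bulges=sorted(bulges),
                )
            )
    out.sort(key=lambda sl: sl.stem_outer[0])
    return out
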