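"""Core sequence record type shared by every pipeline stage."""

from __future__ import annotations

from dataclasses import dataclass, field

DNA_CHARS = set("ACGTN")
RNA_CHARS = set("ACGUN")
# IUPAC ambiguity codes tolerated in genome contigs; scanners treat them as mismatches.
IUPAC_EXTRA = set("RYSWKMBDHV")
PROTEIN_CHARS = set("ACDEFGHIKLMNPQRSTVWY*X")

COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class SequenceRecord:
    """An identified sequence with optional per-base Phred qualities.

    ``seq`` is stored uppercase. ``meta`` carries stage-specific annotations
    (e.g. trimming flags, match offsets) as strings.
    """

    id: str
    seq: str
    qual: list[int] | None = None
    meta: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        self.seq = self.seq.upper()
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError(
                f"record {self.id!r}: quality length {len(self.qual)} != "
                f"sequence length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def validate_alphabet(self, kind: str = "dna") -> None:
        allowed = {
            "dna": DNA_CHARS | IUPAC_EXTRA,
            "rna": RNA_CHARS | IUPAC_EXTRA,
            "protein": PROTEIN_CHARS,
        }[kind]
        bad = set(self.seq) - allowed
        if bad:
            raise ValueError(
                f"record {self.id!r}: invalid {kind} characters {sorted(bad)}"
            )

    def reverse_complement(self) -> "SequenceRecord":
        qual = None if self.qual is None else self.qual[::-1]
        return SequenceRecord(self.id, revcomp(self.seq), qual, dict(self.meta))
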