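"""Synthetic genomes, transcripts, and 5'-anchored reads with ground truth.

The generator emulates the genomic architecture of spliced-leader (SL)
trans-splicing in a unicellular eukaryote:

* two SL RNA gene families sharing a leader exon but carrying distinct
  introns (subtypes SL-I and SL-II), planted in multiple mutated copies on
  both strands of short contigs;
* heterogeneous transcription start sites on the SL genes — SL-I starts in
  the exon's 5'-terminal region, SL-II mid-exon — so the leader actually
  attached to mRNAs has a ragged 5' end (28-33 nt for a 33-nt exon with
  starts at +1..+6);
* recipient genes with a pyrimidine-tract-bearing outron ending in the
  trans-splice acceptor AG, a spliced CDS, and AAUAAA-directed
  polyadenylation with cleavage a fixed distance downstream of the signal;
* cap-anchored reads (every read starts at transcript base 1) of ~136 nt
  with substitution errors, plus bacterial contaminant and rRNA reads.

All coordinates in the truth tables are 1-based, inclusive, on the contig's
forward strand; features on the minus strand carry strand '-'.

The default leader exon is synthetic in its 5' 13 bases; its 3'-terminal
20 bases are the published conserved core of the *Paulinella micropora* SL
(TGGATAATCCGGCTTTTCTG) so that core-based collection and the 22-bp genome
query exercise the same sequence the field uses. The full 33-nt default is
NOT the real *P. micropora* leader, whose complete sequence is not public
in plain text.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .records import SequenceRecord, revcomp
from .io import write_sequences

# Published 20-base conserved core of the SL (3' end of the leader exon).
SL_CORE = "TGGATAATCCGGCTTTTCTG"

# Default 33-nt leader exon: 13 synthetic 5' bases + the conserved core.
DEFAULT_SL_EXON = "AACTTGAGTCGAT" + SL_CORE

# SL-I intron template (95 nt): two hairpin-forming blocks, a pyrimidine-rich
# A...G tract (a relaxed Sm-site candidate), and C/A-rich linkers chosen so
# an MFE fold leaves the tract single-stranded. Screened to contain no
# AATAAA, no canonical Sm motif, no poly(T) pyrimidine stretch.
SL1_INTRON_TEMPLATE = (
    "CCAACCAACC"
    + "GCCACGGA" + "TCAA" + "TCCGTGGC"      # stem-loop block
    + "AAACCCACCC"
    + "ACCTCTCCCTTCTCTTCG"                  # relaxed Sm-site tract (DNA form)
    + "CACAAAAAAC"
    + "GGCAGAC" + "CATA" + "GTCTGCC"        # stem-loop block
    + "ACCCACAAA"
)

# SL-II intron template (80 nt), < 50% identical to the SL-I template.
SL2_INTRON_TEMPLATE = (
    "CGAGCATTAACGTTTCCGGGTATTACCACAACGGGGCAAG"
    "CCCAAGGCGTCGTCCTACTGCAACTCCAAGAGTTACATGA"
)

STOP_CODONS = {"TAA", "TAG", "TGA"}

_PYR_RE = re.compile(r"[CT]{6,}")


@dataclass
class SimConfig:
    """Generative parameters; the defaults are the study conditions."""

    seed: int = 0
    sl_exon: str = DEFAULT_SL_EXON
    n_sl1_copies: int = 43
    n_sl2_copies: int = 14
    intron_template_1: str = SL1_INTRON_TEMPLATE
    intron_template_2: str = SL2_INTRON_TEMPLATE
    copy_mutation_rate: float = 0.01
    # SL-I TSS weights over exon positions +1..+6: six start positions give
    # attached leader lengths 28..33 for a 33-nt exon.
    sl1_tss_weights: dict[int, float] = field(
        default_factory=lambda: {k: 1 / 6 for k in range(1, 7)}
    )
    sl2_tss_position: int = 19
    n_recipient_genes: int = 20
    outron_length_range: tuple[int, int] = (80, 200)
    pyrimidine_tract_length: int = 10
    trans_splice_fraction: float = 1.0
    premature_fraction: float = 0.05
    polya_signal_offset: int = 70      # block end -> first base of AATAAA
    cleavage_offset: int = 14          # last base of AATAAA -> last templated base
    polya_signal_fraction: float = 4 / 12  # fraction of SL loci carrying AATAAA
    gene_intron_count: int = 2
    transcripts_per_gene: int = 30
    sl1_rna_copies: int = 100          # SL-I : SL-II transcript abundance ~100:1
    sl2_rna_copies: int = 1
    polya_tail_length: int = 30
    cleavage_jitter: int = 0
    read_length_mean: float = 136.0
    read_length_sd: float = 30.0
    read_error_rate: float = 0.005
    contaminant_fraction: float = 0.10
    rrna_fraction: float = 0.05
    n_reads: int = 2000

    def validate(self) -> None:
        exon = self.sl_exon.upper()
        if not exon.endswith("G"):
            raise ValueError("sl_exon must end in G (base before the GT donor)")
        if "TTT" not in exon and "UUU" not in exon:
            raise ValueError("sl_exon must contain a UUU/TTT triplet")
        if not 16 <= len(exon) <= 52:
            raise ValueError("sl_exon length must be in [16, 52]")
        if self.intron_template_1 == self.intron_template_2:
            raise ValueError("intron templates must differ")
        if _global_identity(self.intron_template_1, self.intron_template_2) >= 0.5:
            raise ValueError("intron templates must be < 50% identical")
        for name in (
            "copy_mutation_rate", "trans_splice_fraction", "premature_fraction",
            "polya_signal_fraction", "read_error_rate", "contaminant_fraction",
            "rrna_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} not in [0, 1]")
        if self.copy_mutation_rate > 0.1:
            raise ValueError("copy_mutation_rate must be <= 0.1")
        w = sum(self.sl1_tss_weights.values())
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"sl1_tss_weights sum {w} != 1")
        if any(k < 1 or k > len(exon) for k in self.sl1_tss_weights):
            raise ValueError("sl1_tss_weights positions outside the exon")

    def config_hash(self) -> str:
        d = asdict(self)
        d.pop("seed")
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _global_identity(a: str, b: str) -> float:
    import edlib

    d = edlib.align(a, b, task="distance")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


@dataclass
class GroundTruth:
    """Machine-readable record of everything the simulator planted."""

    loci: pd.DataFrame
    genes: pd.DataFrame
    transcripts: pd.DataFrame
    reads: pd.DataFrame
    aux_refs: dict[str, str] = field(default_factory=dict)

    def to_dir(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in ("loci", "genes", "transcripts", "reads"):
            df: pd.DataFrame = getattr(self, name)
            df.to_csv(outdir / f"truth_{name}.tsv", sep="\t", index=False)

    @classmethod
    def from_dir(cls, outdir: str | Path) -> "GroundTruth":
        outdir = Path(outdir)
        frames = {
            name: pd.read_csv(outdir / f"truth_{name}.tsv", sep="\t")
            for name in ("loci", "genes", "transcripts", "reads")
        }
        return cls(**frames)


# ---------------------------------------------------------------------------
# helpers

_MAX_RETRIES = 50


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def _clean_segment(rng, n, forbidden, predicate=None) -> str:
    """Random segment free of forbidden exact substrings (and predicate)."""
    for _ in range(_MAX_RETRIES):
        s = _random_seq(rng, n)
        if any(f in s for f in forbidden):
            continue
        if predicate is not None and not predicate(s):
            continue
        return s
    raise RuntimeError("could not generate collision-free spacer within retry bound")


def _no_pyr_terminator(s: str) -> bool:
    return not any("TTT" in m.group(0) for m in _PYR_RE.finditer(s))


def _count_overlapping(s: str, pat: str) -> int:
    n = i = 0
    while True:
        i = s.find(pat, i)
        if i == -1:
            return n
        n += 1
        i += 1


def _mutate(seq: str, rate: float, rng: np.random.Generator,
            protect_core: tuple[int, int] | None = None,
            core_max_mut: int = 2) -> str:
    """Per-site substitution; the conserved core tolerates at most
    ``core_max_mut`` substitutions (purifying selection on the core)."""
    if rate <= 0:
        return seq
    for _ in range(_MAX_RETRIES):
        chars = list(seq)
        hits = np.flatnonzero(rng.random(len(seq)) < rate)
        for i in hits:
            alt = "ACGT".replace(chars[i], "")
            chars[i] = alt[rng.integers(0, 3)]
        if protect_core is not None:
            lo, hi = protect_core
            n_core = sum(1 for i in hits if lo <= i < hi)
            if n_core > core_max_mut:
                continue
        return "".join(chars)
    return seq  # mutation-free fallback after repeated core damage


def _flip_pos(pos: int, contig_len: int) -> int:
    return contig_len - pos + 1


# ---------------------------------------------------------------------------
# operations


def build_genome(cfg: SimConfig) -> tuple[list[SequenceRecord], GroundTruth]:
    """Plant SL RNA loci and recipient genes on short contigs.

    Each locus/gene sits on its own contig (mirroring a fragmented shotgun
    assembly) flanked by i.i.d. uniform ACGT spacers screened by exact match
    against the leader core on either strand. Deterministic given cfg.seed.
    """
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(1)[0])
    exon = cfg.sl_exon.upper()
    core = exon[-20:]
    forbidden = [core, revcomp(core)]

    contigs: list[SequenceRecord] = []
    locus_rows: list[dict] = []
    gene_rows: list[dict] = []

    # --- SL RNA loci -------------------------------------------------------
    subtype_specs = [("SL-I", cfg.intron_template_1)] * cfg.n_sl1_copies + [
        ("SL-II", cfg.intron_template_2)
    ] * cfg.n_sl2_copies
    n_loci = len(subtype_specs)
    # deterministic count of signal-bearing loci per subtype
    n_sig1 = round(cfg.n_sl1_copies * cfg.polya_signal_fraction)
    n_sig2 = round(cfg.n_sl2_copies * cfg.polya_signal_fraction)
    has_signal = [i < n_sig1 for i in range(cfg.n_sl1_copies)] + [
        i < n_sig2 for i in range(cfg.n_sl2_copies)
    ]

    for idx, ((subtype, template), sig) in enumerate(zip(subtype_specs, has_signal)):
        exon_copy = _mutate(
            exon, cfg.copy_mutation_rate, rng,
            protect_core=(len(exon) - 20, len(exon)),
        )
        # keep the exon's terminal base G and the donor intact: the splice
        # donor is under strong constraint in real SL genes
        exon_copy = exon_copy[:-1] + "G"
        intron_copy = _mutate(template, cfg.copy_mutation_rate, rng)
        conserved = exon_copy + "GT" + intron_copy
        # the downstream region must carry AATAAA exactly when planted: a
        # stray hexamer arising across segment joins or from copy mutation
        # would corrupt the poly(A)-signal census, so screen the assembly
        for _ in range(_MAX_RETRIES):
            gap = _clean_segment(
                rng, cfg.polya_signal_offset - 1, forbidden + ["AATAAA"],
                predicate=_no_pyr_terminator,
            )
            if sig:
                # the base after the cleavage position is non-A so the
                # templated-A boundary of the poly(A) junction is unambiguous
                down = (
                    gap + "AATAAA"
                    + _clean_segment(rng, cfg.cleavage_offset,
                                     forbidden + ["AATAAA"],
                                     predicate=_no_pyr_terminator)
                    + _clean_segment(rng, 40, forbidden + ["AATAAA"],
                                     predicate=lambda s: s[0] != "A"
                                     and _no_pyr_terminator(s))
                )
            else:
                down = gap + _clean_segment(
                    rng, 6 + cfg.cleavage_offset + 40, forbidden + ["AATAAA"],
                    predicate=_no_pyr_terminator,
                )
            if _count_overlapping(conserved[-5:] + down, "AATAAA") == (
                1 if sig else 0
            ):
                break
        else:
            raise RuntimeError("could not assemble downstream region")
        left = _clean_segment(rng, int(rng.integers(40, 81)), forbidden)
        right = _clean_segment(rng, int(rng.integers(20, 61)), forbidden)
        body = conserved + down
        contig_seq = left + body + right
        L = len(contig_seq)

        leader_start = len(left) + 1
        leader_end = len(left) + len(exon_copy)
        donor_pos = leader_end + 1                       # first base of GT
        conserved_end = len(left) + len(conserved)
        signal_start = conserved_end + cfg.polya_signal_offset if sig else 0
        cleavage_pos = signal_start + 5 + cfg.cleavage_offset if sig else 0

        # positional truth fields are stranded endpoints: they map back onto
        # the locus strand via _to_local, so on '-' loci leader_start is
        # numerically larger than leader_end
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            contig_seq = revcomp(contig_seq)
            leader_start = _flip_pos(leader_start, L)
            leader_end = _flip_pos(leader_end, L)
            donor_pos = _flip_pos(donor_pos, L)
            conserved_end = _flip_pos(conserved_end, L)
            if sig:
                signal_start = _flip_pos(signal_start, L)
                cleavage_pos = _flip_pos(cleavage_pos, L)

        contig_id = f"ctg_sl_{idx:03d}"
        contigs.append(SequenceRecord(contig_id, contig_seq))
        locus_rows.append(
            dict(
                locus_id=f"sl_{idx:03d}", contig=contig_id, strand=strand,
                leader_start=leader_start, leader_end=leader_end,
                donor_pos=donor_pos, subtype=subtype,
                exon_seq=exon_copy, intron_seq=intron_copy,
                conserved_end=conserved_end,
                has_polya_signal=sig, signal_start=signal_start,
                cleavage_pos=cleavage_pos,
            )
        )

    # --- recipient genes ---------------------------------------------------
    for g in range(cfg.n_recipient_genes):
        rec = _build_gene_contig(cfg, rng, g, forbidden)
        contigs.append(rec["record"])
        gene_rows.append(rec["row"])

    # --- auxiliary references (contaminant + rRNA, synthetic) --------------
    aux = {
        "contaminant": _clean_segment(rng, 5000, forbidden),
        "rrna": _clean_segment(rng, 1800, forbidden),
    }

    truth = GroundTruth(
        loci=pd.DataFrame(locus_rows),
        genes=pd.DataFrame(gene_rows),
        transcripts=pd.DataFrame(),
        reads=pd.DataFrame(),
        aux_refs=aux,
    )
    _check_conservation(contigs, truth)
    return contigs, truth


def _build_gene_contig(cfg, rng, g, forbidden) -> dict:
    m = int(rng.integers(cfg.outron_length_range[0], cfg.outron_length_range[1] + 1))
    tract = "".join(
        "CT"[i] for i in rng.integers(0, 2, size=cfg.pyrimidine_tract_length)
    )
    # guarantee the poly(T) run the scanners look for
    tract = tract[:3] + "TTT" + tract[6:]
    pre_len = m - 2 - cfg.pyrimidine_tract_length - 4
    if pre_len < 0:
        raise ValueError("outron too short for the pyrimidine tract")
    outron = (
        _clean_segment(rng, pre_len, forbidden)
        + tract
        + _clean_segment(rng, 4, forbidden)
        + "AG"
    )
    utr5 = _clean_segment(rng, 20, forbidden + ["ATG"])
    codons = []
    while len(codons) < 100:
        c = _random_seq(rng, 3)
        if c not in STOP_CODONS:
            codons.append(c)
    coding = "ATG" + "".join(codons) + "TAA"
    # cis introns at random interior codon boundaries, >= 30 nt apart so
    # every exon piece can seed alignment anchors
    n_int = cfg.gene_intron_count
    while True:
        cut_points = sorted(
            int(3 * p)
            for p in rng.choice(np.arange(10, 95), size=n_int, replace=False)
        )
        if all(b - a >= 30 for a, b in zip(cut_points, cut_points[1:])):
            break
    pieces, introns_local = [], []
    prev = 0
    offset = 0
    for cp in cut_points:
        pieces.append(coding[prev:cp])
        ilen = int(rng.integers(50, 81))
        intron = "GT" + _clean_segment(rng, ilen - 4, forbidden) + "AG"
        introns_local.append((cp + offset, cp + offset + len(intron) - 1))  # 0-based
        pieces.append(intron)
        offset += len(intron)
        prev = cp
    pieces.append(coding[prev:])
    gene_body = "".join(pieces)
    utr3a = _clean_segment(rng, 30, forbidden + ["AATAAA"])
    utr3b = _clean_segment(rng, cfg.cleavage_offset, forbidden + ["AATAAA"])
    tail = _clean_segment(rng, 50, forbidden)
    left = _clean_segment(rng, int(rng.integers(60, 121)), forbidden)

    local = left + outron + utr5 + gene_body + utr3a + "AATAAA" + utr3b + tail
    L = len(local)
    tss_pos = len(left) + 1
    outron_start = tss_pos
    outron_end = len(left) + m                 # the G of AG
    acceptor_pos = outron_end
    atg_pos = outron_end + len(utr5) + 1
    signal_start = len(left) + m + len(utr5) + len(gene_body) + len(utr3a) + 1
    cleavage_pos = signal_start + 5 + cfg.cleavage_offset
    intr = [
        (atg_pos + s, atg_pos + e) for s, e in introns_local
    ]  # contig coords, 1-based inclusive

    strand = "+" if rng.random() < 0.5 else "-"
    contig_seq = local
    if strand == "-":
        contig_seq = revcomp(local)
        tss_pos = _flip_pos(tss_pos, L)
        outron_start = _flip_pos(outron_start, L)
        outron_end = _flip_pos(outron_end, L)
        acceptor_pos = _flip_pos(acceptor_pos, L)
        atg_pos = _flip_pos(atg_pos, L)
        signal_start = _flip_pos(signal_start, L)
        cleavage_pos = _flip_pos(cleavage_pos, L)
        # intron intervals stay numerically sorted (strand-agnostic)
        intr = [(_flip_pos(e, L), _flip_pos(s, L)) for s, e in intr]

    cds_end = atg_pos + len(gene_body) - 1 if strand == "+" else _flip_pos(
        _flip_pos(atg_pos, L) + len(gene_body) - 1, L
    )
    contig_id = f"ctg_gene_{g:03d}"
    return dict(
        record=SequenceRecord(contig_id, contig_seq),
        row=dict(
            gene_id=f"gene_{g:03d}", contig=contig_id, strand=strand,
            tss_pos=tss_pos, outron_start=outron_start, outron_end=outron_end,
            acceptor_pos=acceptor_pos, atg_pos=atg_pos, cds_end=cds_end,
            introns=";".join(f"{s}-{e}" for s, e in sorted(intr)),
            signal_start=signal_start, cleavage_pos=cleavage_pos,
        ),
    )


def _check_conservation(contigs: list[SequenceRecord], truth: GroundTruth) -> None:
    """Every truth leader interval must reproduce the exon + GT on its strand."""
    by_id = {c.id: c.seq for c in contigs}
    for row in truth.loci.itertuples():
        seq = by_id[row.contig]
        L = len(seq)
        local = _gene_strand_seq(seq, row.strand)
        lls = _to_local(row.leader_start, row.strand, L)
        lle = _to_local(row.leader_end, row.strand, L)
        sub = local[lls - 1 : lle + 2]
        if sub != row.exon_seq + "GT":
            raise AssertionError(f"truth interval mismatch at {row.locus_id}")


def _gene_strand_seq(contig_seq: str, strand: str) -> str:
    return contig_seq if strand == "+" else revcomp(contig_seq)


def _to_local(pos: int, strand: str, L: int) -> int:
    """Contig coordinate -> coordinate on the gene strand."""
    return pos if strand == "+" else L - pos + 1


def transcribe(cfg: SimConfig, truth: GroundTruth,
               contigs: list[SequenceRecord]) -> list[SequenceRecord]:
    """Emit mature/premature mRNAs and SL RNA transcripts with provenance.

    Each gene yields ``transcripts_per_gene`` instances: trans-spliced with
    probability ``trans_splice_fraction`` (outron replaced by a leader whose
    length follows the SL-I TSS distribution), otherwise the outron is
    retained; a ``premature_fraction`` of instances stay unspliced. SL RNA
    transcripts from signal-bearing loci are added at SL-I:SL-II abundance
    ``sl1_rna_copies:sl2_rna_copies`` and are polyadenylated at their
    cleavage site.
    """
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(2)[1])
    by_id = {c.id: c.seq for c in contigs}
    exon = cfg.sl_exon.upper()
    tss_positions = sorted(cfg.sl1_tss_weights)
    tss_probs = np.array([cfg.sl1_tss_weights[k] for k in tss_positions])
    tail = "A" * cfg.polya_tail_length

    out: list[SequenceRecord] = []
    tx_rows: list[dict] = []

    for row in truth.genes.itertuples():
        seq = _gene_strand_seq(by_id[row.contig], row.strand)
        L = len(by_id[row.contig])
        tss = _to_local(row.tss_pos, row.strand, L)
        acceptor = _to_local(row.acceptor_pos, row.strand, L)
        cleavage = _to_local(row.cleavage_pos, row.strand, L)
        if seq[acceptor - 2 : acceptor] != "AG":
            raise ValueError(f"{row.gene_id}: outron does not end in AG")
        introns = []
        if isinstance(row.introns, str) and row.introns:
            for part in row.introns.split(";"):
                s, e = map(int, part.split("-"))
                s, e = sorted((_to_local(s, row.strand, L), _to_local(e, row.strand, L)))
                introns.append((s, e))
        introns.sort()

        def spliced(lo: int, hi: int) -> str:
            """Gene-strand sequence [lo, hi] with cis introns removed."""
            pieces, cur = [], lo
            for s, e in introns:
                if e < lo or s > hi:
                    continue
                pieces.append(seq[cur - 1 : s - 1])
                cur = e + 1
            pieces.append(seq[cur - 1 : hi])
            return "".join(pieces)

        for t in range(cfg.transcripts_per_gene):
            tx_id = f"tx_{row.gene_id}_{t:03d}"
            if rng.random() < cfg.premature_fraction:
                body = seq[tss - 1 : cleavage]          # unspliced, outron retained
                out.append(SequenceRecord(tx_id, body, meta={"kind": "premature"}))
                tx_rows.append(dict(tx_id=tx_id, source_id=row.gene_id,
                                    kind="premature", trans_spliced=False,
                                    leader_len=0, tss_used=tss))
                continue
            if rng.random() < cfg.trans_splice_fraction:
                k = int(rng.choice(tss_positions, p=tss_probs))
                leader = exon[k - 1 :]
                body = leader + spliced(acceptor + 1, cleavage) + tail
                out.append(SequenceRecord(tx_id, body, meta={"kind": "mature_trans"}))
                tx_rows.append(dict(tx_id=tx_id, source_id=row.gene_id,
                                    kind="mature_trans", trans_spliced=True,
                                    leader_len=len(leader), tss_used=k))
            else:
                body = spliced(tss, cleavage) + tail
                out.append(SequenceRecord(tx_id, body, meta={"kind": "mature_cis"}))
                tx_rows.append(dict(tx_id=tx_id, source_id=row.gene_id,
                                    kind="mature_cis", trans_spliced=False,
                                    leader_len=0, tss_used=tss))

    # SL RNA transcripts from signal-bearing loci: total instances per
    # subtype equal sl1_rna_copies / sl2_rna_copies, spread round-robin
    sig_loci = truth.loci[truth.loci.has_polya_signal]
    for subtype, total in (("SL-I", cfg.sl1_rna_copies),
                           ("SL-II", cfg.sl2_rna_copies)):
        members = list(sig_loci[sig_loci.subtype == subtype].itertuples())
        if not members or total <= 0:
            continue
        for t in range(total):
            row = members[t % len(members)]
            seq = _gene_strand_seq(by_id[row.contig], row.strand)
            L = len(by_id[row.contig])
            exon_plus1 = _to_local(row.leader_start, row.strand, L)
            cleav_local = _to_local(row.cleavage_pos, row.strand, L)
            if subtype == "SL-I":
                k = int(rng.choice(tss_positions, p=tss_probs))
            else:
                k = cfg.sl2_tss_position
            start = exon_plus1 + k - 1
            tx_id = f"tx_{row.locus_id}_{t:03d}"
            body = seq[start - 1 : cleav_local] + tail
            out.append(SequenceRecord(tx_id, body, meta={"kind": "sl_rna"}))
            tx_rows.append(dict(tx_id=tx_id, source_id=row.locus_id,
                                kind="sl_rna", trans_spliced=False,
                                leader_len=0, tss_used=k))

    truth.transcripts = pd.DataFrame(tx_rows)
    return out


def sample_reads(transcripts: list[SequenceRecord], cfg: SimConfig,
                 truth: GroundTruth) -> list[SequenceRecord]:
    """Cap-anchored reads: every transcript-derived read starts at base 1.

    Lengths ~ Normal(mean, sd) truncated to [30, transcript length]; per-base
    substitution errors at ``read_error_rate``. Contaminant and rRNA reads are
    drawn from the synthetic references at random offsets. Read ids encode
    nothing about their origin.
    """
    if not transcripts:
        raise ValueError("empty transcript pool")
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(3)[2])
    classes = rng.choice(
        ["transcript", "contaminant", "rrna"],
        size=cfg.n_reads,
        p=[1 - cfg.contaminant_fraction - cfg.rrna_fraction,
           cfg.contaminant_fraction, cfg.rrna_fraction],
    )
    reads: list[SequenceRecord] = []
    read_rows: list[dict] = []
    cont = truth.aux_refs.get("contaminant", "")
    rrna = truth.aux_refs.get("rrna", "")
    for i, cls in enumerate(classes):
        rid = f"r{i:06d}"
        if cls == "transcript":
            tx = transcripts[rng.integers(0, len(transcripts))]
            n = int(np.clip(round(rng.normal(cfg.read_length_mean,
                                             cfg.read_length_sd)),
                            30, len(tx.seq)))
            raw = tx.seq[:n]
            src = tx.id
        else:
            ref = cont if cls == "contaminant" else rrna
            n = int(np.clip(round(rng.normal(cfg.read_length_mean,
                                             cfg.read_length_sd)),
                            30, len(ref)))
            start = int(rng.integers(0, len(ref) - n + 1))
            raw = ref[start : start + n]
            src = cls
        errs = np.flatnonzero(rng.random(len(raw)) < cfg.read_error_rate)
        chars = list(raw)
        for j in errs:
            alt = "ACGT".replace(chars[j], "") if chars[j] in "ACGT" else "ACGT"
            chars[j] = alt[rng.integers(0, len(alt))]
        seq = "".join(chars)
        reads.append(SequenceRecord(rid, seq, qual=[30] * len(seq)))
        read_rows.append(dict(read_id=rid, source=src, read_class=cls,
                              length=len(seq), n_errors=len(errs)))
    truth.reads = pd.DataFrame(read_rows)
    return reads


def gene_proteins(truth: GroundTruth,
                  contigs: list[SequenceRecord]) -> list[SequenceRecord]:
    """Translations of the planted CDSs.

    Stands in for the public protein database used to select reads encoding
    protein N-termini: in a simulation, the 'known proteins' are the planted
    genes' own products.
    """
    from Bio.Seq import Seq

    by_id = {c.id: c.seq for c in contigs}
    out = []
    for row in truth.genes.itertuples():
        seq = _gene_strand_seq(by_id[row.contig], row.strand)
        L = len(by_id[row.contig])
        atg = _to_local(row.atg_pos, row.strand, L)
        end = _to_local(row.cds_end, row.strand, L)
        introns = []
        if isinstance(row.introns, str) and row.introns:
            for part in row.introns.split(";"):
                s, e = map(int, part.split("-"))
                s, e = sorted((_to_local(s, row.strand, L),
                               _to_local(e, row.strand, L)))
                introns.append((s, e))
        introns.sort()
        pieces, cur = [], atg
        for s, e in introns:
            pieces.append(seq[cur - 1 : s - 1])
            cur = e + 1
        pieces.append(seq[cur - 1 : end])
        cds = "".join(pieces)
        aa = str(Seq(cds).translate()).rstrip("*")
        out.append(SequenceRecord(f"prot_{row.gene_id}", aa))
    return out


SCENARIOS: dict[str, dict] = {
    "tiny": dict(n_sl1_copies=3, n_sl2_copies=2, n_recipient_genes=2,
                 n_reads=200, read_error_rate=0.0, copy_mutation_rate=0.0,
                 contaminant_fraction=0.0, rrna_fraction=0.0,
                 premature_fraction=0.0),
    "default": dict(),  # the study conditions are the dataclass defaults
    "stress": dict(n_recipient_genes=50, n_reads=10_000, read_error_rate=0.01,
                   copy_mutation_rate=0.02),
}


def scenario(name: str, seed: int | None = None, **overrides) -> SimConfig:
    params = dict(SCENARIOS[name])
    params.update(overrides)
    if seed is not None:
        params["seed"] = seed
    return SimConfig(**params)


def emit_dataset(cfg: SimConfig, outdir: str | Path) -> dict:
    """Run the full generator and write FASTA/FASTQ/TSV plus a JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    contigs, truth = build_genome(cfg)
    transcripts = transcribe(cfg, truth, contigs)
    reads = sample_reads(transcripts, cfg, truth)

    paths = {
        "contigs": str(outdir / "contigs.fasta"),
        "transcripts": str(outdir / "transcripts.fasta"),
        "reads": str(outdir / "reads.fastq"),
        "contaminants": str(outdir / "contaminants.fasta"),
        "proteins": str(outdir / "proteins.fasta"),
    }
    write_sequences(contigs, paths["contigs"], "fasta")
    write_sequences(transcripts, paths["transcripts"], "fasta")
    write_sequences(reads, paths["reads"], "fastq")
    write_sequences(gene_proteins(truth, contigs), paths["proteins"], "fasta")
    write_sequences(
        [SequenceRecord("contaminant_1", truth.aux_refs["contaminant"]),
         SequenceRecord("rrna_1", truth.aux_refs["rrna"])],
        paths["contaminants"], "fasta",
    )
    truth.to_dir(outdir)
    manifest = {
        "paths": paths,
        "truth_tables": {n: str(outdir / f"truth_{n}.tsv")
                         for n in ("loci", "genes", "transcripts", "reads")},
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "n_contigs": len(contigs),
        "n_transcripts": len(transcripts),
        "n_reads": len(reads),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
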