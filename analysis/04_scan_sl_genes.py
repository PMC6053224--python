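#!/usr/bin/env python
"""SL RNA gene census and characterization: genome scan with the
core+GT query, subtype clustering, conserved-block delimitation, TSS
profiling from capped reads, poly(A)-signal and terminator-motif scans,
cleavage-site inference, and secondary structure of the conserved region."""

import argparse
from pathlib import Path

from slseeker.io import read_sequences, write_annotations
from slseeker.simulate import GroundTruth, SL_CORE
from slseeker.slgene import (
    build_query, scan_loci, classify_subtypes, align_and_conserved_block,
    map_tss, infer_cleavage_sites, find_polya_signal,
    find_pyrimidine_terminator, find_3prime_box, find_canonical_sm,
    find_relaxed_sm, fold, find_stem_loops,
)

POLYA_SEARCH_WINDOW = 110  # nt downstream of the conserved block


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--dataset", type=Path, default=Path("results/dataset"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    contigs = read_sequences(args.dataset / "contigs.fasta")
    reads = read_sequences(args.dataset / "reads.fastq")
    truth = GroundTruth.from_dir(args.dataset)

    print(f"genome query: {build_query(SL_CORE)} ({len(build_query(SL_CORE))} bp)")
    loci = scan_loci(contigs, SL_CORE)
    classify_subtypes(loci)
    counts = {}
    for l in loci:
        counts[l.subtype] = counts.get(l.subtype, 0) + 1
    print(f"{len(loci)} candidate SL RNA loci; subtypes: {counts}")

    gff = [
        dict(seqid=l.contig, type="SL_RNA_gene",
             start=min(l.match_start, l.match_end),
             end=max(l.match_start, l.match_end),
             strand=l.strand,
             attributes=dict(ID=l.locus_id, subtype=str(l.subtype),
                             mismatches=l.mismatches))
        for l in loci
    ]
    write_annotations(gff, args.out / "sl_loci.gff3", "gff3")

    # conserved block from the 12 largest-family members (pmSL1-style panel)
    sl1 = [l for l in loci if l.subtype == "SL-I"]
    seqs = [l.exon_seq + "GT" + l.downstream[:250] for l in sl1[:12]]
    _, block = align_and_conserved_block(seqs)
    print(f"conserved block (core-anchored coordinates): +1..+{block[1]}")

    # TSS profiles per subtype from reads of SL RNA transcripts
    tx_src = dict(zip(truth.transcripts.tx_id, truth.transcripts.source_id))
    read_src = dict(zip(truth.reads.read_id, truth.reads.source))
    tss_rows = []
    for l in loci:
        key = (l.contig, l.strand, l.donor_pos)
        match = truth.loci[
            (truth.loci.contig == l.contig) & (truth.loci.strand == l.strand)
            & (truth.loci.donor_pos == l.donor_pos)
        ]
        if match.empty:
            continue
        locus_id = match.iloc[0].locus_id
        locus_reads = [r for r in reads
                       if tx_src.get(read_src[r.id], "") == locus_id]
        if not locus_reads:
            continue
        ctx = l.upstream + l.exon_seq + "GT" + l.downstream
        prof = map_tss(locus_reads, ctx, exon_offset=1, locus_id=l.locus_id)
        donor_ctx = len(l.upstream) + len(l.exon_seq) + 1
        for pos, n in sorted(prof.counts.items()):
            tss_rows.append(dict(locus=l.locus_id, subtype=l.subtype,
                                 tss_to_donor=donor_ctx - pos, reads=n))
    write_annotations(tss_rows, args.out / "tss_profiles.tsv", "tsv")
    sl1_lengths = [r["tss_to_donor"] for r in tss_rows if r["subtype"] == "SL-I"]
    if sl1_lengths:
        print(f"SL-I leader length (5'-most TSS to donor): {max(sl1_lengths)} nt; "
              f"observed lengths {sorted(set(sl1_lengths))}")

    # 3'-end characterization of SL-I loci
    motif_rows = []
    n_sig = 0
    offsets = []
    for l in sl1:
        ctx = (l.exon_seq + "GT" + l.downstream)[: block[1] + POLYA_SEARCH_WINDOW]
        down = ctx[block[1]:]
        sig = find_polya_signal(ctx, search_start=block[1])
        pyr = find_pyrimidine_terminator(down)
        box = find_3prime_box(down)
        if sig:
            n_sig += 1
            offsets.append(sig[0].offset)
        motif_rows.append(dict(locus=l.locus_id, polya_signal=bool(sig),
                               signal_offset=sig[0].offset if sig else "",
                               pyrimidine_terminator=bool(pyr),
                               three_prime_box=bool(box)))
    write_annotations(motif_rows, args.out / "three_prime_motifs.tsv", "tsv")
    print(f"poly(A) signal in {n_sig}/{len(sl1)} SL-I loci; "
          f"offsets from block end: {sorted(set(offsets))}")
    print(f"pyrimidine terminator found: {any(r['pyrimidine_terminator'] for r in motif_rows)}; "
          f"3'-box found: {any(r['three_prime_box'] for r in motif_rows)}")

    # cleavage sites from polyadenylated SL RNA transcripts
    txs = read_sequences(args.dataset / "transcripts.fasta")
    cl_offsets = []
    for row in truth.loci[truth.loci.has_polya_signal
                          & (truth.loci.subtype == "SL-I")].itertuples():
        lc = next((l for l in loci if (l.contig, l.strand, l.donor_pos)
                   == (row.contig, row.strand, row.donor_pos)), None)
        if lc is None:
            continue
        ctx = lc.exon_seq + "GT" + lc.downstream
        sig = find_polya_signal(ctx, search_start=block[1])
        if not sig:
            continue
        cdnas = [t for t in txs if tx_src.get(t.id) == row.locus_id]
        cl_offsets += infer_cleavage_sites(ctx, sig[0].end, cdnas)
    print(f"cleavage offsets downstream of the signal: {sorted(set(cl_offsets))} "
          f"({len(cl_offsets)} cDNAs)")

    # secondary structure of the conserved region: prefer the thermodynamic
    # (MFE) fold through the external plug-in, fall back to pair
    # maximization (which tends to over-pair single-stranded tracts)
    region = (sl1[0].exon_seq + "GT" + sl1[0].downstream[: block[1] - 22])
    try:
        from slseeker.fold import rnafold_structure

        structure = rnafold_structure(region)
    except RuntimeError:
        structure = fold(region)
    stems = find_stem_loops(structure)
    print(f"conserved region fold ({structure.source}): {len(structure.pairs)} "
          f"pairs, {len(stems)} stem-loops")
    sm = find_canonical_sm(region)
    print(f"canonical Sm site in conserved region: {bool(sm)}")
    relaxed = find_relaxed_sm(region.replace('T', 'U'), structure)
    print(f"relaxed Sm candidates ({structure.source}): "
          + (relaxed[0].matched if relaxed else "none"))
    (args.out / "conserved_region_structure.txt").write_text(
        region + "\n" + structure.dotbracket + "\n"
    )


if __name__ == "__main__":
    main()
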