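#!/usr/bin/env python
"""Read-filtering cascade: length filter, contaminant/rRNA screen, and
selection of reads encoding protein N-termini. Writes the filtered reads
and a per-stage report mirroring a Methods-style cascade."""

import argparse
from pathlib import Path

from slseeker.io import read_sequences, write_sequences, write_annotations
from slseeker.pipeline import prep_reads


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--dataset", type=Path, default=Path("results/dataset"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    reads = read_sequences(args.dataset / "reads.fastq")
    refs = read_sequences(args.dataset / "contaminants.fasta")
    proteins = read_sequences(args.dataset / "proteins.fasta")

    res = prep_reads(reads, contaminant_refs=refs, proteins=proteins)
    args.out.mkdir(parents=True, exist_ok=True)
    write_sequences(res.reads, args.out / "prepped_reads.fastq")
    rows = [
        dict(stage=r.stage, input=r.input_count, kept=r.kept_count,
             **{f"discarded_{k}": v for k, v in r.discarded.items()})
        for r in res.reports
    ]
    cols = sorted({k for row in rows for k in row}, key=lambda c: c != "stage")
    write_annotations(rows, args.out / "filter_report.tsv", "tsv", columns=cols)
    for r in res.reports:
        print(f"{r.stage}: {r.input_count} -> {r.kept_count} "
              f"(discarded {dict(r.discarded)})")
    print(f"{len(res.reads)} reads enter leader discovery")


if __name__ == "__main__":
    main()
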