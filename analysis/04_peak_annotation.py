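"""Peak arm: consensus/merge behaviour, TSS partition, nearest-gene
annotation and promoter/enhancer classification of the simulated layout."""

import argparse
from pathlib import Path

import pandas as pd

from xcikit.intervals import annotate_peaks, classify_yy1_peaks, merge_peaks, partition_tss
from xcikit.io import read_bed, read_gene_models

ap = argparse.ArgumentParser()
ap.add_argument("--fixtures", type=Path, default=Path("results/fixtures"))
ap.add_argument("--outdir", type=Path, default=Path("results/peaks"))
args = ap.parse_args()
args.outdir.mkdir(parents=True, exist_ok=True)

genes = read_gene_models(args.fixtures / "genes.tsv")
atac = read_bed(args.fixtures / "peaks_atac.bed")
yy1 = pd.concat(
    [
        read_bed(args.fixtures / "peaks_yy1_promoter.bed"),
        read_bed(args.fixtures / "peaks_yy1_enhancer.bed"),
    ],
    ignore_index=True,
)
ac = read_bed(args.fixtures / "peaks_h3k27ac.bed")

part = partition_tss(atac, genes)
print(f"ATAC peaks: {(part == 'proximal').sum()} TSS-proximal, {(part == 'distal').sum()} distal")
ann = annotate_peaks(atac, genes)
ann.to_csv(args.outdir / "atac_annotation.tsv", sep="\t", index=False)

merged = merge_peaks(atac, max_gap=1000)
print(f"merging at gap <= 1 kb: {len(atac)} peaks -> {len(merged)} regions")

labels, gene_ann = classify_yy1_peaks(yy1, ac, genes)
counts = labels["role"].value_counts().to_dict()
print(f"YY1 peaks: {counts} (placement policies: 40 promoter, 40 enhancer-band)")
pd.concat([yy1[["chrom", "start", "end"]], labels], axis=1).to_csv(
    args.outdir / "yy1_classification.tsv", sep="\t", index=False
)
gene_ann.to_csv(args.outdir / "yy1_gene_assignments.tsv", sep="\t", index=False)
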