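"""Generate the synthetic study inputs for all downstream analyses.

Writes allelic WT/mutant count tables with ground-truth labels, the
three-population two-replicate expression matrix with planted DEGs, and a
gene/peak interval layout, under results/fixtures/.
"""

import argparse
from pathlib import Path

from xcikit.io import write_allelic_counts, write_bed, write_expression_tsv, write_gene_models
from xcikit.sim import (
    AllelicSimConfig,
    ExpressionSimConfig,
    IntervalSimConfig,
    PeakSetSpec,
    simulate_allelic_counts,
    simulate_expression_matrix,
    simulate_intervals,
)

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=1)
ap.add_argument("--outdir", type=Path, default=Path("results/fixtures"))
args = ap.parse_args()
out = args.outdir
out.mkdir(parents=True, exist_ok=True)

tables, truth = simulate_allelic_counts(AllelicSimConfig(seed=args.seed))
for cond, df in tables.items():
    write_allelic_counts(df, out / f"allelic_{cond}.tsv")
truth.to_csv(out / "allelic_truth.tsv", sep="\t", index=False)
print(
    f"allelic: {len(truth)} genes, {int(truth['true_escape'].sum())} escape, "
    f"{int(truth['true_dependent'].sum())} Xist-dependent (planted)"
)

matrix, etruth = simulate_expression_matrix(ExpressionSimConfig(seed=args.seed))
write_expression_tsv(matrix.counts, matrix.lengths, out / "expression_counts.tsv")
matrix.samples.to_csv(out / "expression_samples.tsv", sep="\t")
etruth.to_csv(out / "expression_truth.tsv", sep="\t", index=False)
print(
    f"expression: {matrix.counts.shape[0]} genes x {matrix.counts.shape[1]} samples; "
    f"planted {int((etruth['planted'] == 'cDEG').sum())} cDEGs, "
    f"{int((etruth['planted'] == 'lsDEG').sum())} lsDEGs"
)

icfg = IntervalSimConfig(
    n_genes=30,
    chrom_length=40_000_000,
    peak_sets={
        "yy1_promoter": PeakSetSpec(40, placement="promoter"),
        "yy1_enhancer": PeakSetSpec(40, placement="enhancer_band"),
        "atac": PeakSetSpec(120, placement="random"),
    },
    seed=args.seed,
)
genes, peaks = simulate_intervals(icfg)
write_gene_models(genes, out / "genes.tsv")
for name, df in peaks.items():
    write_bed(df, out / f"peaks_{name}.bed")
print(f"intervals: {len(genes)} genes, peak tracks: {sorted(peaks)}")
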