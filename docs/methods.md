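# Methods

## Model and procedure

The analysis treats each X-linked feature (gene or peak) as a binomial
draw over its allelically assignable reads: of n = Reads_Xi + Reads_Xa
reads, the Xi fraction π determines the d-score d = π̂ − 0.5. Silenced
genes sit near d = −0.5; biallelic escape genes sit higher. All decisions
are threshold rules on the counts:

| parameter | default | meaning |
|---|---|---|
| `min_allelic_reads` | 10 reads | analyzability floor; below it d is undefined |
| `escape_ratio` | 0.05 | Reads_Xi/Reads_Xa cutoff for XCI escape (WT only) |
| `delta_d` | 0.03 | d-score shift declaring Xist dependence / peak change |
| TSS window | 3 000 bp | promoter / TSS-proximal region, ±window around the TSS |
| enhancer band | 3–125 kb | distance range for enhancer TF peaks (with H3K27ac overlap) |
| merge gap | 1 000 bp | transitive gap-union of peak intervals |
| consensus fraction | 0.5 | minimum fraction of samples supporting a real peak |
| FPKM activity | 1 | actively-transcribed cutoff (inclusive) |

All threshold comparisons are inclusive, exactly as printed. They are
evaluated in exact integer/rational arithmetic on raw counts
(cross-multiplication), never by comparing floats: a gene with
Reads_Xi/Reads_Xa exactly 0.05, or a d-score shift of exactly 3/100,
classifies identically to an exact-rational oracle. The float `d_score`
is reporting only. The case Reads_Xa = 0 with Reads_Xi > 0 (unbounded
ratio) is classified escape and flagged `xa_zero_escape` in the output.

Classification requires analyzability in *both* compared conditions;
escape status is determined from wild-type counts alone. *Xist* is not
special-cased in the classifier: callers exclude it by id where
appropriate. In particular, the escape × dependence association is
reported with *Xist* excluded from the escape row — *Xist* is an escape
gene by the ratio rule, but its d-score necessarily falls when the gene
itself is deleted, so it carries no information about dependence of
silencing. On the observed counts this gives the table [[14, 3], [21, 313]]
and p = 3.47e−13; keeping *Xist* gives [[14, 4], [21, 313]] and 1.41e−12.
Both modes are supported (`exclude=` / `--exclude-gene`).

## Differential expression

Counts are normalized by median-of-ratios size factors (per-gene geometric
mean reference over genes positive in every sample), implemented in-repo.
A DEG is an active gene moving strictly in the same direction in both
replicate comparisons; ties count as no change ("increase or decrease"
excludes equality). Replicates are paired by index (WT rep i vs KO rep i)
— the weakest assumption for an n = 2 design — with an all-pairs mode
available. "Active" is mean FPKM ≥ 1 in at least one genotype
(configurable to `both`/`wt`): the source rule does not say in which
genotype the cutoff must hold, and the `any` scope keeps both induced and
silenced genes assessable. Signature genes of the three myeloid
progenitors additionally need p < 0.05 for upregulation in the focal
population; no test is named for that p-value, so the default is a Welch
t-test on log2(FPKM+1) of the focal samples against the pooled others,
one-sided, with a hook for externally supplied p-values — an approximation,
flagged as such.

## Interval conventions

Coordinates are 0-based half-open everywhere; overlap means ≥ 1 bp shared.
"Within ±3 kb from the TSS" for a peak means the peak interval overlaps
the [TSS−3000, TSS+3000) window, consistent with the ≥ 1 bp convention;
the nearest-TSS distance used for annotation is measured from the peak
midpoint (edge vs midpoint vs summit is not specified by the source
convention; midpoint is deterministic and summit-free). Nearest-gene ties
break toward the lexicographically smaller gene id and are flagged
`ambiguous`. Consensus peaks keep every pooled interval supported by
≥ 50% of sample sets (inclusive, exact rational comparison) and return
the union of the kept intervals; gap-merging follows the transitive
gap ≤ d rule. These operations are direct sorted-sweep implementations —
their inclusive-boundary semantics are the analysis contract — and every
one is tested against a naive quadratic oracle.

## Statistics

Fisher's exact test is two-sided by the probability-mass definition (sum
of hypergeometric probabilities of margin-preserving tables no more
probable than observed, with a small relative tolerance for float ties),
delegated to scipy; the test suite checks it exhaustively against an
exact-rational enumeration over all 2×2 tables with total ≤ 40 (worst
relative deviation ~6e−16). Chi-squared (no Yates correction by default;
flag available) replaces Fisher when the number of units exceeds 300,
strict. The two-sample KS test uses exact enumeration when min(n, m) ≤ 10
and the asymptotic formula otherwise, checked against a full permutation
enumeration at n = m = 5.

## Synthetic data

One integer seed drives three independent substreams
(`SeedSequence.spawn`), one per generator, so outputs are byte-identical
across runs and adding a generator perturbs nothing.

**Allelic counts.** Per-gene total depth is negative-binomial with mean
`depth_mean` (default 10 000) and dispersion 0.1 (Poisson at 0) — a
heterogeneous-depth choice, not fitted to any observed depth distribution;
Xi reads are binomial with the gene's true Xi fraction. Subjective genes
have wild-type Xi fraction 0.005 (faint misassignment-level signal);
escape genes draw uniformly from [0.05/1.05, 0.35], whose lower bound is
exactly the ratio-rule boundary. Dependence adds `dependent_shift`
(default 0.1) to the mutant Xi fraction — an additive d-score shift.
Default mixing reproduces the observed regime (escape fraction 18/352,
P(dependent | escape) = 14/17, P(dependent | subjective) = 21/334), so the
default simulation yields a strongly significant association. Genes at the
escape boundary are intrinsically coin-flips at finite depth; with the
default depth they are ~1% of escape genes, which is why ≥ 95% recovery is
attainable and attained.

**Expression.** Gene abundances are heavy-tailed (gamma weights,
library-normalized), counts negative-binomial around genotype-specific
means, 3 populations × 2 genotypes × 2 replicates, library size 2e6.
Planted cDEGs (30 up, 10 down — the scale of the observed shared-DEG sets)
shift by `effect_log2fc` in all populations, lsDEGs (40 per population,
half up) in exactly one. Planted genes' baseline weights are floored so a
"true DEG" is an active gene; a planted effect below the activity filter
would be undefined under the DEG rule. Note the replicate-consistency rule
has a ~50% per-population false-call rate on null genes by construction
(two replicates agreeing by chance) — matching the source rule, which
relies on cross-population intersection, not per-population specificity.

**Intervals.** Genes are packed without overlap on one synthetic
chromosome (multinomial gaps); promoter-policy peaks centre within ±3 kb
of a TSS, enhancer-band peaks are placed 3–125 kb from a TSS, rejected if
they touch any promoter window, and co-generated with an overlapping
H3K27ac peak, so the placement policies guarantee their own labels.
Infeasible packings raise a generation error rather than silently
overlapping.

## What the simulations do and do not show

The generators validate the *rules*: threshold logic, boundary
inclusivity, replicate consistency, interval conventions, and end-to-end
label recovery when the planted effects are well separated from the
thresholds. They do not emulate mappability or SNP-density variation in
allelic assignment, reference bias, correlated replicates, isoform
structure, or peak-calling noise — so passing tests certify the analysis
logic, not robustness to those real-data artifacts.

## Problem sizes

Default problem sizes (352–2 000 genes, depth 1e4, ≤ 500-interval
fixtures, exhaustive Fisher grid to total 40) were chosen so the full
suite and the acceptance script each complete in about a minute while
keeping every boundary and oracle comparison exhaustive where
enumerability allows.

## Known limitations

* The signature-gene p-value test is a stand-in for an unspecified test.
* DEG comparison assumes normalized counts; the alternative (raw counts)
  is a one-line change but is not the default.
* `annotate_peaks` is quadratic per chromosome in the worst case; fine at
  the scale of this analysis, not tuned for genome-wide peak atlases.
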