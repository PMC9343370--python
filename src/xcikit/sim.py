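"""Synthetic data with known ground truth for every pipeline stage.

Three generators, each seeded through an independent substream of a single
integer seed (``numpy.random.SeedSequence(seed).spawn``), so adding one
generator never perturbs another and identical configs reproduce identical
outputs byte for byte.

``simulate_allelic_counts`` emulates the allele-split read counts of a
clonal female fibroblast line: per gene, a total allelic depth is drawn
from a negative-binomial law (Poisson when dispersion is 0) and Xi reads
are binomial with the gene's true Xi fraction.  Wild-type Xi fractions are
near zero for silenced (XCI-subjective) genes and at least 0.05/1.05 for
escape genes, so planted escape genes satisfy the Reads_Xi/Reads_Xa >= 0.05
rule in expectation.  Xist-dependent genes get their mutant Xi fraction
raised by ``dependent_shift`` (a pure additive d-score shift).  The default
mixing proportions reproduce the observed regime: roughly 5% of genes
escape, ~14/17 of escape genes and ~21/334 of subjective genes are
Xist-dependent, so the default simulation yields a strongly significant
escape x dependence association.

``simulate_expression_matrix`` emulates the two-replicate, three-population
HSPC count design with planted shared (cDEG) and lineage-specific (lsDEG)
differentially expressed genes.

``simulate_intervals`` lays out non-overlapping genes and peak sets on one
synthetic chromosome with placement policies (promoter / enhancer_band /
random) that exercise every annotation rule by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AllelicSimConfig",
    "ExpressionSimConfig",
    "IntervalSimConfig",
    "PeakSetSpec",
    "simulate_allelic_counts",
    "simulate_expression_matrix",
    "simulate_intervals",
]

# substream indices of the master seed, one per generator
_STREAM_ALLELIC, _STREAM_EXPRESSION, _STREAM_INTERVALS = 0, 1, 2

_ESCAPE_MIN_FRACTION = 0.05 / 1.05  # Xi/(Xi+Xa) when Xi/Xa is exactly 0.05


def _rng(seed: int, stream: int) -> np.random.Generator:
    children = np.random.SeedSequence(int(seed)).spawn(3)
    return np.random.Generator(np.random.PCG64(children[stream]))


def _nb_counts(rng: np.random.Generator, mean: float, dispersion: float, size: int) -> np.ndarray:
    """Negative-binomial totals with var = mu + dispersion * mu^2;
    dispersion 0 degenerates to Poisson."""
    if dispersion == 0:
        return rng.poisson(mean, size=size)
    r = 1.0 / dispersion
    lam = rng.gamma(shape=r, scale=mean / r, size=size)
    return rng.poisson(lam)


# ---------------------------------------------------------------------------
# allelic counts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AllelicSimConfig:
    """Generative regime of the allele-specific experiment.

    Defaults mirror the observed study regime: ~18/352 of X-linked genes
    escape XCI; most escape genes (14/17) but few subjective genes (21/334)
    depend on Xist; silenced genes show ~0.5% residual Xi reads; the
    dependence shift (0.1) is comfortably above the 0.03 call threshold.
    """

    n_genes: int = 352
    escape_fraction: float = 18 / 352
    p_dependent_given_escape: float = 14 / 17
    p_dependent_given_subjective: float = 21 / 334
    depth_mean: float = 10_000.0
    depth_dispersion: float = 0.1
    silenced_xi_fraction: float = 0.005
    escape_xi_fraction_range: tuple[float, float] = (_ESCAPE_MIN_FRACTION, 0.35)
    dependent_shift: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        for name in (
            "escape_fraction",
            "p_dependent_given_escape",
            "p_dependent_given_subjective",
            "silenced_xi_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        lo, hi = self.escape_xi_fraction_range
        if not (_ESCAPE_MIN_FRACTION - 1e-12 <= lo <= hi <= 0.5):
            raise ValueError(
                "escape_xi_fraction_range must lie within [0.05/1.05, 0.5] "
                "so planted escape genes satisfy the ratio rule in expectation"
            )
        if self.depth_mean <= 0 or self.depth_dispersion < 0:
            raise ValueError("depth_mean must be > 0 and depth_dispersion >= 0")
        if self.dependent_shift < 0:
            raise ValueError("dependent_shift must be >= 0")
        if hi + self.dependent_shift > 1.0:  # mutant xi fraction must stay <= 1
            raise ValueError("dependent_shift drives the mutant Xi fraction above 1")


def simulate_allelic_counts(
    cfg: AllelicSimConfig,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Returns ({'WT': table, 'MUT': table}, truth).

    Each table has columns feature_id, reads_xi, reads_xa; truth has
    gene_id, true_escape, true_dependent, true_xi_fraction_wt,
    true_xi_fraction_mut.
    """
    rng = _rng(cfg.seed, _STREAM_ALLELIC)
    n = cfg.n_genes
    gene_ids = np.array([f"gene_{i:05d}" for i in range(n)], dtype=object)

    escape = rng.random(n) < cfg.escape_fraction
    p_dep = np.where(
        escape, cfg.p_dependent_given_escape, cfg.p_dependent_given_subjective
    )
    dependent = rng.random(n) < p_dep

    lo, hi = cfg.escape_xi_fraction_range
    frac_wt = np.where(
        escape, rng.uniform(lo, hi, size=n), cfg.silenced_xi_fraction
    )
    frac_mut = np.minimum(frac_wt + np.where(dependent, cfg.dependent_shift, 0.0), 1.0)

    tables = {}
    for cond, frac in (("WT", frac_wt), ("MUT", frac_mut)):
        depth = _nb_counts(rng, cfg.depth_mean, cfg.depth_dispersion, n)
        xi = rng.binomial(depth, frac)
        tables[cond] = pd.DataFrame(
            {"feature_id": gene_ids, "reads_xi": xi, "reads_xa": depth - xi}
        )

    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "true_escape": escape,
            "true_dependent": dependent,
            "true_xi_fraction_wt": frac_wt,
            "true_xi_fraction_mut": frac_mut,
        }
    )
    return tables, truth


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExpressionSimConfig:
    """Two-replicate multi-population count design with planted DEGs.

    Planted common DEGs shift in every population with one direction;
    lineage-specific DEGs shift in exactly one population.  Planted genes
    are guaranteed a baseline abundance that clears the FPKM >= 1 activity
    filter: a planted 'true DEG' below the activity filter would be
    undefined under the replicate-consistency rule.
    """

    n_genes: int = 2000
    n_populations: int = 3
    n_replicates: int = 2
    n_cdeg_up: int = 30
    n_cdeg_down: int = 10
    n_lsdeg_per_population: int = 40
    effect_log2fc: float = 1.0
    dispersion: float = 0.05
    library_size: int = 2_000_000
    seed: int = 0

    def __post_init__(self):
        if min(self.n_genes, self.n_populations, self.n_replicates) <= 0:
            raise ValueError("n_genes, n_populations, n_replicates must be positive")
        planted = (
            self.n_cdeg_up
            + self.n_cdeg_down
            + self.n_lsdeg_per_population * self.n_populations
        )
        if planted > self.n_genes:
            raise ValueError("planted DEG counts exceed n_genes")
        if self.effect_log2fc < 0 or self.dispersion < 0 or self.library_size <= 0:
            raise ValueError("invalid effect size, dispersion or library size")


def simulate_expression_matrix(
    cfg: ExpressionSimConfig,
) -> tuple["object", pd.DataFrame]:
    """Returns (ExpressionMatrix, truth).

    The matrix holds all populations and genotypes; its ``samples`` metadata
    carries population, genotype ('WT'/'KO') and replicate.  truth has
    gene_id, planted ('cDEG'/'lsDEG'/'non'), direction, population (the
    single population of an lsDEG, '' otherwise).
    """
    from .expression import ExpressionMatrix

    rng = _rng(cfg.seed, _STREAM_EXPRESSION)
    n = cfg.n_genes
    gene_ids = [f"gene_{i:05d}" for i in range(n)]
    pops = [f"pop{i+1}" for i in range(cfg.n_populations)]

    lengths = rng.integers(500, 5001, size=n)
    # relative abundances: heavy-tailed, library-normalised
    weight = rng.gamma(shape=0.6, scale=1.0, size=n) + 1e-6

    # choose planted genes and lift their baseline above the activity filter
    planted_total = cfg.n_cdeg_up + cfg.n_cdeg_down + cfg.n_lsdeg_per_population * cfg.n_populations
    planted_idx = rng.choice(n, size=planted_total, replace=False)
    floor = 5.0 * np.median(weight)  # comfortably active at default depth
    weight[planted_idx] = np.maximum(weight[planted_idx], floor)

    cursor = 0
    cdeg_up = planted_idx[cursor : cursor + cfg.n_cdeg_up]; cursor += cfg.n_cdeg_up
    cdeg_down = planted_idx[cursor : cursor + cfg.n_cdeg_down]; cursor += cfg.n_cdeg_down
    lsdeg = {
        p: planted_idx[cursor + i * cfg.n_lsdeg_per_population : cursor + (i + 1) * cfg.n_lsdeg_per_population]
        for i, p in enumerate(pops)
    }

    fold = 2.0 ** cfg.effect_log2fc
    counts = {}
    meta_rows = []
    for p in pops:
        ko_mult = np.ones(n)
        ko_mult[cdeg_up] = fold
        ko_mult[cdeg_down] = 1.0 / fold
        half = len(lsdeg[p]) // 2
        ko_mult[lsdeg[p][:half]] = fold
        ko_mult[lsdeg[p][half:]] = 1.0 / fold
        for geno, mult in (("WT", np.ones(n)), ("KO", ko_mult)):
            base = weight * mult
            mean = cfg.library_size * base / base.sum()
            for rep in range(1, cfg.n_replicates + 1):
                name = f"{p}_{geno}_rep{rep}"
                # NB around the per-gene mean (vectorised)
                if cfg.dispersion == 0:
                    counts[name] = rng.poisson(mean)
                else:
                    r = 1.0 / cfg.dispersion
                    lam = rng.gamma(shape=r, scale=mean / r)
                    counts[name] = rng.poisson(lam)
                meta_rows.append((name, p, geno, rep))

    counts_df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"))
    samples = pd.DataFrame(
        meta_rows, columns=["sample", "population", "genotype", "replicate"]
    ).set_index("sample")
    matrix = ExpressionMatrix(
        counts=counts_df,
        lengths=pd.Series(lengths, index=counts_df.index, name="length_bp"),
        samples=samples,
    )

    planted = np.full(n, "non", dtype=object)
    direction = np.full(n, "non", dtype=object)
    population = np.full(n, "", dtype=object)
    planted[cdeg_up] = "cDEG"; direction[cdeg_up] = "up"
    planted[cdeg_down] = "cDEG"; direction[cdeg_down] = "down"
    for p in pops:
        half = len(lsdeg[p]) // 2
        planted[lsdeg[p]] = "lsDEG"
        direction[lsdeg[p][:half]] = "up"
        direction[lsdeg[p][half:]] = "down"
        population[lsdeg[p]] = p
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "planted": planted,
            "direction": direction,
            "population": population,
        }
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# interval layouts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PeakSetSpec:
    """One named peak track: how many peaks, their widths, and where.

    placement 'promoter' centres peaks within +/-3 kb of a TSS;
    'enhancer_band' places peaks entirely 3-125 kb from a TSS, clear of all
    promoter windows, with an overlapping H3K27ac peak co-generated;
    'random' places peaks uniformly.
    """

    n_peaks: int
    width_range: tuple[int, int] = (200, 800)
    placement: str = "random"

    def __post_init__(self):
        if self.n_peaks < 0:
            raise ValueError("n_peaks must be >= 0")
        if not (0 < self.width_range[0] <= self.width_range[1]):
            raise ValueError("widths must be positive and ordered")
        if self.placement not in ("promoter", "enhancer_band", "random"):
            raise ValueError(f"unknown placement {self.placement!r}")


@dataclass(frozen=True)
class IntervalSimConfig:
    n_genes: int = 40
    chrom: str = "chrX"
    chrom_length: int = 20_000_000
    gene_length_range: tuple[int, int] = (2_000, 20_000)
    peak_sets: Mapping[str, PeakSetSpec] = field(default_factory=dict)
    tss_window: int = 3000
    enhancer_min: int = 3000
    enhancer_max: int = 125_000
    seed: int = 0

    def __post_init__(self):
        if self.n_genes <= 0 or self.chrom_length <= 0:
            raise ValueError("n_genes and chrom_length must be positive")
        if not (0 < self.gene_length_range[0] <= self.gene_length_range[1]):
            raise ValueError("gene lengths must be positive and ordered")
        if self.gene_length_range[1] * self.n_genes > self.chrom_length:
            raise ValueError(
                "requested genes cannot fit on the chromosome "
                f"({self.n_genes} x up to {self.gene_length_range[1]} bp "
                f"> {self.chrom_length} bp)"
            )


class GenerationError(RuntimeError):
    """Raised when a requested interval layout cannot be packed."""


def _place_genes(rng: np.random.Generator, cfg: IntervalSimConfig) -> pd.DataFrame:
    lo, hi = cfg.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=cfg.n_genes)
    slack = cfg.chrom_length - int(lengths.sum())
    if slack < 0:
        raise GenerationError("genes exceed chromosome capacity")
    # non-overlapping placement: distribute the slack as random gaps
    gaps = rng.multinomial(slack, np.ones(cfg.n_genes + 1) / (cfg.n_genes + 1))
    starts = np.cumsum(gaps[:-1]) + np.concatenate([[0], np.cumsum(lengths[:-1])])
    strands = rng.choice(["+", "-"], size=cfg.n_genes)
    return pd.DataFrame(
        {
            "gene_id": [f"gene_{i:04d}" for i in range(cfg.n_genes)],
            "chrom": cfg.chrom,
            "start": starts.astype(np.int64),
            "end": (starts + lengths).astype(np.int64),
            "strand": strands,
        }
    )


def simulate_intervals(
    cfg: IntervalSimConfig,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Returns (genes, peak tables).  When any set uses 'enhancer_band', an
    'h3k27ac' track with one overlapping peak per enhancer is added."""
    from .intervals import gene_tss

    rng = _rng(cfg.seed, _STREAM_INTERVALS)
    genes = _place_genes(rng, cfg)
    tss = gene_tss(genes).to_numpy(np.int64)

    prom_lo = np.maximum(tss - cfg.tss_window, 0)
    prom_hi = tss + cfg.tss_window

    def in_promoter_window(s: int, e: int) -> bool:
        return bool(np.any((np.minimum(e, prom_hi) - np.maximum(s, prom_lo)) >= 1))

    peak_tables: dict[str, pd.DataFrame] = {}
    h3k27ac_rows: list[tuple] = []

    for name, spec in cfg.peak_sets.items():
        rows = []
        for j in range(spec.n_peaks):
            width = int(rng.integers(spec.width_range[0], spec.width_range[1] + 1))
            placed = False
            for _ in range(200):
                if spec.placement == "promoter":
                    g = int(rng.integers(cfg.n_genes))
                    mid = int(tss[g] + rng.integers(-cfg.tss_window + 1, cfg.tss_window))
                    s = max(mid - width // 2, 0)
                elif spec.placement == "enhancer_band":
                    g = int(rng.integers(cfg.n_genes))
                    side = 1 if rng.random() < 0.5 else -1
                    off_max = cfg.enhancer_max - width
                    if off_max <= cfg.enhancer_min:
                        raise GenerationError("enhancer band narrower than peak width")
                    off = int(rng.integers(cfg.enhancer_min, off_max))
                    s = tss[g] + off if side > 0 else tss[g] - off - width
                    if s < 0:
                        continue
                else:
                    s = int(rng.integers(0, cfg.chrom_length - width))
                e = s + width
                if e > cfg.chrom_length or s < 0:
                    continue
                if spec.placement == "enhancer_band" and in_promoter_window(s, e):
                    continue  # must stay classifiable as enhancer, not promoter
                rows.append((cfg.chrom, int(s), int(e), f"{name}_{j:04d}"))
                if spec.placement == "enhancer_band":
                    # co-placed H3K27ac peak overlapping the enhancer
                    ac_w = int(rng.integers(spec.width_range[0], spec.width_range[1] + 1))
                    ac_s = max(int(s + rng.integers(0, max(width // 2, 1)) - ac_w // 2), 0)
                    h3k27ac_rows.append(
                        (cfg.chrom, ac_s, ac_s + ac_w, f"h3k27ac_{name}_{j:04d}")
                    )
                placed = True
                break
            if not placed:
                raise GenerationError(
                    f"could not place peak {j} of set {name!r} "
                    f"({spec.placement}); layout infeasible"
                )
        peak_tables[name] = pd.DataFrame(
            rows, columns=["chrom", "start", "end", "id"]
        )

    if h3k27ac_rows:
        peak_tables.setdefault(
            "h3k27ac",
            pd.DataFrame(h3k27ac_rows, columns=["chrom", "start", "end", "id"]),
        )
    return genes, peak_tables
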