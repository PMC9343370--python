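"""Non-allelic expression arm: FPKM, activity filter, replicate-consistent
differential expression, common vs lineage-specific DEG scoping, myeloid
signature genes, keyword grouping, and fold-change CDF preparation.

The differential-expression rule is deliberately simple and matches a
two-replicate design: an *active* gene (mean FPKM >= 1 in at least one
genotype by default) is called a DEG when its size-factor-normalized counts
move in the same direction in both biological replicates — strictly up in
both (up), strictly down in both (down), anything else non.  Normalization
uses the median-of-ratios size factors (geometric-mean reference over genes
positive in every sample).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

__all__ = [
    "ExpressionMatrix",
    "compute_fpkm",
    "size_factors_median_of_ratios",
    "call_active",
    "call_deg",
    "scope_degs",
    "signature_genes",
    "keyword_group",
    "foldchange_cdf",
]


@dataclass
class ExpressionMatrix:
    """Raw gene x sample counts with gene lengths and sample metadata.

    counts  : DataFrame, genes (index) x samples (columns), integers >= 0.
    lengths : Series of gene lengths in bp, same index as counts, > 0.
    samples : DataFrame indexed by sample name with columns
              population, genotype, replicate.
    """

    counts: pd.DataFrame
    lengths: pd.Series
    samples: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if not self.counts.index.equals(self.lengths.index):
            self.lengths = self.lengths.reindex(self.counts.index)
        if self.lengths.isna().any() or (self.lengths <= 0).any():
            raise ValueError("every gene needs a positive length_bp")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        if (self.counts.sum(axis=0) <= 0).any():
            raise ValueError("every sample must have total count > 0")
        if self.samples is None:
            self.samples = pd.DataFrame(index=self.counts.columns)
        elif not self.samples.index.equals(self.counts.columns):
            self.samples = self.samples.reindex(self.counts.columns)


def compute_fpkm(m: ExpressionMatrix) -> pd.DataFrame:
    """FPKM = 1e9 * count / (sample total * gene length in bp)."""
    totals = m.counts.sum(axis=0).to_numpy(dtype=float)
    lengths = m.lengths.to_numpy(dtype=float)
    return 1e9 * m.counts / (totals[np.newaxis, :] * lengths[:, np.newaxis])


def size_factors_median_of_ratios(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    Reference = per-gene geometric mean over samples; a sample's factor is
    the median, over genes positive in every sample, of count/reference.
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    arr = counts.to_numpy(dtype=float)
    positive = (arr > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene has nonzero counts in every sample")
    log_ref = np.log(arr[positive]).mean(axis=1)
    factors = np.exp(np.median(np.log(arr[positive]) - log_ref[:, None], axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts divided by their median-of-ratios size factors."""
    return counts / size_factors_median_of_ratios(counts)


def call_active(
    fpkm: pd.DataFrame,
    genotypes: pd.Series,
    threshold: float = 1.0,
    scope: str = "any",
) -> pd.Series:
    """Actively transcribed flag: mean FPKM >= threshold (inclusive).

    ``genotypes`` maps sample -> genotype label.  scope 'any' requires the
    cutoff in at least one genotype, 'both' in all, 'wt' in the genotype
    named WT only.
    """
    if scope not in ("any", "both", "wt"):
        raise ValueError(f"unknown active scope {scope!r}")
    genotypes = genotypes.reindex(fpkm.columns)
    means = fpkm.T.groupby(genotypes).mean().T  # genes x genotypes
    if scope == "any":
        return (means >= threshold).any(axis=1)
    if scope == "both":
        return (means >= threshold).all(axis=1)
    if "WT" not in means.columns:
        raise ValueError("scope 'wt' requires a genotype labelled 'WT'")
    return means["WT"] >= threshold


def call_deg(
    norm_counts: pd.DataFrame,
    wt_samples: Sequence[str],
    ko_samples: Sequence[str],
    active: Optional[pd.Series] = None,
    pairing: str = "index",
) -> pd.DataFrame:
    """Replicate-consistent DEG call for one cell population.

    up   : KO > WT in every replicate comparison (strict),
    down : KO < WT in every replicate comparison (strict),
    non  : anything else, including ties and inactive genes.

    pairing 'index' compares WT rep i with KO rep i (requires equal replicate
    numbers); 'all-pairs' compares every WT replicate with every KO replicate.
    """
    if pairing not in ("index", "all-pairs"):
        raise ValueError(f"unknown pairing {pairing!r}")
    wt = norm_counts[list(wt_samples)].to_numpy(dtype=float)
    ko = norm_counts[list(ko_samples)].to_numpy(dtype=float)
    if pairing == "index":
        if wt.shape[1] != ko.shape[1]:
            raise ValueError(
                "index pairing requires equal WT and KO replicate counts "
                f"({wt.shape[1]} vs {ko.shape[1]})"
            )
        up = (ko > wt).all(axis=1)
        down = (ko < wt).all(axis=1)
    else:
        diff = ko[:, None, :] - wt[:, :, None]  # genes x wt x ko
        up = (diff > 0).all(axis=(1, 2))
        down = (diff < 0).all(axis=(1, 2))
    direction = np.where(up, "up", np.where(down, "down", "non"))
    active_arr = (
        np.ones(len(norm_counts), dtype=bool)
        if active is None
        else active.reindex(norm_counts.index).fillna(False).to_numpy()
    )
    direction = np.where(active_arr, direction, "non")
    return pd.DataFrame(
        {"direction": direction, "active": active_arr}, index=norm_counts.index
    )


def scope_degs(calls: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Partition DEGs into common (cDEG) and lineage-specific (lsDEG).

    ``calls`` maps population -> output of :func:`call_deg` on a shared gene
    universe.  A gene is a cDEG when it is a DEG with the same direction in
    every population; any other gene that is a DEG somewhere is an lsDEG.
    Venn-style counts are attached as ``result.attrs['venn']``.
    """
    pops = list(calls)
    if not pops:
        raise ValueError("no populations supplied")
    universe = calls[pops[0]].index
    dirs = pd.DataFrame(
        {p: calls[p]["direction"].reindex(universe) for p in pops}, index=universe
    )
    is_deg = dirs != "non"
    any_deg = is_deg.any(axis=1)
    all_up = (dirs == "up").all(axis=1)
    all_down = (dirs == "down").all(axis=1)
    cdeg = all_up | all_down

    scope = np.where(cdeg, "cDEG", np.where(any_deg, "lsDEG", "non"))
    direction = np.where(
        all_up, "up", np.where(all_down, "down", "mixed")
    )
    direction = np.where(any_deg, direction, "non")
    populations = is_deg.apply(lambda r: ",".join(sorted(r.index[r])), axis=1)

    out = pd.DataFrame(
        {"scope": scope, "direction": direction, "populations": populations},
        index=universe,
    )
    venn = {
        "per_population_deg": {p: int(is_deg[p].sum()) for p in pops},
        "per_population_up": {p: int((dirs[p] == "up").sum()) for p in pops},
        "per_population_down": {p: int((dirs[p] == "down").sum()) for p in pops},
        "n_cdeg": int(cdeg.sum()),
        "n_cdeg_up": int(all_up.sum()),
        "n_cdeg_down": int(all_down.sum()),
        "n_lsdeg": int((any_deg & ~cdeg).sum()),
        "n_deg_union": int(any_deg.sum()),
    }
    out.attrs["venn"] = venn
    return out


def signature_genes(
    fpkm_by_population: pd.DataFrame,
    p_values: Optional[pd.DataFrame] = None,
    log_fpkm_by_sample: Optional[pd.DataFrame] = None,
    sample_population: Optional[pd.Series] = None,
    p_threshold: float = 0.05,
    fpkm_threshold: float = 1.0,
) -> dict[str, list[str]]:
    """Population signature genes among exactly three populations.

    A gene belongs to population P's signature when it is significantly
    upregulated there (p < p_threshold and mean FPKM >= fpkm_threshold) and
    not actively transcribed (FPKM < fpkm_threshold) in the two others.
    When ``p_values`` is not supplied, a Welch two-sample t-test on
    log2(FPKM+1) of the focal population's samples against the pooled other
    samples is used (requires per-sample log FPKM and a sample->population
    map).  The three signature sets are pairwise disjoint by construction.
    """
    pops = list(fpkm_by_population.columns)
    if len(pops) != 3:
        raise ValueError(f"signature analysis requires exactly 3 populations, got {len(pops)}")
    if p_values is None:
        if log_fpkm_by_sample is None or sample_population is None:
            raise ValueError(
                "supply p_values, or per-sample log FPKM with a population map"
            )
        cols = {}
        for p in pops:
            focal = log_fpkm_by_sample.loc[
                :, sample_population.reindex(log_fpkm_by_sample.columns) == p
            ]
            other = log_fpkm_by_sample.loc[
                :, sample_population.reindex(log_fpkm_by_sample.columns) != p
            ]
            t = _sps.ttest_ind(
                focal, other, axis=1, equal_var=False, alternative="greater"
            )
            cols[p] = t.pvalue
        p_values = pd.DataFrame(cols, index=log_fpkm_by_sample.index)
    p_values = p_values.reindex(index=fpkm_by_population.index, columns=pops)

    out: dict[str, list[str]] = {}
    for p in pops:
        others = [q for q in pops if q != p]
        mask = (
            (p_values[p] < p_threshold)
            & (fpkm_by_population[p] >= fpkm_threshold)
            & (fpkm_by_population[others] < fpkm_threshold).all(axis=1)
        )
        out[p] = sorted(fpkm_by_population.index[mask.fillna(False)])
    return out


def keyword_group(
    annotations: pd.DataFrame,
    keyword_sets: Mapping[str, Sequence[str]],
    gene_col: str = "gene_id",
    term_col: str = "term",
) -> pd.DataFrame:
    """Flag genes whose annotation term names contain any listed keyword.

    Matching is case-insensitive substring search, e.g. the cell-cycle list
    ("cell cycle", "nuclear division", "DNA replication", ...) flags a gene
    annotated with "mitotic cell cycle".  Returns one boolean column per
    keyword set, indexed by gene.
    """
    for name, kws in keyword_sets.items():
        if len(kws) == 0:
            raise ValueError(f"keyword set {name!r} is empty")
    genes = pd.Index(sorted(annotations[gene_col].unique()), name=gene_col)
    terms = annotations[term_col].astype(str).str.lower()
    out = pd.DataFrame(False, index=genes, columns=list(keyword_sets))
    for name, kws in keyword_sets.items():
        hit = pd.Series(False, index=annotations.index)
        for kw in kws:
            hit |= terms.str.contains(str(kw).lower(), regex=False)
        flagged = annotations.loc[hit, gene_col].unique()
        out.loc[out.index.intersection(flagged), name] = True
    return out


def foldchange_cdf(
    fpkm: pd.DataFrame,
    genotypes: pd.Series,
    chrom_map: pd.Series,
    x_chrom: str = "chrX",
    wt_label: str = "WT",
    ko_label: str = "KO",
    fpkm_threshold: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Expression fold-change vectors for the X-linked vs autosomal CDF plot.

    FC = mean KO FPKM / mean WT FPKM over genes passing the activity filter
    (mean FPKM >= threshold in at least one genotype).  Genes whose WT mean
    is zero after filtering are excluded with a warning.  Returns the
    (X-linked, autosomal) fold-change vectors, ready for ks_two_sample.
    """
    import warnings

    genotypes = genotypes.reindex(fpkm.columns)
    wt_mean = fpkm.loc[:, genotypes == wt_label].mean(axis=1)
    ko_mean = fpkm.loc[:, genotypes == ko_label].mean(axis=1)
    active = (wt_mean >= fpkm_threshold) | (ko_mean >= fpkm_threshold)
    zero_wt = active & (wt_mean == 0)
    if zero_wt.any():
        warnings.warn(
            f"{int(zero_wt.sum())} active gene(s) with zero WT mean excluded "
            "from fold-change vectors",
            stacklevel=2,
        )
    keep = active & (wt_mean > 0)
    fc = (ko_mean / wt_mean)[keep]
    chrom = chrom_map.reindex(fc.index)
    return (
        fc[chrom == x_chrom].to_numpy(dtype=float),
        fc[chrom != x_chrom].to_numpy(dtype=float),
    )
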