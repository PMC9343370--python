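"""Interval arithmetic against examples and naive quadratic oracles."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from oracles import (
    consensus_naive,
    enhancer_naive,
    merge_naive,
    overlap_naive,
    partition_naive,
)
from xcikit.intervals import (
    GenomicInterval,
    annotate_peaks,
    classify_replicate_change,
    classify_yy1_peaks,
    consensus_peaks,
    gene_tss,
    merge_peaks,
    overlaps,
    partition_tss,
    rpk,
    rpkm,
)


def iv(chrom, start, end):
    return GenomicInterval(chrom, start, end)


def df(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def genes_df(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])


# --- intensities -------------------------------------------------------------


def test_rpkm_arithmetic():
    assert rpkm(100, 1_000_000, 2000) == pytest.approx(50.0)
    assert rpkm(0, 1_000_000, 2000) == 0.0
    assert rpkm(100, 2_000_000, 2000) == pytest.approx(25.0)  # doubling total halves


def test_rpkm_input_errors():
    with pytest.raises(ValueError):
        rpkm(10, 0, 100)
    with pytest.raises(ValueError):
        rpkm(10, 100, 0)


def test_rpk_arithmetic():
    assert rpk(500, 2500) == pytest.approx(200.0)
    assert rpk(0, 2500) == 0.0
    assert rpk(500, 1250) == pytest.approx(400.0)  # half width doubles RPK


# --- overlap -----------------------------------------------------------------


@pytest.mark.parametrize(
    "a, b, expected",
    [
        (("c", 100, 200), ("c", 199, 300), True),   # 1 bp shared
        (("c", 100, 200), ("c", 200, 300), False),  # abutting half-open
        (("c", 100, 200), ("d", 100, 200), False),  # different chrom
        (("c", 100, 200), ("c", 50, 400), True),
    ],
)
def test_overlap_convention(a, b, expected):
    assert overlaps(iv(*a), iv(*b)) is expected
    assert overlap_naive(a, b) is expected


# --- merge -------------------------------------------------------------------


def test_merge_gap_boundary():
    """bedtools -d semantics: gap = next.start - prev.end, inclusive."""
    merged = merge_peaks(df([("c", 100, 200), ("c", 1150, 1300)]), max_gap=1000)
    assert merged.values.tolist() == [["c", 100, 1300]]  # gap 950
    kept = merge_peaks(df([("c", 100, 200), ("c", 1201, 1300)]), max_gap=1000)
    assert len(kept) == 2  # gap 1001


def test_merge_overlapping_and_idempotent():
    peaks = df([("c", 100, 300), ("c", 250, 500), ("c", 5000, 5100), ("d", 0, 10)])
    m1 = merge_peaks(peaks, max_gap=1000)
    m2 = merge_peaks(m1, max_gap=1000)
    assert m1.values.tolist() == m2.values.tolist()


def test_merge_matches_quadratic_oracle():
    rng = np.random.default_rng(12)
    for _ in range(20):
        n = rng.integers(1, 120)
        starts = rng.integers(0, 50_000, size=n)
        widths = rng.integers(1, 2000, size=n)
        chroms = rng.choice(["c1", "c2"], size=n)
        peaks = df(list(zip(chroms, starts, starts + widths)))
        gap = int(rng.integers(-1, 1500))
        got = [tuple(r) for r in merge_peaks(peaks, max_gap=gap).values.tolist()]
        want = merge_naive(list(peaks.itertuples(index=False, name=None)), gap)
        assert sorted(got) == sorted(want)


# --- consensus ---------------------------------------------------------------


def test_consensus_inclusive_boundary():
    """2 of 4 samples is retained (0.5 >= 0.5); 1 of 4 is dropped; 1 of 2 kept."""
    shared = ("c", 100, 200)
    lone = ("c", 10_000, 10_100)
    sets4 = [df([shared]), df([(shared[0], 150, 250)]), df([lone]), df([("c", 99_000, 99_100)])]
    cons = consensus_peaks(sets4, min_fraction=0.5)
    spans = [tuple(r) for r in cons.values.tolist()]
    assert ("c", 100, 250) in spans
    assert all(not overlap_naive(s, lone) for s in spans)
    cons2 = consensus_peaks([df([shared]), df([lone])], min_fraction=0.5)
    assert len(cons2) == 2  # each peak supported by 1 of 2 samples


def test_consensus_monotone_in_fraction_and_matches_oracle():
    rng = np.random.default_rng(21)
    for _ in range(10):
        n_samples = int(rng.integers(2, 5))
        sets = []
        for _ in range(n_samples):
            k = int(rng.integers(1, 40))
            s = rng.integers(0, 30_000, size=k)
            w = rng.integers(50, 1500, size=k)
            sets.append(df(list(zip(["c"] * k, s, s + w))))
        prev = None
        for frac in (0.25, 0.5, 0.75, 1.0):
            cons = consensus_peaks(sets, min_fraction=frac)
            got = sorted(tuple(r) for r in cons.values.tolist())
            want = sorted(
                consensus_naive(
                    [list(s.itertuples(index=False, name=None)) for s in sets],
                    Fraction(str(frac)),
                )
            )
            assert got == want
            covered = sum(e - s for _, s, e in got)
            if prev is not None:
                assert covered <= prev  # raising the fraction never adds
            prev = covered


def test_consensus_empty_input():
    assert len(consensus_peaks([], min_fraction=0.5)) == 0


# --- TSS partition and annotation --------------------------------------------


GENES = genes_df(
    [
        ("geneA", "c", 10_000, 20_000, "+"),   # TSS 10_000
        ("geneB", "c", 50_000, 58_000, "-"),   # TSS 57_999
    ]
)


def test_gene_tss_strand():
    tss = gene_tss(GENES)
    assert tss.tolist() == [10_000, 57_999]


def test_gene_tss_unstranded_rejected():
    g = genes_df([("g", "c", 0, 10, ".")])
    with pytest.raises(ValueError, match="strand"):
        gene_tss(g)


def test_partition_window_overlap():
    peaks = df(
        [
            ("c", 12_900, 13_100),   # peak [TSS+2900, TSS+3100): overlaps window
            ("c", 13_001, 13_200),   # entirely beyond +3 kb
            ("c", 9_950, 10_050),    # contains the TSS
            ("c", 30_000, 30_100),   # far from both genes
        ]
    )
    labels = partition_tss(peaks, GENES, window=3000)
    assert labels.tolist() == ["proximal", "distal", "proximal", "distal"]


def test_partition_matches_quadratic_oracle():
    rng = np.random.default_rng(31)
    for _ in range(10):
        ng = int(rng.integers(1, 15))
        gs = np.sort(rng.choice(np.arange(0, 500_000, 100), size=ng, replace=False))
        genes = genes_df(
            [
                (f"g{i}", "c", int(s), int(s + rng.integers(500, 5000)), rng.choice(["+", "-"]))
                for i, s in enumerate(gs)
            ]
        )
        k = int(rng.integers(1, 200))
        ps = rng.integers(0, 520_000, size=k)
        peaks = df(list(zip(["c"] * k, ps, ps + rng.integers(50, 2000, size=k))))
        got = partition_tss(peaks, genes, window=3000).tolist()
        tss_list = [("c", int(t)) for t in gene_tss(genes)]
        want = partition_naive(
            list(peaks.itertuples(index=False, name=None)), tss_list, 3000
        )
        assert got == want


def test_annotate_proximal_nearest_tss():
    peaks = df([("c", 10_400, 10_600)])  # midpoint 10_500: 500 bp from geneA TSS
    ann = annotate_peaks(peaks, GENES)
    assert ann.loc[0, "tss_class"] == "proximal"
    assert ann.loc[0, "gene_id"] == "geneA"
    assert ann.loc[0, "distance"] == 500


def test_annotate_distal_gene_body():
    peaks = df([("c", 52_000, 52_300)])  # inside geneB's body but > 3 kb from TSSs?
    # geneB TSS = 57,999; 52,000..52,300 is > 3 kb away from both TSSs
    ann = annotate_peaks(peaks, GENES)
    assert ann.loc[0, "tss_class"] == "distal"
    assert ann.loc[0, "gene_id"] == "geneB"
    assert ann.loc[0, "distance"] == 0


def test_annotate_tie_breaks_lexicographically():
    genes = genes_df(
        [("geneB", "c", 14_000, 15_000, "+"), ("geneA", "c", 8_000, 9_000, "+")]
    )
    # TSSs at 14_000 and 8_000; the peak midpoint 11_000 is 3 kb from both
    # and the peak overlaps the TSS windows, so it is proximal
    peaks = df([("c", 10_900, 11_100)])
    ann = annotate_peaks(peaks, genes)
    assert ann.loc[0, "gene_id"] == "geneA"
    assert bool(ann.loc[0, "ambiguous"])


def test_annotate_no_genes_on_chrom_flagged():
    peaks = df([("other", 0, 100)])
    ann = annotate_peaks(peaks, GENES)
    assert bool(ann.loc[0, "unassigned"])


# --- replicate change --------------------------------------------------------


def test_classify_replicate_change():
    wt = np.array([[10, 12], [10, 12], [10, 10], [20, 22]])
    ko = np.array([[20, 22], [20, 8], [10, 10], [10, 12]])
    got = classify_replicate_change(wt, ko)
    assert got.tolist() == ["increased", "unchanged", "unchanged", "decreased"]


# --- promoter / enhancer classification --------------------------------------


def test_yy1_classification_rules():
    genes = genes_df([("g1", "c", 200_000, 210_000, "+")])  # TSS 200_000
    yy1 = df(
        [
            ("c", 199_000, 199_400),  # 1 kb upstream: promoter
            ("c", 250_000, 250_400),  # 50 kb away, with H3K27ac: enhancer
            ("c", 260_000, 260_400),  # 60 kb away, no H3K27ac: other
            ("c", 340_000, 340_400),  # 140 kb away: beyond the band
        ]
    )
    ac = df([("c", 250_100, 250_500), ("c", 340_000, 340_400)])
    labels, ann = classify_yy1_peaks(yy1, ac, genes)
    assert labels["role"].tolist() == ["promoter", "enhancer", "other", "other"]
    roles = ann.set_index("peak")["role"]
    assert roles.loc[0] == "promoter" and roles.loc[1] == "enhancer"
    assert set(ann["gene_id"]) == {"g1"}


def test_yy1_promoter_takes_precedence():
    """A peak in a TSS window that also overlaps H3K27ac is promoter, so the
    promoter and enhancer label sets are disjoint by construction."""
    genes = genes_df([("g1", "c", 100_000, 110_000, "+")])
    yy1 = df([("c", 99_500, 100_500)])
    ac = df([("c", 99_400, 100_600)])
    labels, _ = classify_yy1_peaks(yy1, ac, genes)
    assert labels["role"].tolist() == ["promoter"]


def test_yy1_matches_quadratic_oracle():
    rng = np.random.default_rng(44)
    for _ in range(8):
        ng = int(rng.integers(1, 8))
        gs = np.sort(rng.choice(np.arange(0, 2_000_000, 1000), size=ng, replace=False))
        genes = genes_df(
            [
                (f"g{i}", "c", int(s), int(s + 5000), rng.choice(["+", "-"]))
                for i, s in enumerate(gs)
            ]
        )
        k = int(rng.integers(1, 100))
        ps = rng.integers(0, 2_100_000, size=k)
        yy1 = df(list(zip(["c"] * k, ps, ps + rng.integers(100, 1500, size=k))))
        ka = int(rng.integers(1, 60))
        acs = rng.integers(0, 2_100_000, size=ka)
        ac = df(list(zip(["c"] * ka, acs, acs + rng.integers(100, 1500, size=ka))))
        labels, _ = classify_yy1_peaks(yy1, ac, genes)
        tss_list = [("c", int(t)) for t in gene_tss(genes)]
        want = enhancer_naive(
            list(yy1.itertuples(index=False, name=None)),
            list(ac.itertuples(index=False, name=None)),
            tss_list,
            3000,
            125_000,
        )
        assert labels["role"].tolist() == want
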