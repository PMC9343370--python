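"""Peak interval arithmetic: intensity measures, consensus and merged peaks,
TSS-proximal/distal partition, peak-to-gene annotation, and promoter/enhancer
classification of transcription-factor (YY1) peaks.

Coordinates are 0-based half-open (BED convention) throughout.  Two
intervals overlap when they share at least 1 bp, so [100,200) and [199,300)
overlap while abutting [100,200) and [200,300) do not.  The TSS of a gene is
its start for + strand and end-1 for - strand; unstranded genes are
rejected.  A gene's TSS-proximal window is [TSS-w, TSS+w) with w = 3 kb.

Interval tables are plain DataFrames with columns chrom, start, end and an
optional id/strand; genes additionally need gene_id and strand.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "gene_tss",
    "rpkm",
    "rpk",
    "overlaps",
    "merge_peaks",
    "consensus_peaks",
    "partition_tss",
    "annotate_peaks",
    "classify_replicate_change",
    "classify_yy1_peaks",
]


class GenomicInterval(NamedTuple):
    chrom: str
    start: int
    end: int
    strand: str = "."
    id: str = ""


def _check_intervals(df: pd.DataFrame, name: str = "intervals") -> None:
    for col in ("chrom", "start", "end"):
        if col not in df.columns:
            raise ValueError(f"{name}: missing column {col!r}")
    if len(df) and not (df["start"] < df["end"]).all():
        bad = df.index[~(df["start"] < df["end"])][0]
        raise ValueError(f"{name}: start >= end at row {bad}")
    if len(df) and (df["start"] < 0).any():
        raise ValueError(f"{name}: negative start")


def gene_tss(genes: pd.DataFrame) -> pd.Series:
    """TSS per gene: start on +, end-1 on -; '.' strand is an error."""
    _check_intervals(genes, "genes")
    strand = genes["strand"]
    if not strand.isin(["+", "-"]).all():
        bad = genes.loc[~strand.isin(["+", "-"]), "gene_id"].iloc[0]
        raise ValueError(f"gene {bad!r}: strand must be '+' or '-' to define a TSS")
    tss = np.where(strand == "+", genes["start"], genes["end"] - 1)
    return pd.Series(tss, index=genes.index, name="tss")


# ---------------------------------------------------------------------------
# intensity measures
# ---------------------------------------------------------------------------


def rpkm(read_count, total_reads, region_width_bp):
    """RPKM = 1e6 * reads in region / (total reads * region width in kb)."""
    read_count = np.asarray(read_count, dtype=float)
    total = np.asarray(total_reads, dtype=float)
    width = np.asarray(region_width_bp, dtype=float)
    if (width <= 0).any() or (total <= 0).any():
        raise ValueError("region width and total reads must be positive")
    return 1e6 * read_count / (total * (width / 1e3))


def rpk(normalized_count, peak_width_bp):
    """RPK = normalized reads in peak / peak width in kb."""
    count = np.asarray(normalized_count, dtype=float)
    width = np.asarray(peak_width_bp, dtype=float)
    if (width <= 0).any():
        raise ValueError("peak width must be positive")
    return count / (width / 1e3)


# ---------------------------------------------------------------------------
# overlap machinery
# ---------------------------------------------------------------------------


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two half-open intervals share >= 1 bp on the same chrom."""
    if a.chrom != b.chrom:
        return False
    return min(a.end, b.end) - max(a.start, b.start) >= 1


class _OverlapIndex:
    """Per-chromosome sorted-start index answering 'does any interval
    overlap [qs, qe)?' via a prefix maximum of ends."""

    def __init__(self, df: pd.DataFrame):
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, sub in df.groupby("chrom", sort=False):
            starts = sub["start"].to_numpy(np.int64)
            ends = sub["end"].to_numpy(np.int64)
            order = np.argsort(starts, kind="stable")
            starts, ends = starts[order], ends[order]
            self._by_chrom[str(chrom)] = (starts, np.maximum.accumulate(ends))

    def any_overlap(self, chrom: np.ndarray, qs: np.ndarray, qe: np.ndarray) -> np.ndarray:
        out = np.zeros(len(qs), dtype=bool)
        for c in np.unique(chrom):
            entry = self._by_chrom.get(str(c))
            if entry is None:
                continue
            starts, prefmax = entry
            sel = chrom == c
            # candidate intervals start before the query end
            idx = np.searchsorted(starts, qe[sel], side="left")
            hit = np.zeros(idx.shape, dtype=bool)
            nz = idx > 0
            hit[nz] = prefmax[idx[nz] - 1] > qs[sel][nz]
            out[sel] = hit
        return out


def merge_peaks(intervals: pd.DataFrame, max_gap: int = 1000) -> pd.DataFrame:
    """Union intervals on the same chrom whose gap is <= max_gap (bedtools
    ``merge -d`` semantics: gap = next.start - prev.end, applied
    transitively).  Output is sorted and pairwise separated by > max_gap.
    max_gap = -1 unions only truly overlapping intervals.
    """
    _check_intervals(intervals)
    rows = []
    for chrom, sub in intervals.groupby("chrom", sort=True):
        starts = sub["start"].to_numpy(np.int64)
        ends = sub["end"].to_numpy(np.int64)
        order = np.argsort(starts, kind="stable")
        starts, ends = starts[order], ends[order]
        cur_s, cur_e = int(starts[0]), int(ends[0])
        for s, e in zip(starts[1:], ends[1:]):
            if s - cur_e <= max_gap:
                cur_e = max(cur_e, int(e))
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = int(s), int(e)
        rows.append((chrom, cur_s, cur_e))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def consensus_peaks(
    peak_sets: Sequence[pd.DataFrame] | Mapping[str, pd.DataFrame],
    min_fraction: float = 0.5,
) -> pd.DataFrame:
    """Peaks supported by at least ``min_fraction`` of the sample peak sets.

    Every interval from the pooled sets is scored by the number of distinct
    samples with a >= 1 bp overlapping peak (its own sample counts);
    intervals with support/n_samples >= min_fraction (inclusive, evaluated
    in exact rational arithmetic) are kept and their overlapping union is
    returned.  Raising min_fraction can only remove consensus regions.
    """
    if isinstance(peak_sets, Mapping):
        peak_sets = list(peak_sets.values())
    n = len(peak_sets)
    if n == 0 or all(len(p) == 0 for p in peak_sets):
        return pd.DataFrame(columns=["chrom", "start", "end"])
    for p in peak_sets:
        _check_intervals(p, "peak set")
    indexes = [_OverlapIndex(p) for p in peak_sets]
    pooled = pd.concat(
        [p[["chrom", "start", "end"]] for p in peak_sets], ignore_index=True
    )
    chrom = pooled["chrom"].to_numpy()
    qs = pooled["start"].to_numpy(np.int64)
    qe = pooled["end"].to_numpy(np.int64)
    support = np.zeros(len(pooled), dtype=np.int64)
    for ix in indexes:
        support += ix.any_overlap(chrom, qs, qe)
    frac = Fraction(str(float(min_fraction)))
    keep = support * frac.denominator >= frac.numerator * n
    if not keep.any():
        return pd.DataFrame(columns=["chrom", "start", "end"])
    return merge_peaks(pooled.loc[keep], max_gap=-1)


# ---------------------------------------------------------------------------
# TSS partition and annotation
# ---------------------------------------------------------------------------


def _tss_windows(genes: pd.DataFrame, window: int) -> pd.DataFrame:
    tss = gene_tss(genes)
    return pd.DataFrame(
        {
            "chrom": genes["chrom"].to_numpy(),
            "start": np.maximum(tss.to_numpy() - window, 0),
            "end": tss.to_numpy() + window,
            "gene_id": genes["gene_id"].to_numpy(),
            "tss": tss.to_numpy(),
        }
    )


def partition_tss(
    peaks: pd.DataFrame, genes: pd.DataFrame, window: int = 3000
) -> pd.Series:
    """'proximal' iff the peak overlaps the [TSS-w, TSS+w) window of any
    gene (>= 1 bp overlap convention); 'distal' otherwise."""
    _check_intervals(peaks, "peaks")
    wins = _tss_windows(genes, window)
    ix = _OverlapIndex(wins)
    hit = ix.any_overlap(
        peaks["chrom"].to_numpy(),
        peaks["start"].to_numpy(np.int64),
        peaks["end"].to_numpy(np.int64),
    )
    return pd.Series(
        np.where(hit, "proximal", "distal"), index=peaks.index, name="tss_class"
    )


def _interval_distance(ps, pe, gs, ge) -> np.ndarray:
    """Gap between half-open intervals; 0 when they overlap or abut."""
    return np.maximum(0, np.maximum(gs - pe, ps - ge))


def annotate_peaks(
    peaks: pd.DataFrame, genes: pd.DataFrame, window: int = 3000
) -> pd.DataFrame:
    """Assign each peak to one gene.

    TSS-proximal peaks go to the gene with the closest TSS (distance from
    the peak midpoint); TSS-distal peaks go to the gene with the closest
    gene body (distance 0 when overlapping).  Exact ties are broken toward
    the lexicographically smaller gene_id and flagged ambiguous; peaks on a
    chromosome without genes are left unassigned and flagged.
    """
    _check_intervals(peaks, "peaks")
    _check_intervals(genes, "genes")
    tss_class = partition_tss(peaks, genes, window=window)
    tss = gene_tss(genes).to_numpy(np.int64)

    gene_id = np.empty(len(peaks), dtype=object)
    distance = np.full(len(peaks), np.nan)
    ambiguous = np.zeros(len(peaks), dtype=bool)
    gene_id[:] = None

    gene_by_chrom = {
        str(c): sub.index.to_numpy() for c, sub in genes.groupby("chrom", sort=False)
    }
    g_start = genes["start"].to_numpy(np.int64)
    g_end = genes["end"].to_numpy(np.int64)
    g_name = genes["gene_id"].to_numpy(object)

    pmid = (peaks["start"].to_numpy(np.int64) + peaks["end"].to_numpy(np.int64)) // 2
    p_start = peaks["start"].to_numpy(np.int64)
    p_end = peaks["end"].to_numpy(np.int64)
    p_chrom = peaks["chrom"].to_numpy()
    proximal = (tss_class == "proximal").to_numpy()

    for i in range(len(peaks)):
        gidx = gene_by_chrom.get(str(p_chrom[i]))
        if gidx is None or len(gidx) == 0:
            continue
        if proximal[i]:
            d = np.abs(pmid[i] - tss[gidx])
        else:
            d = _interval_distance(p_start[i], p_end[i], g_start[gidx], g_end[gidx])
        best = d.min()
        cand = g_name[gidx[d == best]]
        cand.sort()
        gene_id[i] = cand[0]
        distance[i] = float(best)
        ambiguous[i] = len(cand) > 1

    return pd.DataFrame(
        {
            "tss_class": tss_class.to_numpy(),
            "gene_id": gene_id,
            "distance": distance,
            "ambiguous": ambiguous,
            "unassigned": pd.isna(gene_id),
        },
        index=peaks.index,
    )


def classify_replicate_change(
    rpk_wt: np.ndarray, rpk_ko: np.ndarray
) -> np.ndarray:
    """Per-peak replicate-consistent intensity change.

    'increased' iff KO RPK > WT RPK in every replicate pair (strict),
    'decreased' iff lower in every pair, otherwise 'unchanged' (including
    ties and discordant replicates).  Inputs are peak x replicate arrays
    with matching replicate order.
    """
    wt = np.atleast_2d(np.asarray(rpk_wt, dtype=float))
    ko = np.atleast_2d(np.asarray(rpk_ko, dtype=float))
    if wt.shape != ko.shape:
        raise ValueError("WT and KO replicate arrays must have the same shape")
    up = (ko > wt).all(axis=1)
    down = (ko < wt).all(axis=1)
    return np.where(up, "increased", np.where(down, "decreased", "unchanged"))


def classify_yy1_peaks(
    yy1: pd.DataFrame,
    h3k27ac: pd.DataFrame,
    genes: pd.DataFrame,
    window: int = 3000,
    enhancer_max: int = 125000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Promoter / enhancer / other classification of TF peaks.

    A peak overlapping any gene's +/-3 kb TSS window is a promoter peak.
    Otherwise, a peak overlapping at least one H3K27ac peak and lying within
    3-125 kb of some TSS (i.e. overlapping a +/-125 kb TSS window without
    being promoter) is an enhancer peak.  Everything else is 'other'.
    Promoter peaks are annotated to all genes with TSS within +/-3 kb,
    enhancer peaks to all genes with TSS within +/-125 kb; one peak may
    annotate many genes.

    Returns (labels, annotations): labels has a 'role' column per peak;
    annotations is long-form (peak index, gene_id, role).
    """
    _check_intervals(yy1, "yy1")
    _check_intervals(h3k27ac, "h3k27ac")
    prom_wins = _tss_windows(genes, window)
    enh_wins = _tss_windows(genes, enhancer_max)

    chrom = yy1["chrom"].to_numpy()
    qs = yy1["start"].to_numpy(np.int64)
    qe = yy1["end"].to_numpy(np.int64)

    is_prom = _OverlapIndex(prom_wins).any_overlap(chrom, qs, qe)
    near = _OverlapIndex(enh_wins).any_overlap(chrom, qs, qe)
    has_ac = (
        _OverlapIndex(h3k27ac).any_overlap(chrom, qs, qe)
        if len(h3k27ac)
        else np.zeros(len(yy1), dtype=bool)
    )
    is_enh = ~is_prom & has_ac & near
    role = np.where(is_prom, "promoter", np.where(is_enh, "enhancer", "other"))
    labels = pd.DataFrame({"role": role}, index=yy1.index)

    # many-to-many annotation via quadratic-per-chromosome window hits;
    # peak and gene counts per chromosome are small in this analysis
    ann_rows: list[tuple] = []
    for wins, mask, rname in ((prom_wins, is_prom, "promoter"), (enh_wins, is_enh, "enhancer")):
        for chrom_name, gsub in wins.groupby("chrom", sort=False):
            psel = np.flatnonzero((chrom == chrom_name) & mask)
            if len(psel) == 0:
                continue
            ws = gsub["start"].to_numpy(np.int64)
            we = gsub["end"].to_numpy(np.int64)
            gn = gsub["gene_id"].to_numpy(object)
            for i in psel:
                hit = np.minimum(qe[i], we) - np.maximum(qs[i], ws) >= 1
                for g in gn[hit]:
                    ann_rows.append((yy1.index[i], g, rname))
    annotations = pd.DataFrame(ann_rows, columns=["peak", "gene_id", "role"])
    return labels, annotations
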