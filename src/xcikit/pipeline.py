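"""End-to-end workflows binding the analysis stages together.

Two workflows: the allelic fibroblast workflow (d-scores -> escape /
dependence classification -> association test) and the non-allelic HSPC
workflow (FPKM -> activity -> replicate-consistent DEGs -> cDEG/lsDEG
scoping -> fold-change CDF + KS test).  Each run writes its tables under an
output directory plus a JSON manifest with the configuration snapshot,
per-stage row counts and output checksums; identical inputs and
configuration reproduce identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from .allelic import Thresholds, run_allelic_pipeline
from .expression import (
    ExpressionMatrix,
    call_active,
    call_deg,
    compute_fpkm,
    foldchange_cdf,
    normalize_counts,
    scope_degs,
)
from .io import read_allelic_counts
from .stats import escape_dependence_association, ks_two_sample

__all__ = ["AllelicRunConfig", "run_allelic_workflow", "run_hspc_workflow", "validate_inputs"]


@dataclass
class AllelicRunConfig:
    wt_path: str
    mut_path: str
    outdir: str
    min_allelic_reads: int = 10
    escape_ratio: float = 0.05
    delta_d: float = 0.03
    exclude_features: tuple[str, ...] = ()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(outdir: Path, config: dict, counts: dict, outputs: list[Path]) -> Path:
    manifest = {
        "package": "xcikit",
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "config": config,
        "row_counts": counts,
        "checksums": {p.name: _sha256(p) for p in outputs},
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path


def run_allelic_workflow(cfg: AllelicRunConfig) -> dict:
    """Classify a WT/mutant allelic count pair and test the association.

    Writes classification.tsv, summary.json and manifest.json under
    cfg.outdir; returns the summary dict (classification counts, the 2x2
    table, and the Fisher p-value).
    """
    for p in (cfg.wt_path, cfg.mut_path):
        if not Path(p).exists():
            raise FileNotFoundError(f"allelic count table not found: {p}")
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    th = Thresholds(cfg.min_allelic_reads, cfg.escape_ratio, cfg.delta_d)
    wt = read_allelic_counts(cfg.wt_path)
    mut = read_allelic_counts(cfg.mut_path)
    classification = run_allelic_pipeline(wt, mut, th)

    if len(classification):
        table, result = escape_dependence_association(
            classification, exclude=cfg.exclude_features
        )
        assoc = {
            "table": table.as_array().tolist(),
            "fisher_p": result.p_value,
            "odds_ratio": result.statistic,
        }
    else:
        assoc = {"table": None, "fisher_p": None, "odds_ratio": None}

    class_path = outdir / "classification.tsv"
    classification.to_csv(class_path, sep="\t", index_label="feature_id")
    summary = {**classification.attrs.get("summary", {}), **assoc}
    summary_path = outdir / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2))
    _write_manifest(
        outdir,
        asdict(cfg),
        {"classification": len(classification)},
        [class_path, summary_path],
    )
    return summary


def run_hspc_workflow(
    matrix: ExpressionMatrix,
    chrom_map: pd.Series,
    outdir: str,
    active_scope: str = "any",
    x_chrom: str = "chrX",
) -> dict:
    """Non-allelic expression workflow over a multi-population matrix.

    Per population: FPKM, activity filter, replicate-consistent DEG calls on
    median-of-ratios-normalized counts; across populations: cDEG/lsDEG
    scoping with Venn counts; per population additionally the X-vs-autosome
    fold-change KS comparison.  Writes deg_scope.tsv, summary.json and
    manifest.json under ``outdir``; returns the summary.
    """
    outdir_p = Path(outdir)
    outdir_p.mkdir(parents=True, exist_ok=True)

    fpkm = compute_fpkm(matrix)
    meta = matrix.samples
    calls = {}
    ks = {}
    for pop, msub in meta.groupby("population", sort=True):
        cols = msub.index
        sub_counts = matrix.counts[cols]
        norm = normalize_counts(sub_counts)
        active = call_active(fpkm[cols], meta.loc[cols, "genotype"], scope=active_scope)
        wt_cols = msub.index[msub["genotype"] == "WT"].tolist()
        ko_cols = msub.index[msub["genotype"] == "KO"].tolist()
        calls[pop] = call_deg(norm, wt_cols, ko_cols, active=active)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            x_fc, auto_fc = foldchange_cdf(
                fpkm[cols], meta.loc[cols, "genotype"], chrom_map, x_chrom=x_chrom
            )
        if len(x_fc) and len(auto_fc):
            ks[pop] = ks_two_sample(x_fc, auto_fc).p_value
        else:
            ks[pop] = None

    scoped = scope_degs(calls)
    scope_path = outdir_p / "deg_scope.tsv"
    scoped.to_csv(scope_path, sep="\t", index_label="gene_id")

    summary = {"venn": scoped.attrs["venn"], "ks_p_by_population": ks}
    summary_path = outdir_p / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2))
    _write_manifest(
        outdir_p,
        {"active_scope": active_scope, "x_chrom": x_chrom},
        {"genes": len(scoped)},
        [scope_path, summary_path],
    )
    return summary


def validate_inputs(paths: dict[str, str]) -> list[str]:
    """Schema check of input files; returns a list of violations (empty when
    the bundle is valid).  Never mutates inputs.

    Keys of ``paths`` select the schema: 'allelic_*' -> allelic count TSV,
    'bed_*' -> BED intervals, 'genes' -> gene-model TSV.
    """
    violations: list[str] = []
    for key, path in paths.items():
        p = Path(path)
        if not p.exists():
            violations.append(f"{key}: file not found: {path}")
            continue
        try:
            if key.startswith("allelic"):
                df = read_allelic_counts(p)
                for col in ("reads_xi", "reads_xa"):
                    bad = df.index[df[col] < 0]
                    for i in bad:
                        violations.append(f"{key}: row {i + 2}: negative {col}")
            elif key.startswith("bed"):
                raw = pd.read_csv(p, sep="\t", header=None, comment="#")
                for i, row in raw.iterrows():
                    if int(row[1]) >= int(row[2]):
                        violations.append(f"{key}: line {i + 1}: start >= end")
            elif key == "genes":
                from .io import read_gene_models

                df = read_gene_models(p)
                for i, row in df.iterrows():
                    if row["start"] >= row["end"]:
                        violations.append(f"{key}: row {i + 2}: start >= end")
                    if row["strand"] not in ("+", "-"):
                        violations.append(f"{key}: row {i + 2}: bad strand {row['strand']!r}")
        except Exception as exc:  # report, don't raise
            violations.append(f"{key}: {exc}")
    return violations
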