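"""Headline association: the escape x dependence Fisher test.

Computes the test on the observed study counts (352 analyzable X-linked
genes: 18 escape of which 14 Xist-dependent, 334 subjective of which 21
Xist-dependent; Xist itself excluded from the escape row since its own
reads vanish upon deletion) and on the synthetic classification from
02_allelic_classification.py.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from xcikit.stats import escape_dependence_association, fisher_exact

ap = argparse.ArgumentParser()
ap.add_argument("--allelic", type=Path, default=Path("results/allelic"))
ap.add_argument("--outdir", type=Path, default=Path("results/association"))
args = ap.parse_args()
args.outdir.mkdir(parents=True, exist_ok=True)

printed = fisher_exact([[14, 3], [21, 313]])
print(f"observed-count table [[14,3],[21,313]]: Fisher p = {printed.p_value:.2g}")

res = pd.read_csv(args.allelic / "classification.tsv", sep="\t").set_index("feature_id")
tab, synth = escape_dependence_association(res)
print(f"synthetic classification table {tab.as_array().tolist()}: Fisher p = {synth.p_value:.3g}")

(args.outdir / "association.json").write_text(
    json.dumps(
        {
            "printed_counts_p": printed.p_value,
            "synthetic_table": tab.as_array().tolist(),
            "synthetic_p": synth.p_value,
        },
        indent=2,
    )
)
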