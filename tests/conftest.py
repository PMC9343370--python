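import sys
from pathlib import Path

import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from xcikit.sim import (
    AllelicSimConfig,
    ExpressionSimConfig,
    simulate_allelic_counts,
    simulate_expression_matrix,
)


@pytest.fixture(scope="session")
def allelic_default():
    """Default-regime allelic simulation: tables, truth (indexed)."""
    tables, truth = simulate_allelic_counts(AllelicSimConfig(seed=11))
    return tables, truth.set_index("gene_id")


@pytest.fixture(scope="session")
def expression_strong_effect():
    """Expression simulation with a strong planted effect and low noise."""
    cfg = ExpressionSimConfig(effect_log2fc=2.0, dispersion=0.01, seed=7)
    matrix, truth = simulate_expression_matrix(cfg)
    return matrix, truth.set_index("gene_id")
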