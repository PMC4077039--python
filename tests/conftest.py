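import numpy as np
import pandas as pd
import pytest

import pairscreen as ps
from pairscreen.screen_io import RESULT_COLUMNS, ResultTable, ScreenTable


@pytest.fixture
def small_screen() -> ScreenTable:
    """12 x 10 quadruplicate screen with 3 spiked pairs at fold 0.5."""
    cfg = ps.SimulationConfig(
        n_a=12, n_b=10, n_replicates=4, n_true_positives=3, fold=0.5, seed=101
    )
    table, _ = ps.generate_screen(cfg)
    return table


@pytest.fixture
def null_screen() -> ScreenTable:
    """20 x 20 quadruplicate screen with no interactions."""
    cfg = ps.SimulationConfig(
        n_a=20, n_b=20, n_replicates=4, n_true_positives=0, fold=1.0, seed=202
    )
    table, _ = ps.generate_screen(cfg)
    return table


def make_results(rows) -> ResultTable:
    return ResultTable(pd.DataFrame(rows, columns=RESULT_COLUMNS))


@pytest.fixture
def results_fixture() -> ResultTable:
    """Ten hand-written result rows with easily checked values."""
    rows = [
        # pertA, pertB, relA, relB, absA, absB, p_a, p_b, p_comb
        ("KRAS_G12D", "d01", 0.50, 0.55, 150.0, 90.0, 0.001, 0.002, 0.0005),
        ("KRAS_G12D", "d02", 1.05, 1.00, 150.0, 120.0, 0.600, 0.500, 0.550),
        ("BRAF_V600E", "d01", 0.40, 0.45, 200.0, 90.0, 0.010, 0.020, 0.0080),
        ("BRAF_V600E", "d02", 1.10, 0.98, 200.0, 120.0, 0.800, 0.700, 0.760),
        ("TP53_kd", "d01", 0.90, 0.95, 80.0, 90.0, 0.040, 0.300, 0.0600),
        ("TP53_kd", "d02", 1.00, 1.02, 80.0, 120.0, 0.950, 0.900, 0.930),
        ("control", "d01", 1.00, 1.00, 120.0, 90.0, 1.000, 1.000, 1.000),
        ("control", "d02", 1.30, 1.20, 120.0, 120.0, 0.030, 0.200, 0.0400),
        ("PTEN_kd", "d01", 0.70, 0.75, 60.0, 90.0, 0.045, 0.060, 0.0300),
        ("PTEN_kd", "d02", 1.01, 0.99, 60.0, 120.0, np.nan, np.nan, np.nan),
    ]
    return make_results(rows)
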