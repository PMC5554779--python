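import logging
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import isopept as ip
from isopept.transcript_layer import CONTROL, DEPLETED

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

logging.getLogger("isopept").setLevel(logging.ERROR)
warnings.filterwarnings(
    "ignore", message="Precision loss occurred", category=RuntimeWarning
)


def expression_from_medians(medians: dict[str, dict[str, list[float]]],
                            gene_of: dict[str, str]) -> ip.ExpressionTable:
    """Build a long-form expression table from per-condition replicate lists."""
    rows = []
    for tid, conds in medians.items():
        for cond, values in conds.items():
            for rep, v in enumerate(values, start=1):
                rows.append((tid, gene_of[tid], cond, rep, float(v)))
    return ip.ExpressionTable(
        pd.DataFrame(rows, columns=list(ip.ExpressionTable.COLUMNS))
    )


@pytest.fixture
def toy_expression() -> ip.ExpressionTable:
    """Two genes: GA with a usage change (T1 up, T2 down), GB single-isoform."""
    return expression_from_medians(
        {
            "T1": {CONTROL: [8, 8, 8], DEPLETED: [2, 2, 2]},
            "T2": {CONTROL: [2, 2, 2], DEPLETED: [8, 8, 8]},
            "T3": {CONTROL: [5, 5, 5], DEPLETED: [10, 10, 10]},
        },
        {"T1": "GA", "T2": "GA", "T3": "GB"},
    )


def intensity_matrix(values: dict[str, dict[str, list[float]]],
                     normalized: bool = True) -> ip.IntensityMatrix:
    peptides = sorted(values)
    cols = []
    for cond in (CONTROL, DEPLETED):
        n = len(next(iter(values.values()))[cond])
        cols += [(cond, r) for r in range(1, n + 1)]
    data = [
        [v for cond in (CONTROL, DEPLETED) for v in values[p][cond]]
        for p in peptides
    ]
    df = pd.DataFrame(
        data, index=peptides,
        columns=pd.MultiIndex.from_tuples(cols, names=["condition", "replicate"]),
    )
    return ip.IntensityMatrix(df, normalized=normalized)


@pytest.fixture(scope="session")
def small_dataset() -> ip.SyntheticDataset:
    """One small simulated experiment reused across read-only tests."""
    return ip.simulate_dataset(ip.SimulationConfig(n_genes=80, seed=5))


@pytest.fixture(scope="session")
def small_result(small_dataset) -> ip.PipelineResult:
    return ip.run_on_dataset(small_dataset)
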