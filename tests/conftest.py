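"""Shared fixtures: small synthetic cohorts generated at test time."""

import numpy as np
import pandas as pd
import pytest

from metaquad import ExpressionMatrix, SimulationConfig, simulate_cohorts


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    return SimulationConfig(cohort_sizes=(60, 40, 50), n_background_genes=300, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    """A 150-sample, ~400-gene cohort shared by read-only tests."""
    return simulate_cohorts(small_cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """The full default study conditions (2097 genes x 760 samples)."""
    cfg = SimulationConfig(seed=2024)
    return cfg, simulate_cohorts(cfg)


def make_expression(values: np.ndarray, cohort=None, prefix="g") -> ExpressionMatrix:
    """Wrap a plain array as an ExpressionMatrix with simple ids."""
    g, n = values.shape
    cols = [f"s{j}" for j in range(n)]
    if cohort is None:
        cohort = ["batch1"] * n
    return ExpressionMatrix(
        pd.DataFrame(values, index=[f"{prefix}{i}" for i in range(g)], columns=cols),
        pd.Series(list(cohort), index=cols),
    )
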