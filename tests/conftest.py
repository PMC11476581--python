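import numpy as np
import pandas as pd
import pytest

from mhcscreen.io import ClinicalTable, ExpressionMatrix, RunConfig
from mhcscreen.simulate import (
    SimulationConfig,
    simulate_bulk_cohort,
    simulate_cellline_panel,
)


@pytest.fixture(scope="session")
def small_sim_config() -> SimulationConfig:
    """A scaled-down six-cohort study for fast end-to-end tests."""
    return SimulationConfig(n_samples=120, n_genes=100, n_planted_negative=10,
                            n_planted_dual=3, n_cohorts=6, seed=42)


@pytest.fixture(scope="session")
def small_cohort(small_sim_config):
    return simulate_bulk_cohort(small_sim_config)


@pytest.fixture(scope="session")
def small_panel(small_sim_config):
    return simulate_cellline_panel(small_sim_config)


@pytest.fixture()
def run_config() -> RunConfig:
    return RunConfig(seed=42)


@pytest.fixture()
def toy_expression() -> ExpressionMatrix:
    """4 genes x 3 samples used by the frozen scoring walk values."""
    values = np.array([
        [1.0, 2.0, 3.0],
        [3.0, 1.0, 2.0],
        [2.0, 3.0, 1.0],
        [0.0, 5.0, 1.0],
    ])
    return ExpressionMatrix(["g1", "g2", "g3", "g4"], ["s1", "s2", "s3"], values)


def make_clinical(times: dict[str, np.ndarray], events: dict[str, np.ndarray],
                  cohort: str = "BRCA") -> ClinicalTable:
    n = len(next(iter(times.values())))
    samples = [f"S{i:03d}" for i in range(n)]
    endpoints = {
        name: pd.DataFrame({"time": times[name], "event": events[name]}, index=samples)
        for name in times
    }
    return ClinicalTable(sample_ids=samples, endpoints=endpoints,
                         cohort=pd.Series([cohort] * n, index=samples))
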