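"""Shared fixtures: a small synthetic slide/cohort kept session-scoped so
the expensive generation runs once."""

import numpy as np
import pandas as pd
import pytest

from mifquant import AnalysisConfig, CohortSpec, assign_phenotypes, generate_slide


def small_spec(**overrides) -> CohortSpec:
    """A scaled-down slide (quarter-size tumor, fewer TLS) for fast tests."""
    base = dict(
        n_patients=3,
        slide_width_um=6000.0,
        slide_depth_um=5000.0,
        tumor_radius_um=1500.0,
        tumor_center_depth_um=3000.0,
        tls_rate_median=8.0,
        tls_rate_log_sd=0.4,
    )
    base.update(overrides)
    return CohortSpec(**base)


@pytest.fixture(scope="session")
def spec():
    return small_spec()


@pytest.fixture(scope="session")
def slide(spec):
    """One generated slide with phenotypes assigned: (cells, regions, truth)."""
    cells, regions, truth = generate_slide(spec, "P001", seed=42)
    labeled, _ = assign_phenotypes(cells)
    return labeled, regions, truth


@pytest.fixture()
def config():
    return AnalysisConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def run_pipeline(tmp, seed: int = 11, n: int = 4) -> dict:
    """Drive the full CLI chain on a seeded synthetic cohort; returns
    artifact paths."""
    from mifquant.pipeline import run_standard_pipeline

    return run_standard_pipeline(tmp, seed=seed, n_patients=n)


def random_cells(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Cells with independent random binary markers (not biologically
    constrained) — stress input for gating properties."""
    df = pd.DataFrame(
        rng.integers(0, 2, size=(n, 6)),
        columns=["CD3", "CD8", "FoxP3", "CD20", "CD68", "PanCK"],
    )
    df.insert(0, "cell_id", [f"c{i}" for i in range(n)])
    df.insert(1, "x_um", rng.uniform(0, 1000, n))
    df.insert(2, "y_um", rng.uniform(0, 1000, n))
    return df
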