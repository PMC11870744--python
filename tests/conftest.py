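"""Shared fixtures: one simulated cohort per modality, session-scoped."""

import numpy as np
import pytest

from senpatch import scrna
from senpatch.sim import gen_ephys, gen_expression, gen_fish
from senpatch.specs import EphysSimSpec, ExprSimSpec, FishSimSpec

STEP_GRID = np.arange(-100.0, 301.0, 25.0)


@pytest.fixture(scope="session")
def rs_cell():
    """Regular-spiking simulated cell (sweeps, truth)."""
    return gen_ephys(EphysSimSpec.regular_spiking(seed=7), STEP_GRID)


@pytest.fixture(scope="session")
def fs_cell():
    """Fast-spiking simulated cell (sweeps, truth)."""
    return gen_ephys(EphysSimSpec.fast_spiking(seed=7), STEP_GRID)


@pytest.fixture(scope="session")
def expr_cohort():
    """Default 197-cell four-cluster expression cohort (adata, truth, spec)."""
    spec = ExprSimSpec(seed=11)
    adata, truth = gen_expression(spec)
    return adata, truth, spec


@pytest.fixture(scope="session")
def expr_pipeline(expr_cohort):
    """Normalized matrix, cluster labels and marker table for the cohort."""
    adata, truth, spec = expr_cohort
    norm = scrna.normalize_log(adata)
    labels = scrna.cluster_cells(norm, n_clusters=4, seed=0)
    markers = scrna.find_markers(norm, labels)
    return norm, labels, markers, truth, spec


@pytest.fixture(scope="session")
def fish_sample():
    """300-cell spot-table FISH sample (sample, truth, spec)."""
    spec = FishSimSpec(n_cells=300, seed=4)
    sample, truth = gen_fish(spec)
    return sample, truth, spec


@pytest.fixture(scope="session")
def small_fish_volume():
    """Small rendered FISH volume for segmentation/detection tests."""
    spec = FishSimSpec(
        n_cells=6, seed=1,
        soma_axes_um={"PY1": (3.0, 3.5, 3.5), "PY2": (3.8, 4.2, 4.2)},
    )
    sample, truth = gen_fish(spec, mode="volume")
    return sample, truth, spec
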