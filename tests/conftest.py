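"""Shared fixtures: toy problems and session-scoped simulation-study runs."""

import numpy as np
import pytest
from shapely.geometry import box

from gridvax.geometry import (
    AreaPartition,
    ArealCounts,
    CovariateStack,
    assign_membership,
    build_grid,
    build_unit_square_partition,
    median_pairwise_distance,
)
from gridvax.model import PriorSpec


@pytest.fixture(scope="session")
def unit_grid_60():
    grid = build_grid(60, 60, (0, 0, 1, 1))
    return grid


@pytest.fixture(scope="session")
def partition_3x3():
    return build_unit_square_partition(3)


@pytest.fixture(scope="session")
def strip_toy():
    """Three vertical strip areas over a 10x10 grid with one noise covariate.

    Small enough for the MCMC engine; areas have distinct true coverage
    levels (0.35 / 0.55 / 0.70).
    """
    polys = [box(i / 3, 0, (i + 1) / 3, 1) for i in range(3)]
    W = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], float)
    part = AreaPartition(area_ids=["a", "b", "c"], polygons=polys, W=W)
    grid = build_grid(10, 10, (0, 0, 1, 1))
    mem = assign_membership(grid, part)
    rng = np.random.default_rng(7)
    Xg = np.column_stack([np.ones(100), rng.standard_normal(100)])
    Xa = np.column_stack([np.ones(3), rng.standard_normal(3)])
    cov = CovariateStack(Xg, Xa, ["intercept", "x1"])
    counts = ArealCounts(Y=np.array([70.0, 138.0, 105.0]), N=np.array([200.0, 250.0, 150.0]))
    priors = PriorSpec().with_median_distance(median_pairwise_distance(grid, seed=0))
    return {
        "partition": part,
        "grid": grid,
        "membership": mem,
        "cov": cov,
        "counts": counts,
        "priors": priors,
    }


def _run_setting_study(r, n_side, replicates, seed):
    from gridvax.simulation import SimSetting, run_study

    settings = [SimSetting(r=r, n_side=n_side, replicates=replicates, seed=seed)]
    return run_study(settings, engine="laplace", seed=seed)


@pytest.fixture(scope="session")
def study_worst_setting():
    """25-replicate study in the least favourable design cell (r=0.3, nA=9)."""
    return _run_setting_study(r=0.3, n_side=3, replicates=25, seed=20240901)


@pytest.fixture(scope="session")
def study_best_setting():
    """25-replicate study in the most favourable design cell (r=0.7, nA=100)."""
    return _run_setting_study(r=0.7, n_side=10, replicates=25, seed=20240901)


@pytest.fixture(scope="session")
def study_full_design():
    """Reduced-replicate run of the full 3x3 design for trend checks."""
    from gridvax.simulation import SimSetting, run_study

    settings = [
        SimSetting(r=r, n_side=ns, replicates=6, seed=20240902)
        for r in (0.3, 0.5, 0.7)
        for ns in (3, 5, 10)
    ]
    return run_study(settings, engine="laplace", seed=20240902)
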