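"""Shared fixtures: synthetic sessions and analysis contexts.

All fixtures are deterministic; the expensive ~30-minute trajectory session
is built once per test run.
"""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import pfls
from pfls.core import AnalysisConfig
from pfls.information import SessionContext

settings.register_profile(
    "default", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def cfg():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def maze():
    return pfls.build_maze(100.0, 100.0)


@pytest.fixture(scope="session")
def long_session():
    """~30 min trajectory with a single background unit (shared substrate)."""
    spec = pfls.default_session_spec("long")
    spec.place_cells = []
    spec.kinematic_units = []
    spec.coupled_pairs = []
    spec.poisson_units = [("bg0", "HPC", 1.0)]
    spec.n_trials = 83
    session, _ = pfls.generate_session(spec, seed=7)
    return session


@pytest.fixture(scope="session")
def long_ctx(long_session, cfg):
    return SessionContext(long_session, cfg)


@pytest.fixture(scope="session")
def small_session():
    """A compact mixed HPC/LS session for pipeline-level tests."""
    spec = pfls.default_session_spec("small")
    spec.n_trials = 20
    spec.place_cells = spec.place_cells[:6] + spec.place_cells[12:16]
    spec.poisson_units = spec.poisson_units[:6]
    spec.kinematic_units = spec.kinematic_units[:2]
    spec.coupled_pairs = spec.coupled_pairs[:2]
    session, truth = pfls.generate_session(spec, seed=3)
    return session


def make_grid(nx=1, ny=1, bin_size=1.0, x0=0.0, y0=0.0):
    from pfls.kinematics import MapGrid
    return MapGrid(bin_size=bin_size, x0=x0, y0=y0, nx=nx, ny=ny)


def make_maps(P, R, bin_size=1.0, total_time=100.0, mean_rate=None):
    """Hand-built 1-row occupancy and rate maps for analytic information tests."""
    from pfls.kinematics import OccupancyMap, RateMap
    P = np.asarray(P, dtype=float)[:, None]
    R = np.asarray(R, dtype=float)[:, None]
    grid = make_grid(nx=P.shape[0], ny=1, bin_size=bin_size)
    visited = P > 0
    occ = OccupancyMap(grid=grid, dwell=P * total_time, P=P, visited=visited,
                       total_time=total_time)
    if mean_rate is None:
        mean_rate = float((P[visited] * R[visited]).sum())
    rm = RateMap(grid=grid, rate=R, rate_raw=R, visited=visited,
                 mean_rate=mean_rate, smooth_sd=0.0, unit_id="manual")
    return occ, rm
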