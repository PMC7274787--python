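"""Field detection, skew, FRAI, directionality, lap stability, regression."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from pfls.fields import (FieldError, FieldTraversal, classify_directionality,
                         detect_fields, field_center, field_frai,
                         frai_single, lap_stability, speed_accel_regression,
                         traversal_half_rates, weighted_skew)
from pfls.kinematics import MapGrid, RateMap
from pfls.synth import FieldSpec, planted_rate_map


def stem_rate_map(values_by_bin, maze, bin_size=2.0, n_bins=150, peak_row=1):
    """1-row synthetic rate map laid along the stem (u = 100 + x)."""
    nx = n_bins
    grid = MapGrid(bin_size=bin_size, x0=-100.0, y0=0.0, nx=nx, ny=1)
    rate = np.zeros((nx, 1))
    for i, v in values_by_bin.items():
        rate[i, 0] = v
    visited = np.ones((nx, 1), dtype=bool)
    return RateMap(grid=grid, rate=rate, rate_raw=rate, visited=visited,
                   mean_rate=1.0, smooth_sd=0.0, unit_id="manual")


def test_flat_map_has_no_fields(maze, cfg):
    rm = stem_rate_map({}, maze)
    rm.rate += 1.0
    rm.rate_raw += 1.0
    assert detect_fields(rm, maze, cfg) == []


def test_minimum_length_boundary(maze, cfg):
    """A 14 cm suprathreshold region is rejected; 16 cm is kept."""
    bump7 = {60 + i: 10.0 for i in range(7)}    # 7 bins x 2 cm = 14 cm
    rm = stem_rate_map(bump7, maze)
    assert detect_fields(rm, maze, cfg) == []
    bump8 = {60 + i: 10.0 for i in range(8)}    # 16 cm
    fields = detect_fields(rm := stem_rate_map(bump8, maze), maze, cfg)
    assert len(fields) == 1
    assert fields[0].length == pytest.approx(16.0)


def test_low_rate_unit_excluded(maze, cfg):
    rm = stem_rate_map({60 + i: 0.04 for i in range(10)}, maze)
    assert detect_fields(rm, maze, cfg) == []


def test_wrong_bin_size_rejected(maze, cfg):
    grid = MapGrid(bin_size=1.0, x0=0.0, y0=0.0, nx=10, ny=1)
    rm = RateMap(grid=grid, rate=np.ones((10, 1)), rate_raw=np.ones((10, 1)),
                 visited=np.ones((10, 1), bool), mean_rate=1.0, smooth_sd=0.0)
    with pytest.raises(FieldError):
        detect_fields(rm, maze, cfg)


def test_center_is_argmax_with_tie_rule(maze, cfg):
    vals = {60 + i: 10.0 for i in range(10)}
    vals[64] = 20.0
    rm = stem_rate_map(vals, maze)
    f = detect_fields(rm, maze, cfg)[0]
    assert f.center_bin == (64, 0)
    assert field_center(f, rm) == f.center_xy
    # two equal maxima -> lowest linearized coordinate wins
    vals[68] = 20.0
    f2 = detect_fields(stem_rate_map(vals, maze), maze, cfg)[0]
    assert f2.center_bin == (64, 0)


def test_noiseless_planted_field_recovered_exactly(long_ctx, maze, cfg):
    spec = FieldSpec(center=150.0, width_sd=8.0, peak_rate=6.0,
                     baseline_rate=0.1)
    rm = planted_rate_map(spec, long_ctx.field_occ, maze, cfg.map_smooth_sd)
    fields = detect_fields(rm, maze, cfg)
    assert len(fields) == 1
    assert abs(fields[0].center_u - 150.0) <= cfg.field_bin


def test_weighted_skew_oracle_and_symmetries():
    # independent moment computation, frozen: profile [1,2,4,8] at x=1..4
    x = np.array([1.0, 2.0, 3.0, 4.0])
    w = np.array([1.0, 2.0, 4.0, 8.0])
    W = w.sum()
    mu = (w * x).sum() / W
    m2 = (w * (x - mu) ** 2).sum() / W
    m3 = (w * (x - mu) ** 3).sum() / W
    oracle = m3 / m2 ** 1.5
    assert weighted_skew(x, w) == pytest.approx(oracle, abs=1e-12)
    assert weighted_skew(x, w) == pytest.approx(-1.0517716942224802, abs=1e-9)
    # symmetric profile -> 0; mirrored profile -> sign flip
    assert weighted_skew(np.arange(5.0), [1, 2, 5, 2, 1]) == \
        pytest.approx(0.0, abs=1e-12)
    assert weighted_skew(-x, w) == pytest.approx(-oracle, abs=1e-12)
    # zero variance -> undefined
    assert np.isnan(weighted_skew([1.0], [2.0]))


@given(st.lists(st.floats(0.01, 100.0), min_size=3, max_size=20),
       st.floats(0.5, 5.0))
def test_skew_invariant_to_weight_scaling(w, c):
    x = np.arange(len(w), dtype=float)
    s1 = weighted_skew(x, np.array(w))
    s2 = weighted_skew(x, c * np.array(w))
    if np.isfinite(s1):
        assert s2 == pytest.approx(s1, rel=1e-9, abs=1e-9)


def test_frai_formula_and_single_traversal():
    assert frai_single(2.0, 1.0) == pytest.approx(1 / 3)
    assert frai_single(1.0, 1.0) == 0.0
    # constructed traversal with F1 = 2 Hz, F2 = 1 Hz
    t = FieldTraversal(lap=0, entry=0.0, exit=3.0,
                       spike_times=np.array([0.3, 0.8, 1.2, 2.9]),
                       direction="toward_reward")
    f1, f2 = traversal_half_rates(t)
    assert (f1, f2) == (pytest.approx(2.0), pytest.approx(1.0))
    assert field_frai([t]) == pytest.approx(1 / 3)


def test_frai_zero_for_constant_rate_and_bounded():
    rng = np.random.default_rng(4)
    vals = []
    for k in range(200):
        n = rng.integers(2, 40)
        sp = np.sort(rng.uniform(0.05, 2.95, n))
        t = FieldTraversal(lap=k, entry=0.0, exit=3.0, spike_times=sp,
                           direction="both")
        r = traversal_half_rates(t)
        if r is not None:
            vals.append(frai_single(*r))
    vals = np.array(vals)
    assert np.all((vals >= -1) & (vals <= 1))
    assert abs(vals.mean()) < 0.1   # uniform spiking is symmetric on average
    # fewer than 2 spikes -> no contribution
    t1 = FieldTraversal(lap=0, entry=0.0, exit=1.0,
                        spike_times=np.array([0.5]), direction="both")
    assert np.isnan(field_frai([t1]))


class _F:
    def __init__(self, u, unit="u", direction="toward_reward"):
        self.center_u = u
        self.arm_label = "stem"
        self.unit_id = unit
        self.direction = direction
        self.bidirectional = False


def test_directionality_merge_boundary(maze):
    ft, fa = [_F(150.0)], [_F(169.0, direction="away_from_reward")]
    out = classify_directionality(ft, fa, maze, 20.0)
    assert all(f.bidirectional for f in out)
    ft, fa = [_F(150.0)], [_F(170.0, direction="away_from_reward")]
    out = classify_directionality(ft, fa, maze, 20.0)
    assert not any(f.bidirectional for f in out)
    out = classify_directionality([_F(150.0)], [], maze, 20.0)
    assert len(out) == 1 and not out[0].bidirectional


def test_lap_stability_identical_laps_and_exclusion(long_session, maze):
    f = _F(150.0)
    f.bins = np.zeros((1, 2), dtype=int)
    travs = []
    for k in range(20):
        travs.append(FieldTraversal(
            lap=k, entry=10.0 * k, exit=10.0 * k + 2.0,
            spike_times=10.0 * k + np.array([0.5, 1.0, 1.5]),
            direction="toward_reward"))
    # identical spiking positions every lap -> all distances 0
    pos = long_session.positions

    class SessStub:
        positions = pos
    d = lap_stability(f, travs, long_session, maze, 2.0, 15)
    # spikes interpolate to whatever position; all laps share relative times,
    # so just assert the qualifying length and nonnegativity here
    assert d is not None and len(d) == 20 and np.all(d >= 0)
    assert lap_stability(f, travs[:14], long_session, maze, 2.0, 15) is None


def test_speed_accel_regression_cases():
    rng = np.random.default_rng(3)
    grid = MapGrid(bin_size=2.0, x0=0.0, y0=0.0, nx=10, ny=10)
    speed = rng.uniform(10, 40, (10, 10))
    accel = rng.normal(0, 5, (10, 10))
    vis = np.ones((10, 10), bool)
    rate = 2.0 * speed
    rm = RateMap(grid=grid, rate=rate, rate_raw=rate, visited=vis,
                 mean_rate=1.0, smooth_sd=0.0)
    assert speed_accel_regression(rm, speed, accel) == pytest.approx(1.0)
    # rate independent of kinematics -> small r^2 (median over seeds)
    r2s = []
    for s in range(9):
        rng2 = np.random.default_rng(100 + s)
        rate2 = rng2.exponential(2.0, (10, 10))
        rm2 = RateMap(grid=grid, rate=rate2, rate_raw=rate2, visited=vis,
                      mean_rate=1.0, smooth_sd=0.0)
        r2s.append(speed_accel_regression(rm2, speed, accel))
    assert np.median(r2s) < 0.1
    # closed-form normal-equation oracle
    y = rate.ravel()
    X = np.column_stack([np.ones(y.size), speed.ravel(), accel.ravel()])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    r2_oracle = 1 - resid.var() / y.var()
    assert speed_accel_regression(rm, speed, accel) == \
        pytest.approx(r2_oracle, abs=1e-9)
    with pytest.raises(FieldError):
        small = RateMap(grid=MapGrid(2.0, 0, 0, 3, 1),
                        rate=np.ones((3, 1)), rate_raw=np.ones((3, 1)),
                        visited=np.ones((3, 1), bool), mean_rate=1.0,
                        smooth_sd=0.0)
        speed_accel_regression(small, np.ones((3, 1)), np.ones((3, 1)))


def test_direction_gated_cell_detected_one_way(long_session, long_ctx, maze,
                                               cfg):
    from pfls.fields import split_by_direction
    from pfls.synth import generate_place_cell
    spec = FieldSpec(center=150.0, width_sd=8.0, peak_rate=8.0,
                     baseline_rate=0.1, direction="toward_reward")
    tr = generate_place_cell(spec, long_session.positions, maze, seed=13,
                             events=long_session.events)
    (occ_t, rm_t), (occ_a, rm_a) = split_by_direction(
        long_session, tr.spike_times, long_ctx, "gated")
    f_t = detect_fields(rm_t, maze, cfg, "toward_reward")
    f_a = detect_fields(rm_a, maze, cfg, "away_from_reward")
    assert len(f_t) == 1 and abs(f_t[0].center_u - 150.0) <= 5.0
    assert all(abs(f.center_u - 150.0) > 5.0 for f in f_a)


def test_ungated_cell_bidirectional(long_session, long_ctx, maze, cfg):
    from pfls.fields import split_by_direction
    from pfls.synth import generate_place_cell
    spec = FieldSpec(center=150.0, width_sd=8.0, peak_rate=8.0,
                     baseline_rate=0.1)
    tr = generate_place_cell(spec, long_session.positions, maze, seed=14,
                             events=long_session.events)
    (_, rm_t), (_, rm_a) = split_by_direction(
        long_session, tr.spike_times, long_ctx, "ungated")
    f_t = detect_fields(rm_t, maze, cfg, "toward_reward")
    f_a = detect_fields(rm_a, maze, cfg, "away_from_reward")
    d = maze.track_distance(f_t[0].center_u, f_t[0].arm_label,
                            f_a[0].center_u, f_a[0].arm_label)
    assert d < 20.0
    merged = classify_directionality(f_t, f_a, maze, cfg.match_radius)
    assert all(f.bidirectional for f in merged)


def test_split_requires_reward_events(long_session, long_ctx):
    from pfls.core import Session
    from pfls.fields import split_by_direction
    bare = Session(session_id="no_events",
                   positions=long_session.positions, trains=[],
                   maze=long_session.maze, events=[])
    with pytest.raises(FieldError):
        split_by_direction(bare, np.array([1.0]), long_ctx)
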