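"""Synthetic generators: determinism, Poisson statistics, coupling wiring."""

import numpy as np
import pytest
from scipy import stats as sps

import pfls
from pfls.kinematics import compute_speed
from pfls.synth import (CouplingSpec, FieldSpec, GeneratorError,
                        generate_coupled_pair, generate_place_cell,
                        generate_poisson_unit, simulate_trajectory)


def test_field_spec_validation():
    with pytest.raises(GeneratorError):
        FieldSpec(center=10, width_sd=0, peak_rate=5)
    with pytest.raises(GeneratorError):
        FieldSpec(center=10, width_sd=5, peak_rate=1, baseline_rate=2)
    with pytest.raises(GeneratorError):
        CouplingSpec(transmission_prob=1.5)


def test_trajectory_determinism_and_dropout(maze):
    p1, e1 = simulate_trajectory(maze, 5, seed=4)
    p2, e2 = simulate_trajectory(maze, 5, seed=4)
    assert np.array_equal(p1.t, p2.t) and np.array_equal(p1.x, p2.x)
    assert [ev.time for ev in e1] == [ev.time for ev in e2]
    # dropout 0.5 of 30 Hz samples -> mean interval ~1/15 s
    assert np.mean(np.diff(p1.t)) == pytest.approx(1 / 15, rel=0.1)
    with pytest.raises(GeneratorError):
        simulate_trajectory(maze, 5, dropout_frac=1.0)
    with pytest.raises(GeneratorError):
        simulate_trajectory(maze, 0)


def test_trajectory_speed_closed_loop(maze):
    """Kinematics recovers the commanded running speed on run segments."""
    pos, events = simulate_trajectory(maze, 12, speed_mean=40.0,
                                      dropout_frac=0.0, seed=9, noise_px=0.0)
    kin = compute_speed(pos, smooth_sd=1.0)
    # mid-stem samples are far from pauses and turns
    mid = (np.abs(pos.x_cm - 50) < 25) & (np.abs(pos.y_cm) < 5)
    assert np.median(kin.speed[mid]) == pytest.approx(40.0, rel=0.15)


def test_forced_side_constraint(maze):
    _, events = simulate_trajectory(maze, 200, seed=2)
    sides = [e.side for e in events if e.kind == "trial_start"]
    runs, cur = [], 1
    for a, b in zip(sides, sides[1:]):
        cur = cur + 1 if a == b else 1
        runs.append(cur)
    assert max(runs) <= 3


def test_poisson_unit_count_and_isis():
    tr = generate_poisson_unit(5.0, 1800.0, seed=0)
    assert abs(len(tr) - 9000) < 3 * np.sqrt(9000)
    assert len(generate_poisson_unit(0.0, 100.0, seed=0)) == 0
    with pytest.raises(GeneratorError):
        generate_poisson_unit(-1.0, 10.0, seed=0)
    # ISIs exponential: KS p-values behave like a uniform sample over seeds
    ps = []
    for s in range(10):
        t = generate_poisson_unit(5.0, 1800.0, seed=100 + s).spike_times
        ps.append(sps.kstest(np.diff(t), "expon",
                             args=(0, 1 / 5.0)).pvalue)
    ps = np.array(ps)
    assert ps.min() > 1e-3
    assert sps.kstest(ps, "uniform").pvalue > 0.01


def test_place_cell_zero_rate_and_empty_trajectory(long_session, maze):
    pos = long_session.positions
    spec = FieldSpec(center=150, width_sd=8, peak_rate=1e-12,
                     baseline_rate=0.0)
    tr = generate_place_cell(spec, pos, maze, seed=0)
    assert len(tr) == 0
    import dataclasses
    empty = dataclasses.replace(pos, t=np.array([]), x=np.array([]),
                                y=np.array([]))
    with pytest.raises(GeneratorError):
        generate_place_cell(FieldSpec(center=150, width_sd=8, peak_rate=5),
                            empty, maze, seed=0)


def test_place_cell_spikes_concentrate_at_field(long_session, maze):
    pos, events = long_session.positions, long_session.events
    spec = FieldSpec(center=150.0, width_sd=8.0, peak_rate=8.0,
                     baseline_rate=0.0)
    tr = generate_place_cell(spec, pos, maze, seed=5, events=events)
    sx = np.interp(tr.spike_times, pos.t, pos.x_cm)
    sy = np.interp(tr.spike_times, pos.t, pos.y_cm)
    u, _, _ = maze.linearize(sx, sy)
    assert np.abs(np.median(u) - 150.0) < 5.0
    assert np.mean(np.abs(u - 150.0) < 25.0) > 0.9


def test_direction_gated_cell_fires_one_way(long_session, maze):
    from pfls.synth import direction_mask
    pos, events = long_session.positions, long_session.events
    spec = FieldSpec(center=150.0, width_sd=8.0, peak_rate=8.0,
                     baseline_rate=0.0, direction="toward_reward")
    tr = generate_place_cell(spec, pos, maze, seed=6, events=events)
    d = np.interp(tr.spike_times, pos.t,
                  direction_mask(pos.t, events).astype(float))
    assert len(tr) > 100
    assert np.all(d > 0)


def test_coupled_pair_exact_shift_and_independence(long_session, maze):
    pos, events = long_session.positions, long_session.events
    fs = FieldSpec(center=150.0, width_sd=8.0, peak_rate=6.0,
                   baseline_rate=0.1)
    # prob 1, jitter 0, background 0 -> LS is HPC shifted by the lag exactly
    cp = CouplingSpec(lag_ms=20.0, transmission_prob=1.0, jitter_sd_ms=0.0,
                      ls_background_rate=0.0)
    hpc, ls = generate_coupled_pair(fs, cp, pos, maze, seed=8, events=events)
    n = len(ls)
    np.testing.assert_allclose(ls.spike_times, hpc.spike_times[:n] + 0.020,
                               atol=1e-12)
    # prob 0 -> LS is pure background, independent of HPC
    cp0 = CouplingSpec(lag_ms=20.0, transmission_prob=0.0,
                       ls_background_rate=2.0)
    hpc0, ls0 = generate_coupled_pair(fs, cp0, pos, maze, seed=8,
                                      events=events)
    assert abs(len(ls0) - 2.0 * long_session.duration) < \
        4 * np.sqrt(2.0 * long_session.duration)


def test_generate_session_counts_and_determinism(tmp_path):
    spec = pfls.default_session_spec("det")
    spec.n_trials = 6
    s1, g1 = pfls.generate_session(spec, seed=12)
    s2, _ = pfls.generate_session(spec, seed=12)
    assert len(s1.trains) == len(spec.place_cells) + len(spec.poisson_units) \
        + len(spec.kinematic_units) + 2 * len(spec.coupled_pairs)
    pfls.write_session(s1, tmp_path / "a")
    pfls.write_session(s2, tmp_path / "b")
    for rel in ["manifest.json", "positions.csv"]:
        assert (tmp_path / "a" / rel).read_bytes() == \
            (tmp_path / "b" / rel).read_bytes()
    for tr in s1.trains:
        rel = f"spikes/{tr.unit_id}.csv"
        assert (tmp_path / "a" / rel).read_bytes() == \
            (tmp_path / "b" / rel).read_bytes()


def test_ground_truth_round_trip(tmp_path):
    from pfls.synth import SyntheticGroundTruth
    spec = pfls.default_session_spec("gt")
    truth = SyntheticGroundTruth(seed=5, spec=spec)
    truth.to_json(tmp_path / "gt.json")
    back = SyntheticGroundTruth.from_json(tmp_path / "gt.json")
    assert back.seed == 5
    assert back.spec == spec


def test_duplicate_unit_ids_rejected():
    spec = pfls.default_session_spec("dup")
    spec.poisson_units.append(spec.poisson_units[0])
    with pytest.raises(pfls.ValidationError):
        pfls.generate_session(spec, seed=0)
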