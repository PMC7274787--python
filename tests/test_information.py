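"""Spatial information: analytic values, identities, classification."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from conftest import make_maps
from pfls.core import SpikeTrain
from pfls.information import (InformationError, bits_per_second,
                              bits_per_spike, mutual_information,
                              score_unit, surrogate_population)


def test_analytic_bits_per_spike_values():
    occ, rm = make_maps([0.5, 0.5], [2.0, 0.0])   # mean rate 1 Hz
    assert bits_per_spike(rm, occ) == pytest.approx(1.0, abs=1e-12)
    assert bits_per_second(rm, occ) == pytest.approx(1.0, abs=1e-12)
    occ2, rm2 = make_maps([0.25, 0.75], [4.0, 0.0])
    assert bits_per_spike(rm2, occ2) == pytest.approx(2.0, abs=1e-12)
    occ3, rm3 = make_maps([0.3, 0.7], [3.0, 3.0])  # uniform map
    assert bits_per_spike(rm3, occ3) == pytest.approx(0.0, abs=1e-12)
    assert bits_per_second(rm3, occ3) == pytest.approx(0.0, abs=1e-12)


def test_single_bin_confinement_closed_form():
    """A cell confined to one bin of occupancy p carries log2(1/p) bits."""
    for p in (0.5, 0.25, 0.1, 0.01):
        occ, rm = make_maps([p, 1 - p], [1.0 / p, 0.0])  # mean rate 1
        assert bits_per_spike(rm, occ) == pytest.approx(np.log2(1 / p),
                                                        abs=1e-9)


def test_bits_identity_on_random_maps():
    rng = np.random.default_rng(11)
    for _ in range(200):
        n = rng.integers(2, 30)
        P = rng.dirichlet(np.ones(n))
        R = rng.exponential(3.0, n)
        occ, rm = make_maps(P, R)
        bps = bits_per_spike(rm, occ)
        assert bps >= -1e-12
        assert bits_per_second(rm, occ) == \
            pytest.approx(rm.mean_rate * bps, rel=1e-9, abs=1e-12)


@given(st.integers(0, 2 ** 31 - 1), st.floats(0.5, 20.0))
def test_rate_scaling_invariance(seed, c):
    rng = np.random.default_rng(seed)
    n = 12
    P = rng.dirichlet(np.ones(n))
    R = rng.exponential(2.0, n) + 1e-6
    occ, rm = make_maps(P, R)
    occ2, rm2 = make_maps(P, c * R)
    assert bits_per_spike(rm2, occ2) == \
        pytest.approx(bits_per_spike(rm, occ), rel=1e-9)


def test_zero_mean_rate_is_an_error():
    occ, rm = make_maps([0.5, 0.5], [0.0, 0.0])
    with pytest.raises(InformationError):
        bits_per_spike(rm, occ)


def test_mismatched_grids_rejected():
    occ, _ = make_maps([0.5, 0.5], [2.0, 0.0], bin_size=1.0)
    _, rm = make_maps([0.5, 0.5], [2.0, 0.0], bin_size=2.0)
    with pytest.raises(InformationError):
        bits_per_spike(rm, occ)


def _two_bin_fp(n=2000, dt=1 / 30):
    from pfls.kinematics import FilteredPositions
    t = np.arange(n) * dt
    x = np.where(np.arange(n) % 2 == 0, 0.5, 1.5)
    return FilteredPositions(t=t, x_cm=x, y_cm=np.full(n, 0.5),
                             dwell=np.full(n, dt),
                             speed=np.full(n, 20.0))


def test_mutual_information_deterministic_and_independent():
    from pfls.kinematics import occupancy_map
    fp = _two_bin_fp()
    occ = occupancy_map(fp, bin_size=1.0)
    # one spike in every window spent in bin A, none in bin B -> 1 bit
    spikes = fp.t[fp.x_cm < 1.0] + 0.001
    mi = mutual_information(fp, spikes, occ, count_window=1 / 30)
    assert mi == pytest.approx(1.0, abs=0.05)
    # spikes independent of position -> MI near 0
    rng = np.random.default_rng(0)
    sp = np.sort(rng.uniform(0, fp.t[-1], 500))
    mi0 = mutual_information(fp, sp, occ, count_window=1 / 30)
    assert 0 <= mi0 < 0.02


def test_classification_low_rate_exclusion(long_session, long_ctx):
    t0, t1 = long_session.bounds
    slow = SpikeTrain(unit_id="slow", region="LS",
                      spike_times=np.linspace(t0 + 1, t1 - 1, 40))
    r = score_unit(long_ctx, slow)
    assert r.excluded_reason == "low_rate"
    assert not r.passes_cutoff


def test_planted_cell_passes_homogeneous_fails(long_session, long_ctx, maze):
    from pfls.synth import FieldSpec, generate_place_cell, generate_poisson_unit
    pos, events = long_session.positions, long_session.events
    tr = generate_place_cell(
        FieldSpec(center=150.0, width_sd=6.0, peak_rate=8.0,
                  baseline_rate=0.1), pos, maze, seed=2, events=events,
        unit_id="pc")
    r = score_unit(long_ctx, tr)
    assert r.passes_cutoff and r.bits_per_spike >= 0.8
    t0, t1 = long_session.bounds
    fails = 0
    for s in range(20):
        h = generate_poisson_unit(5.0, t1 - t0, seed=300 + s, t_start=t0)
        rh = score_unit(long_ctx, h)
        fails += not rh.passes_cutoff
    assert fails >= 19


def test_surrogate_population_determinism_and_zero_rates(long_session,
                                                         long_ctx, cfg):
    r1 = surrogate_population(long_session, 5, [1.0, 2.0], 42, cfg, long_ctx)
    r2 = surrogate_population(long_session, 5, [1.0, 2.0], 42, cfg, long_ctx)
    assert [x.bits_per_spike for x in r1] == [x.bits_per_spike for x in r2]
    z = surrogate_population(long_session, 3, [0.0], 42, cfg, long_ctx)
    assert all(x.excluded_reason == "low_rate" for x in z)
    with pytest.raises(ValueError):
        surrogate_population(long_session, 3, [], 42, cfg, long_ctx)


def test_surrogates_below_real_place_cells(long_session, long_ctx, maze, cfg):
    """Surrogate bits/spike sit stochastically below planted place cells."""
    from scipy import stats as sps
    from pfls.synth import FieldSpec, generate_place_cell
    pos, events = long_session.positions, long_session.events
    real = []
    rng = np.random.default_rng(21)
    for i in range(15):
        c = rng.uniform(120, 180)
        tr = generate_place_cell(
            FieldSpec(center=float(c), width_sd=8.0, peak_rate=6.0,
                      baseline_rate=0.1), pos, maze, seed=400 + i,
            events=events, unit_id=f"pc{i}")
        real.append(score_unit(long_ctx, tr).bits_per_spike)
    rates = [0.5 + 0.2 * i for i in range(15)]
    sur = surrogate_population(long_session, 15, rates, 77, cfg, long_ctx)
    sur_bits = [x.bits_per_spike for x in sur]
    r = sps.ks_2samp(real, sur_bits, alternative="less")
    assert np.mean(real) > np.mean(sur_bits)
    assert sps.ks_2samp(real, sur_bits).pvalue < 0.01


def test_homogeneous_bits_shrink_with_duration(long_session, cfg, maze):
    """Plug-in bits/spike of a homogeneous unit decays as data accumulate."""
    from dataclasses import replace as dreplace
    from pfls.core import Session
    from pfls.information import SessionContext
    from pfls.synth import generate_poisson_unit
    pos = long_session.positions
    t0 = pos.t[0]
    bits = []
    for dur in (240.0, 1800.0):
        m = pos.t <= t0 + dur
        sub_pos = dreplace(pos, t=pos.t[m], x=pos.x[m], y=pos.y[m])
        ev = [e for e in long_session.events if e.time <= t0 + dur]
        sub = Session(session_id="sub", positions=sub_pos, trains=[],
                      maze=long_session.maze, events=ev)
        ctx = SessionContext(sub, cfg)
        tr = generate_poisson_unit(3.0, dur, seed=9, t_start=t0)
        rm = ctx.unit_rate_map(tr.spike_times, "info", "h")
        bits.append(bits_per_spike(rm, ctx.info_occ))
    assert bits[1] < bits[0]
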