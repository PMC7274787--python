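"""Synthetic T-maze sessions with known ground truth.

Emulates the structure of a tetrode session on a double-sided T maze:
a ~30 Hz overhead-camera trajectory running forced-arm -> stem -> choice-arm
loops with reward-site pauses and occlusion dropouts; place cells as
inhomogeneous Poisson processes with configurable center, width, peak,
skew and travel-direction gating; speed/acceleration-modulated non-place
cells; homogeneous Poisson surrogates; and HPC->LS coupled pairs with a
configurable transmission lag.  Every generator is deterministic under its
seed, and the planted parameters are serialized next to the session so the
analysis stages can be scored against ground truth.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np
from scipy.stats import norm

from .core import (PositionSeries, Session, SpikeTrain, TrialEvent,
                   ValidationError, as_seedseq)
from .geometry import MazeGeometry, build_maze


class GeneratorError(ValueError):
    """Invalid generator parameter."""


# ----------------------------------------------------------------------
# Specs (the planted ground truth)
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class FieldSpec:
    """A planted place field on the linearized track.

    ``center`` is the run coordinate (cm) of the firing-rate mode,
    ``width_sd`` the Gaussian scale of the bump, ``skew_shape`` the
    skew-normal shape parameter (0 = symmetric; positive shifts rate mass
    toward larger run coordinates, i.e. toward reward).  ``direction``
    restricts firing to travel toward/away from reward; ``side`` restricts
    firing to one lateral arm (fields at stem coordinates ignore it).
    """

    center: float
    width_sd: float
    peak_rate: float
    baseline_rate: float = 0.0
    skew_shape: float = 0.0
    direction: str = "both"        # toward_reward | away_from_reward | both
    side: Optional[str] = None     # left | right | None (both sides)

    def __post_init__(self):
        if self.width_sd <= 0:
            raise GeneratorError("width_sd must be positive")
        if not (self.peak_rate > self.baseline_rate >= 0):
            raise GeneratorError("need peak_rate > baseline_rate >= 0")
        if self.direction not in ("toward_reward", "away_from_reward", "both"):
            raise GeneratorError(f"unknown direction {self.direction!r}")


@dataclass(frozen=True)
class CouplingSpec:
    """HPC->LS spike transmission: lag, reliability, jitter, LS background."""

    lag_ms: float = 20.0
    transmission_prob: float = 0.3
    jitter_sd_ms: float = 2.0
    ls_background_rate: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.transmission_prob <= 1.0:
            raise GeneratorError("transmission_prob must be in [0, 1]")
        if self.jitter_sd_ms < 0:
            raise GeneratorError("jitter_sd_ms must be nonnegative")


@dataclass
class SessionSpec:
    """Full recipe for a synthetic session.

    The defaults describe the emulated study conditions: a ~30-minute
    session of forced->stem->choice loops on a maze with 100 cm arms and a
    100 cm stem, mean running speed 40 cm/s with reward pauses, tracking at
    30 Hz with half the samples dropped by occlusion.
    """

    session_id: str = "synthetic"
    arm_length: float = 100.0
    stem_length: float = 100.0
    n_trials: int = 60
    speed_mean: float = 40.0       # cm/s
    pause_s: float = 4.0           # reward-site pause
    forced_pause_s: float = 2.0    # forced-arm-end pause before departure
    dropout_frac: float = 0.5
    px_per_cm: float = 3.5
    noise_px: float = 1.0
    # unit recipes: (unit_id, region, spec-or-rate...)
    place_cells: list = field(default_factory=list)       # (id, region, FieldSpec)
    poisson_units: list = field(default_factory=list)     # (id, region, rate_hz)
    kinematic_units: list = field(default_factory=list)   # (id, region, base, g_speed, g_accel)
    coupled_pairs: list = field(default_factory=list)     # (hpc_id, ls_id, FieldSpec, CouplingSpec)


@dataclass
class SyntheticGroundTruth:
    """Planted parameters of a generated session, serializable to JSON."""

    seed: int
    spec: SessionSpec

    def field_specs(self) -> dict:
        out = {uid: fs for uid, _, fs in self.spec.place_cells}
        for hpc_id, ls_id, fs, _ in self.spec.coupled_pairs:
            out[hpc_id] = fs
        return out

    def to_json(self, path):
        def enc(o):
            if isinstance(o, (FieldSpec, CouplingSpec)):
                return asdict(o)
            raise TypeError(type(o))
        with open(path, "w") as fh:
            json.dump({"seed": self.seed, "spec": asdict(self.spec)}, fh,
                      indent=1, sort_keys=True, default=enc)
            fh.write("\n")

    @classmethod
    def from_json(cls, path):
        with open(path) as fh:
            d = json.load(fh)
        sp = d["spec"]
        sp["place_cells"] = [(u, r, FieldSpec(**f)) for u, r, f in sp["place_cells"]]
        sp["coupled_pairs"] = [(h, l, FieldSpec(**f), CouplingSpec(**c))
                               for h, l, f, c in sp["coupled_pairs"]]
        sp["poisson_units"] = [tuple(x) for x in sp["poisson_units"]]
        sp["kinematic_units"] = [tuple(x) for x in sp["kinematic_units"]]
        return cls(seed=d["seed"], spec=SessionSpec(**sp))


# ----------------------------------------------------------------------
# Trajectory
# ----------------------------------------------------------------------

def _forced_sides(n_trials: int, rng) -> list:
    """Uniform random sides, never more than three consecutive repeats."""
    sides = []
    for _ in range(n_trials):
        s = "left" if rng.random() < 0.5 else "right"
        if len(sides) >= 3 and sides[-1] == sides[-2] == sides[-3] == s:
            s = "left" if s == "right" else "right"
        sides.append(s)
    return sides


def simulate_trajectory(maze: MazeGeometry, n_trials: int,
                        speed_mean: float = 40.0, pause_s: float = 4.0,
                        dropout_frac: float = 0.5, seed: int = 0,
                        forced_pause_s: float = 2.0, px_per_cm: float = 3.5,
                        noise_px: float = 1.0, rate_hz: float = 30.0):
    """Simulate a camera-tracked trajectory of forced->choice trials.

    Each trial: pause at the forced-arm end, run forced arm -> stem ->
    choice arm (correct side), pause at the reward site, then return to the
    next trial's forced arm.  Per-leg speeds are truncated normal (mean
    ``speed_mean``, SD 20%, floor 1 cm/s); reward/forced-end pauses exercise
    the running-speed filter.  A ``dropout_frac`` fraction of samples is
    deleted uniformly at random to emulate occlusion.

    Returns ``(PositionSeries, events)`` with ``trial_start`` (departure from
    the forced-arm end) and ``reward`` (arrival at the reward site) events.
    """
    if n_trials < 1:
        raise GeneratorError("n_trials must be >= 1")
    if not 0.0 <= dropout_frac < 1.0:
        raise GeneratorError("dropout_frac must be in [0, 1)")
    rng = np.random.default_rng(seed)
    a, s = maze.arm_length, maze.stem_length
    dt = 1.0 / rate_hz

    def pt(arm, side):
        if arm == "forced_end":
            return np.array([0.0, a if side == "left" else -a])
        if arm == "forced_junction":
            return np.array([0.0, 0.0])
        if arm == "choice_junction":
            return np.array([s, 0.0])
        return np.array([s, a if side == "left" else -a])  # reward site

    sides = _forced_sides(n_trials, rng)
    xs, ys, n_samples = [], [], 0
    t_now = 0.0
    events = []

    def leg(p0, p1):
        nonlocal t_now
        v = max(1.0, rng.normal(speed_mean, 0.2 * speed_mean))
        dur = float(np.hypot(*(p1 - p0))) / v
        n = max(1, int(round(dur / dt)))
        frac = (np.arange(1, n + 1)) / n
        pts = p0 + frac[:, None] * (p1 - p0)
        xs.append(pts[:, 0]); ys.append(pts[:, 1])
        t_now += n * dt

    def pause(p, duration):
        nonlocal t_now
        n = max(1, int(round(duration / dt)))
        xs.append(np.full(n, p[0])); ys.append(np.full(n, p[1]))
        t_now += n * dt

    # session opens at the first forced-arm end
    pause(pt("forced_end", sides[0]), forced_pause_s)
    for k, side in enumerate(sides):
        events.append(TrialEvent("trial_start", t_now, side, True))
        leg(pt("forced_end", side), pt("forced_junction", side))
        leg(pt("forced_junction", side), pt("choice_junction", side))
        leg(pt("choice_junction", side), pt("reward", side))
        events.append(TrialEvent("reward", t_now, side, True))
        pause(pt("reward", side), pause_s)
        nxt = sides[k + 1] if k + 1 < n_trials else side
        leg(pt("reward", side), pt("choice_junction", side))
        leg(pt("choice_junction", side), pt("forced_junction", side))
        leg(pt("forced_junction", side), pt("forced_end", nxt))
        pause(pt("forced_end", nxt), forced_pause_s)

    x = np.concatenate(xs); y = np.concatenate(ys)
    t = dt * np.arange(1, len(x) + 1)
    keep = rng.random(len(t)) >= dropout_frac
    keep[0] = keep[-1] = True
    t, x, y = t[keep], x[keep], y[keep]
    x_px = x * px_per_cm + rng.normal(0.0, noise_px, len(x))
    y_px = y * px_per_cm + rng.normal(0.0, noise_px, len(y))
    pos = PositionSeries(t=t, x=x_px, y=y_px, px_per_cm=px_per_cm,
                         nominal_rate=rate_hz)
    return pos, events


def direction_mask(t: np.ndarray, events) -> np.ndarray:
    """Per-time travel phase: +1 toward reward, -1 away, 0 unlabeled.

    Toward = [trial_start, reward); away = [reward, next trial_start).
    """
    out = np.zeros(len(t), dtype=int)
    starts = [e.time for e in events if e.kind == "trial_start"]
    rewards = [e.time for e in events if e.kind == "reward"]
    for k, (ts, tr) in enumerate(zip(starts, rewards)):
        out[(t >= ts) & (t < tr)] = 1
        t_end = starts[k + 1] if k + 1 < len(starts) else np.inf
        out[(t >= tr) & (t < t_end)] = -1
    return out


# ----------------------------------------------------------------------
# Spike generators
# ----------------------------------------------------------------------

def _skew_bump(u: np.ndarray, spec: FieldSpec) -> np.ndarray:
    """Unit-peak skew-normal-shaped bump with its mode at ``spec.center``.

    The profile is exp(-z^2/2) * Phi(alpha*z) rescaled so its maximum is 1
    and shifted so the maximum sits at the nominal center, making the
    planted center directly comparable with the detected (argmax) center.
    """
    alpha = spec.skew_shape
    z_grid = np.linspace(-5, 5, 4001)
    prof = np.exp(-z_grid ** 2 / 2) * norm.cdf(alpha * z_grid)
    i = np.argmax(prof)
    z_mode, peak = z_grid[i], prof[i]
    z = (u - spec.center) / spec.width_sd + z_mode
    return np.exp(-z ** 2 / 2) * norm.cdf(alpha * z) / peak


def field_rate_on_samples(spec: FieldSpec, pos: PositionSeries,
                          maze: MazeGeometry, events=None) -> np.ndarray:
    """Planted rate lambda(t) evaluated at every position sample."""
    if len(pos) == 0:
        raise GeneratorError("empty trajectory")
    u, labels, _ = maze.linearize(pos.x_cm, pos.y_cm)
    lam = spec.baseline_rate + (spec.peak_rate - spec.baseline_rate) * \
        _skew_bump(u, spec)
    if spec.side is not None:
        other = "right" if spec.side == "left" else "left"
        on_other = np.array([lab.endswith(other) for lab in labels])
        lam = np.where(on_other, spec.baseline_rate, lam)
    if spec.direction != "both":
        if events is None:
            raise GeneratorError("direction-gated field needs trial events")
        want = 1 if spec.direction == "toward_reward" else -1
        gate = direction_mask(pos.t, events) == want
        lam = np.where(gate, lam, spec.baseline_rate)
    return lam


def _thin_poisson(t: np.ndarray, lam: np.ndarray, rng) -> np.ndarray:
    """Inhomogeneous Poisson spikes by thinning a homogeneous bound process.

    The candidate rate is the maximum of the (piecewise-linear) rate signal;
    candidates are kept with probability lambda(t)/bound.
    """
    bound = float(np.max(lam))
    if bound <= 0:
        return np.array([])
    t0, t1 = t[0], t[-1]
    n = rng.poisson(bound * (t1 - t0))
    cand = np.sort(rng.uniform(t0, t1, n))
    lam_c = np.interp(cand, t, lam)
    return cand[rng.random(n) < lam_c / bound]


def generate_place_cell(spec: FieldSpec, pos: PositionSeries,
                        maze: MazeGeometry, seed, events=None,
                        unit_id: str = "place", region: str = "HPC") -> SpikeTrain:
    """Inhomogeneous-Poisson place cell on the simulated trajectory."""
    rng = np.random.default_rng(seed)
    lam = field_rate_on_samples(spec, pos, maze, events)
    spikes = _thin_poisson(pos.t, lam, rng)
    return SpikeTrain(unit_id=unit_id, region=region, spike_times=spikes)


def generate_poisson_unit(mean_rate: float, duration: float, seed,
                          t_start: float = 0.0, unit_id: str = "poisson",
                          region: str = "LS") -> SpikeTrain:
    """Homogeneous Poisson train; expected count = rate * duration."""
    if mean_rate < 0:
        raise GeneratorError("mean_rate must be nonnegative")
    rng = np.random.default_rng(seed)
    n = rng.poisson(mean_rate * duration)
    spikes = np.sort(rng.uniform(t_start, t_start + duration, n))
    return SpikeTrain(unit_id=unit_id, region=region, spike_times=spikes)


def generate_kinematic_unit(base_rate: float, speed_gain: float,
                            accel_gain: float, pos: PositionSeries,
                            speed: np.ndarray, accel: np.ndarray, seed,
                            unit_id: str = "kin", region: str = "LS") -> SpikeTrain:
    """Non-place cell whose rate tracks running speed and acceleration.

    lambda(t) = max(0, base + g_speed * speed + g_accel * accel), in Hz with
    speed in cm/s and acceleration in cm/s^2.
    """
    rng = np.random.default_rng(seed)
    lam = np.maximum(0.0, base_rate + speed_gain * speed + accel_gain * accel)
    spikes = _thin_poisson(pos.t, lam, rng)
    return SpikeTrain(unit_id=unit_id, region=region, spike_times=spikes)


def generate_coupled_pair(hpc_spec: FieldSpec, coupling: CouplingSpec,
                          pos: PositionSeries, maze: MazeGeometry, seed,
                          events=None, hpc_id: str = "hpc", ls_id: str = "ls"):
    """HPC place cell plus an LS unit it drives with a transmission lag.

    The LS train is the union of a homogeneous background and, for each HPC
    spike kept with ``transmission_prob``, a transmitted spike at
    ``lag_ms`` (+ Gaussian jitter) later.  Spikes pushed outside the session
    are dropped.
    """
    ss = as_seedseq(seed).spawn(3)
    hpc = generate_place_cell(hpc_spec, pos, maze, ss[0], events,
                              unit_id=hpc_id, region="HPC")
    rng = np.random.default_rng(ss[1])
    t0, t1 = pos.t[0], pos.t[-1]
    bg = generate_poisson_unit(coupling.ls_background_rate, t1 - t0, ss[2],
                               t_start=t0).spike_times
    kept = hpc.spike_times[rng.random(len(hpc)) < coupling.transmission_prob]
    trans = kept + coupling.lag_ms / 1000.0 + \
        rng.normal(0.0, coupling.jitter_sd_ms / 1000.0, len(kept))
    ls_times = np.sort(np.concatenate([bg, trans]))
    ls_times = ls_times[(ls_times >= t0) & (ls_times <= t1)]
    ls = SpikeTrain(unit_id=ls_id, region="LS", spike_times=ls_times)
    return hpc, ls


# ----------------------------------------------------------------------
# Whole sessions
# ----------------------------------------------------------------------

def generate_session(spec: SessionSpec, seed: int):
    """Build a complete session plus its ground truth, deterministic in seed.

    Raises a validation error if a coupled pair reuses a unit id already
    defined elsewhere in the spec.
    """
    ids = [u for u, *_ in spec.place_cells] + \
          [u for u, *_ in spec.poisson_units] + \
          [u for u, *_ in spec.kinematic_units]
    for h, l, *_ in spec.coupled_pairs:
        ids.extend([h, l])
    if len(ids) != len(set(ids)):
        raise ValidationError("duplicate unit ids in session spec")

    root = np.random.SeedSequence(seed)
    ss = iter(root.spawn(1 + len(spec.place_cells) + len(spec.poisson_units)
                         + len(spec.kinematic_units) + len(spec.coupled_pairs)))
    maze = build_maze(spec.arm_length, spec.stem_length)
    pos, events = simulate_trajectory(
        maze, spec.n_trials, spec.speed_mean, spec.pause_s, spec.dropout_frac,
        next(ss), spec.forced_pause_s, spec.px_per_cm, spec.noise_px)
    t0, t1 = float(pos.t[0]), float(pos.t[-1])

    trains = []
    for uid, region, fs in spec.place_cells:
        trains.append(generate_place_cell(fs, pos, maze, next(ss), events,
                                          unit_id=uid, region=region))
    for uid, region, rate in spec.poisson_units:
        trains.append(generate_poisson_unit(rate, t1 - t0, next(ss), t_start=t0,
                                            unit_id=uid, region=region))
    if spec.kinematic_units:
        from .kinematics import compute_acceleration, compute_speed
        kin = compute_acceleration(compute_speed(pos))
        for uid, region, base, gs, ga in spec.kinematic_units:
            trains.append(generate_kinematic_unit(base, gs, ga, pos, kin.speed,
                                                  kin.accel, next(ss),
                                                  unit_id=uid, region=region))
    for hpc_id, ls_id, fs, cp in spec.coupled_pairs:
        hpc, ls = generate_coupled_pair(fs, cp, pos, maze, next(ss), events,
                                        hpc_id=hpc_id, ls_id=ls_id)
        trains.extend([hpc, ls])

    for tr in trains:
        tr.spike_times = tr.spike_times[(tr.spike_times >= t0) &
                                        (tr.spike_times <= t1)]
        tr.session_id = spec.session_id
    session = Session(session_id=spec.session_id, positions=pos, trains=trains,
                      maze=maze, events=events)
    return session, SyntheticGroundTruth(seed=seed, spec=spec)


def planted_rate_map(spec: FieldSpec, occ, maze: MazeGeometry,
                     smooth_sd: float, unit_id: str = "planted"):
    """Noise-free expected rate map of a planted field on a real occupancy.

    Evaluates the planted rate function at the visited bin centers of an
    occupancy map and applies the same mask-normalized smoothing as the
    estimated maps.  Running the field detector on this map gives the
    expected center and extent of the field under the detection rule,
    independent of spike sampling — the ground truth against which recovery
    from spiking data is scored.  Direction gating is ignored (the expected
    map pools both travel directions).
    """
    from .kinematics import RateMap, smooth_masked

    grid = occ.grid
    cx, cy = grid.bin_centers()
    gx, gy = np.meshgrid(cx, cy, indexing="ij")
    u, labels, _ = maze.linearize(gx.ravel(), gy.ravel())
    lam = spec.baseline_rate + (spec.peak_rate - spec.baseline_rate) * \
        _skew_bump(u, spec)
    if spec.side is not None:
        other = "right" if spec.side == "left" else "left"
        on_other = np.array([lab.endswith(other) for lab in labels])
        lam = np.where(on_other, spec.baseline_rate, lam)
    raw = lam.reshape(grid.nx, grid.ny)
    raw = np.where(occ.visited, raw, 0.0)
    sm = smooth_masked(raw, occ.visited, smooth_sd / grid.bin_size)
    mean_rate = float(np.sum(occ.P[occ.visited] * raw[occ.visited]))
    return RateMap(grid=grid, rate=sm, rate_raw=raw, visited=occ.visited,
                   mean_rate=mean_rate, smooth_sd=smooth_sd, unit_id=unit_id,
                   n_spikes=0)


def default_session_spec(session_id: str = "synthetic") -> SessionSpec:
    """A representative mixed HPC/LS session.

    HPC: 12 place cells spread over the track plus 4 non-spatial Poisson
    units.  LS: 8 place cells biased toward the choice side, 10 Poisson
    units at realistic LS rates, 4 speed/acceleration cells, and 4 HPC->LS
    coupled pairs (20 ms lag).  Field peaks 4-10 Hz, widths 6-12 cm SD.
    """
    place_hpc = []
    centers = [20, 45, 80, 115, 130, 150, 170, 185, 220, 250, 270, 285]
    for i, c in enumerate(centers):
        side = None if 110 <= c <= 190 else ("left" if i % 2 else "right")
        skew = [-1.5, 0.0, 1.5][i % 3]
        place_hpc.append((f"hpc_pc_{i:02d}", "HPC",
                          FieldSpec(center=float(c), width_sd=6.0 + (i % 4) * 2,
                                    peak_rate=4.0 + (i % 4) * 2,
                                    baseline_rate=0.1, skew_shape=skew,
                                    side=side)))
    place_ls = []
    ls_centers = [60, 140, 230, 245, 260, 270, 280, 290]
    for i, c in enumerate(ls_centers):
        side = None if 110 <= c <= 190 else ("left" if i % 2 else "right")
        place_ls.append((f"ls_pc_{i:02d}", "LS",
                         FieldSpec(center=float(c), width_sd=7.0 + (i % 3) * 2,
                                   peak_rate=4.0 + (i % 3) * 1.5,
                                   baseline_rate=0.2, skew_shape=(i % 3) - 1.0,
                                   side=side)))
    poisson = [(f"hpc_bg_{i}", "HPC", r) for i, r in enumerate([0.3, 1.0, 2.5, 5.0])]
    poisson += [(f"ls_bg_{i}", "LS", r)
                for i, r in enumerate([0.2, 0.5, 0.8, 1.5, 2.0, 3.0, 4.5, 6.0,
                                       8.0, 10.0])]
    kin_units = [(f"ls_kin_{i}", "LS", 0.5, g, ga)
                 for i, (g, ga) in enumerate([(0.08, 0.0), (0.15, 0.0),
                                              (0.05, 0.1), (0.0, 0.2)])]
    pairs = []
    for i, c in enumerate([235, 255, 275, 65]):
        side = "left" if i % 2 else "right"
        pairs.append((f"hpc_cp_{i}", f"ls_cp_{i}",
                      FieldSpec(center=float(c), width_sd=8.0, peak_rate=7.0,
                                baseline_rate=0.1, side=side),
                      CouplingSpec(lag_ms=20.0, transmission_prob=0.3,
                                   jitter_sd_ms=2.0, ls_background_rate=1.0)))
    return SessionSpec(session_id=session_id, place_cells=place_hpc + place_ls,
                       poisson_units=poisson, kinematic_units=kin_units,
                       coupled_pairs=pairs)
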