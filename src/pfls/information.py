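"""Spatial information: bits/spike, bits/second, mutual information, and the
Poisson surrogate control.

bits/spike is the classic per-spike spatial information

    I = sum_i P_i (R_i / Rbar) log2(R_i / Rbar)

with P_i the occupancy probability of bin i, R_i its mean firing rate and
Rbar the overall mean rate; bits/second drops the 1/Rbar factor and equals
Rbar * bits/spike identically.  Conventions: 0*log2(0) = 0 and bins with
P_i = 0 are excluded.  Units below a 0.05 Hz mean-rate floor during fast
running, or from trials without full track coverage, are excluded rather
than scored.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import AnalysisConfig, Session, SpikeTrain
from .kinematics import (FilteredPositions, MapError, OccupancyMap, RateMap,
                         check_track_coverage, compute_acceleration,
                         compute_speed, grid_from_positions, interp_position,
                         occupancy_map, rate_map, speed_filter)


class InformationError(ValueError):
    """Undefined information (zero mean rate or mismatched grids)."""


def _check_grids(rm: RateMap, occ: OccupancyMap):
    if rm.grid != occ.grid:
        raise InformationError("rate map and occupancy map use different grids")


def bits_per_spike(rm: RateMap, occ: OccupancyMap) -> float:
    """Per-spike spatial information in bits."""
    _check_grids(rm, occ)
    if rm.mean_rate <= 0:
        raise InformationError("mean rate is zero: bits/spike undefined")
    P = occ.P[occ.visited]
    R = rm.rate[occ.visited]
    ratio = R / rm.mean_rate
    ok = (P > 0) & (ratio > 0)
    return float(np.sum(P[ok] * ratio[ok] * np.log2(ratio[ok])))


def bits_per_second(rm: RateMap, occ: OccupancyMap) -> float:
    """Spatial information rate in bits/s; equals mean_rate * bits/spike."""
    _check_grids(rm, occ)
    if rm.mean_rate <= 0:
        raise InformationError("mean rate is zero: bits/second undefined")
    P = occ.P[occ.visited]
    R = rm.rate[occ.visited]
    ok = (P > 0) & (R > 0)
    return float(np.sum(P[ok] * R[ok] * np.log2(R[ok] / rm.mean_rate)))


def mutual_information(fp: FilteredPositions, spike_times: np.ndarray,
                       occ: OccupancyMap, count_window: Optional[float] = None,
                       k_max: int = 3) -> float:
    """Plug-in mutual information between windowed spike count and spatial bin.

    Each speed-filtered position sample contributes one observation: its
    spatial bin and the spike count in a ``count_window``-second window
    starting at the sample (default: one nominal inter-sample interval,
    1/30 s), clipped at ``k_max``.  This is a standard discretized estimator;
    treat its absolute scale as supplementary.
    """
    if len(fp.t) == 0:
        raise InformationError("no samples for mutual information")
    if count_window is None:
        count_window = 1.0 / 30.0
    spike_times = np.asarray(spike_times, dtype=float)
    k = np.searchsorted(spike_times, fp.t + count_window) - \
        np.searchsorted(spike_times, fp.t)
    k = np.clip(k, 0, k_max)
    ix, iy = occ.grid.bin_index(fp.x_cm, fp.y_cm)
    flat = ix * occ.grid.ny + iy
    _, inv = np.unique(flat, return_inverse=True)
    n_bins = inv.max() + 1
    joint = np.zeros((k_max + 1, n_bins))
    np.add.at(joint, (k, inv), 1.0)
    joint /= joint.sum()
    pk = joint.sum(axis=1, keepdims=True)
    pi = joint.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint * np.log2(joint / (pk * pi))
    return float(np.nansum(terms))


# ----------------------------------------------------------------------
# Per-unit classification
# ----------------------------------------------------------------------

@dataclass
class SpatialInfoResult:
    """Per-unit spatial information summary and cutoff classification."""

    unit_id: str
    region: str
    mean_rate: float
    bits_per_spike: float
    bits_per_second: float
    mutual_info: float
    passes_cutoff: bool
    excluded_reason: Optional[str] = None  # "low_rate" | "no_coverage" | None


class SessionContext:
    """Kinematics, filtered trajectory and occupancy shared across units.

    Computing these once per session keeps per-unit scoring cheap; the same
    context is reused by the surrogate-population control so surrogates run
    through the identical pipeline.
    """

    def __init__(self, session: Session, config: AnalysisConfig):
        self.session = session
        self.config = config
        self.kin = compute_acceleration(
            compute_speed(session.positions, config.speed_smooth_sd))
        self.fp, _ = speed_filter(session.positions, self.kin, None,
                                  config.speed_threshold)
        if len(self.fp.t) == 0:
            raise MapError("no samples at or above the speed threshold")
        self.coverage = check_track_coverage(self.fp, session.maze,
                                             config.field_bin)
        self.info_grid = grid_from_positions(session.positions, config.info_bin)
        self.field_grid = grid_from_positions(session.positions, config.field_bin)
        self.info_occ = occupancy_map(self.fp, config.info_bin, self.info_grid)
        self.field_occ = occupancy_map(self.fp, config.field_bin, self.field_grid)

    def filtered_spikes(self, spike_times: np.ndarray) -> np.ndarray:
        _, fs = speed_filter(self.session.positions, self.kin, spike_times,
                             self.config.speed_threshold)
        return fs

    def unit_rate_map(self, spike_times: np.ndarray, bin_size: str = "info",
                      unit_id: str = "") -> RateMap:
        occ = self.info_occ if bin_size == "info" else self.field_occ
        fs = self.filtered_spikes(spike_times)
        sx, sy = interp_position(self.session.positions, fs)
        return rate_map(fs, sx, sy, occ, self.config.map_smooth_sd, unit_id)


def score_unit(ctx: SessionContext, train: SpikeTrain) -> SpatialInfoResult:
    """Information measures and cutoff decision for one unit."""
    cfg = ctx.config
    fs = ctx.filtered_spikes(train.spike_times)
    mean_rate = len(fs) / ctx.fp.total_time
    if mean_rate < cfg.rate_floor:
        return SpatialInfoResult(train.unit_id, train.region, mean_rate,
                                 np.nan, np.nan, np.nan, False, "low_rate")
    if not ctx.coverage:
        return SpatialInfoResult(train.unit_id, train.region, mean_rate,
                                 np.nan, np.nan, np.nan, False, "no_coverage")
    rm = ctx.unit_rate_map(train.spike_times, "info", train.unit_id)
    bps = bits_per_spike(rm, ctx.info_occ)
    bpsec = bits_per_second(rm, ctx.info_occ)
    mi = mutual_information(ctx.fp, fs, ctx.info_occ, k_max=cfg.mi_kmax)
    return SpatialInfoResult(train.unit_id, train.region, mean_rate, bps,
                             bpsec, mi, bps >= cfg.bits_cutoff, None)


def classify_units(session: Session, config: Optional[AnalysisConfig] = None,
                   ctx: Optional[SessionContext] = None):
    """Score every unit in the session against the bits/spike cutoff."""
    config = config or AnalysisConfig()
    ctx = ctx or SessionContext(session, config)
    return [score_unit(ctx, tr) for tr in session.trains]


def surrogate_population(session: Session, n_units: int, rates,
                         seed: int, config: Optional[AnalysisConfig] = None,
                         ctx: Optional[SessionContext] = None):
    """Homogeneous-Poisson surrogate units scored by the identical pipeline.

    Rates are cycled from the supplied list (typically the recorded units'
    mean rates); each surrogate fires as a homogeneous Poisson process over
    the whole session timeline, then passes through the same speed filter,
    occupancy and information computation as real units.
    """
    if len(rates) == 0:
        raise ValueError("need at least one rate for the surrogate population")
    config = config or AnalysisConfig()
    ctx = ctx or SessionContext(session, config)
    rng = np.random.default_rng(seed)
    t0, t1 = session.bounds
    results = []
    for i in range(n_units):
        rate = float(rates[i % len(rates)])
        n = rng.poisson(rate * (t1 - t0))
        spikes = np.sort(rng.uniform(t0, t1, size=n))
        tr = SpikeTrain(unit_id=f"surrogate_{i:04d}", region="LS",
                        spike_times=spikes, session_id=session.session_id)
        results.append(score_unit(ctx, tr))
    return results
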