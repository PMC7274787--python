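"""Place-field detection and shape statistics.

A place field is a 4-connected region of 2 cm bins whose smoothed firing
rate is at least one SD above the unit's mean map rate, containing at least
one bin two SDs above it, with a linearized extent of at least 15 cm.  The
mean and SD are taken over the unit's smoothed rate-map values on visited
bins.  Field shape is summarized by the center (argmax bin), length
(linearized extent), skew of the width-averaged rate profile along the
direction of travel, and the firing-rate asymmetry index (FRAI) of in-field
spikes per traversal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np
from scipy.ndimage import label

from .core import AnalysisConfig, Session, ValidationError
from .geometry import MazeGeometry
from .information import SessionContext
from .kinematics import (RateMap, interp_position, occupancy_map, rate_map,
                         speed_filter)
from .synth import direction_mask

log = logging.getLogger("pfls")

_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


class FieldError(ValueError):
    """Invalid field-detection input."""


@dataclass
class PlaceField:
    """A detected place field and its shape statistics."""

    unit_id: str
    field_id: str
    bins: np.ndarray          # (n, 2) bin indices on the field grid
    center_bin: tuple
    center_xy: tuple          # cm
    center_u: float           # linearized run coordinate, cm
    arm_label: str            # raw arm of the center (with side)
    length: float             # cm, linearized extent
    peak_rate: float          # Hz
    direction: str            # toward_reward | away_from_reward | both
    unit_mean_rate: float = np.nan
    skew: float = np.nan
    frai: float = np.nan
    n_traversals: int = 0
    bidirectional: bool = False
    lap_center_distances: Optional[np.ndarray] = None
    traversals: list = dc_field(default_factory=list, repr=False)

    def bin_mask(self, shape) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[self.bins[:, 0], self.bins[:, 1]] = True
        return m


@dataclass
class FieldTraversal:
    """One contiguous pass through a field."""

    lap: int
    entry: float
    exit: float
    spike_times: np.ndarray
    direction: str
    peak_u: float = np.nan     # location of maximum spiking this pass, cm

    def __post_init__(self):
        if self.exit <= self.entry:
            raise ValidationError("traversal exit must follow entry")


# ----------------------------------------------------------------------
# Detection
# ----------------------------------------------------------------------

def detect_fields(rm: RateMap, maze: MazeGeometry,
                  config: Optional[AnalysisConfig] = None,
                  direction: str = "both", unit_mean_rate: float = np.nan):
    """Connected-region field detection on a 2 cm smoothed rate map.

    Thresholds are relative to the unit's own map statistics (mean mu and SD
    sigma of smoothed visited-bin rates): regions of bins >= mu + 1 sigma,
    keeping those with a peak >= mu + 2 sigma and linearized extent >= the
    minimum field length.  Units whose map maximum is below the rate floor
    are excluded (empty result).
    """
    config = config or AnalysisConfig()
    if abs(rm.grid.bin_size - config.field_bin) > 1e-9:
        raise FieldError(
            f"field detection needs {config.field_bin} cm bins, "
            f"got {rm.grid.bin_size} cm")
    vals = rm.rate
    vis = rm.visited & np.isfinite(vals)
    if not vis.any() or np.nanmax(vals[vis]) < config.rate_floor:
        return []
    mu = float(vals[vis].mean())
    sd = float(vals[vis].std())
    if sd <= 0:   # no spatial modulation at all
        return []
    above1 = vis & (vals >= mu + sd)
    labels, n_comp = label(above1, structure=_FOUR_CONN)

    cx, cy = rm.grid.bin_centers()
    fields = []
    for comp in range(1, n_comp + 1):
        ii, jj = np.nonzero(labels == comp)
        comp_vals = vals[ii, jj]
        if comp_vals.max() < mu + 2 * sd:
            continue
        u, labs, _ = maze.linearize(cx[ii], cy[jj])
        extent = float(u.max() - u.min()) + rm.grid.bin_size
        if extent < config.min_field_len:
            continue
        k = _argmax_lowest_u(comp_vals, u)
        f = PlaceField(
            unit_id=rm.unit_id,
            field_id=f"{rm.unit_id}:{direction[0]}{len(fields)}",
            bins=np.stack([ii, jj], axis=1),
            center_bin=(int(ii[k]), int(jj[k])),
            center_xy=(float(cx[ii[k]]), float(cy[jj[k]])),
            center_u=float(u[k]), arm_label=str(labs[k]),
            length=extent, peak_rate=float(comp_vals[k]),
            direction=direction, unit_mean_rate=unit_mean_rate)
        fields.append(f)
    fields.sort(key=lambda f: f.center_u)
    for i, f in enumerate(fields):
        f.field_id = f"{rm.unit_id}:{direction[0]}{i}"
    return fields


def _argmax_lowest_u(vals: np.ndarray, u: np.ndarray) -> int:
    """Argmax index; ties broken by the lowest linearized coordinate."""
    top = np.isclose(vals, vals.max(), rtol=0, atol=1e-12)
    cand = np.nonzero(top)[0]
    if len(cand) > 1:
        log.info("field center tie among %d bins; taking lowest coordinate",
                 len(cand))
    return int(cand[np.argmin(u[cand])])


def field_center(field: PlaceField, rm: RateMap):
    """Highest-rate coordinates within the field (brute-force recompute)."""
    ii, jj = field.bins[:, 0], field.bins[:, 1]
    cx, cy = rm.grid.bin_centers()
    k = int(np.argmax(rm.rate[ii, jj]))
    return float(cx[ii[k]]), float(cy[jj[k]])


# ----------------------------------------------------------------------
# Direction-split maps
# ----------------------------------------------------------------------

def split_by_direction(session: Session, spike_times: np.ndarray,
                       ctx: SessionContext, unit_id: str = ""):
    """Rate maps from toward-reward and away-from-reward travel segments.

    Segment labels come from the trial phase: trial start -> reward is
    "toward", reward -> next trial start is "away".  Unlabeled samples
    (before the first trial) are excluded with a logged fraction.
    """
    if not session.events_of("reward"):
        raise FieldError("session has no reward events; cannot split by direction")
    cfg = ctx.config
    dmask = direction_mask(session.positions.t, session.events)
    frac_unlabeled = float(np.mean(dmask == 0))
    if frac_unlabeled > 0:
        log.info("direction split: %.1f%% of samples unlabeled; excluded",
                 100 * frac_unlabeled)
    maps = {}
    for name, want in (("toward_reward", 1), ("away_from_reward", -1)):
        fp, fs = speed_filter(session.positions, ctx.kin, spike_times,
                              cfg.speed_threshold, time_mask=dmask == want)
        occ = occupancy_map(fp, cfg.field_bin, ctx.field_grid)
        sx, sy = interp_position(session.positions, fs)
        maps[name] = (occ, rate_map(fs, sx, sy, occ, cfg.map_smooth_sd, unit_id))
    return maps["toward_reward"], maps["away_from_reward"]


def classify_directionality(fields_toward, fields_away, maze: MazeGeometry,
                            match_radius: float = 20.0):
    """Mark fields present in both travel directions as bidirectional.

    Toward/away fields of the same unit whose centers are separated by
    strictly less than ``match_radius`` cm of track are one bidirectional
    field observed twice; both entries are kept (their shape statistics are
    analyzed per direction) and flagged.  All others stay unidirectional.
    """
    used = set()
    for ft in fields_toward:
        best, best_d = None, np.inf
        for k, fa in enumerate(fields_away):
            if k in used or fa.unit_id != ft.unit_id:
                continue
            d = maze.track_distance(ft.center_u, ft.arm_label,
                                    fa.center_u, fa.arm_label)
            if d < best_d:
                best, best_d = k, d
        if best is not None and best_d < match_radius:
            used.add(best)
            ft.bidirectional = True
            fields_away[best].bidirectional = True
    return fields_toward + fields_away


# ----------------------------------------------------------------------
# Traversals, lap stability, FRAI
# ----------------------------------------------------------------------

def find_traversals(f: PlaceField, session: Session, spike_times: np.ndarray,
                    grid, max_gap_s: float = 1.0, min_samples: int = 2):
    """Contiguous in-field passes, with their spikes and travel direction.

    A traversal is a maximal run of consecutive position samples whose bin
    lies in the field (broken by tracking gaps > ``max_gap_s``) with at
    least ``min_samples`` samples.  The lap index counts reward-to-reward
    segments of the session.
    """
    pos = session.positions
    mask2d = f.bin_mask((grid.nx, grid.ny))
    ix, iy = grid.bin_index(pos.x_cm, pos.y_cm)
    inside = mask2d[ix, iy]
    dmask = direction_mask(pos.t, session.events)
    rewards = np.array([e.time for e in session.events_of("reward")])
    spike_times = np.asarray(spike_times, dtype=float)

    travs = []
    i, n = 0, len(pos.t)
    while i < n:
        if not inside[i]:
            i += 1
            continue
        j = i
        while (j + 1 < n and inside[j + 1]
               and pos.t[j + 1] - pos.t[j] <= max_gap_s):
            j += 1
        if j - i + 1 >= min_samples:
            entry, exit_ = pos.t[i], pos.t[j]
            sp = spike_times[(spike_times >= entry) & (spike_times <= exit_)]
            d = {1: "toward_reward", -1: "away_from_reward", 0: "both"}[
                int(dmask[i])]
            lap = int(np.searchsorted(rewards, entry))
            travs.append(FieldTraversal(lap=lap, entry=float(entry),
                                        exit=float(exit_), spike_times=sp,
                                        direction=d))
        i = j + 1
    if f.direction != "both":
        travs = [t for t in travs if t.direction == f.direction]
    return travs


def lap_stability(f: PlaceField, traversals, session: Session,
                  maze: MazeGeometry, bin_size: float = 2.0,
                  min_traversals: int = 15):
    """Per-pass distance of the in-field peak from the mean peak location.

    The per-pass center is the run coordinate of maximum spiking (2 cm
    histogram argmax of in-field spike positions).  Fields passed through
    fewer than ``min_traversals`` times are excluded (returns None).
    """
    spiking = [t for t in traversals if len(t.spike_times)]
    if len(traversals) < min_traversals:
        return None
    peaks = []
    for t in spiking:
        sx, sy = interp_position(session.positions, t.spike_times)
        u, _, _ = maze.linearize(sx, sy)
        lo = u.min()
        idx = ((u - lo) // bin_size).astype(int)
        counts = np.bincount(idx)
        k = int(np.argmax(counts))
        peaks.append(lo + (k + 0.5) * bin_size)
        t.peak_u = peaks[-1]
    if not peaks:
        return None
    peaks = np.array(peaks)
    return np.abs(peaks - peaks.mean())


def frai_single(f1: float, f2: float) -> float:
    """Firing-rate asymmetry index (F1 - F2) / (F1 + F2)."""
    if f1 + f2 == 0:
        return np.nan
    return (f1 - f2) / (f1 + f2)


def traversal_half_rates(t: FieldTraversal):
    """Mean firing rates of the first and second half of in-field spikes.

    The spike list is split by count (odd middle spike goes to the first
    half); each half's rate is its count over the time it occupies, with the
    boundary at the midpoint between the two straddling spikes.
    """
    sp = t.spike_times
    n = len(sp)
    if n < 2:
        return None
    m = (n + 1) // 2
    t_split = 0.5 * (sp[m - 1] + sp[m]) if m < n else sp[-1]
    d1, d2 = t_split - t.entry, t.exit - t_split
    if d1 <= 0 or d2 <= 0:
        return None
    return m / d1, (n - m) / d2


def field_frai(traversals) -> float:
    """Average FRAI over qualifying (>= 2 spike) traversals; NaN if none."""
    vals = []
    for t in traversals:
        rates = traversal_half_rates(t)
        if rates is None:
            continue
        v = frai_single(*rates)
        if np.isfinite(v):
            vals.append(v)
    return float(np.mean(vals)) if vals else np.nan


# ----------------------------------------------------------------------
# Skew
# ----------------------------------------------------------------------

def weighted_skew(x: np.ndarray, w: np.ndarray) -> float:
    """Third standardized moment of a weighted 1-D profile.

    skew = sum w (x - mu)^3 / [sum w (x - mu)^2]^(3/2) with moments
    normalized by sum w; NaN when the profile variance is zero.
    """
    x = np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    W = w.sum()
    if W <= 0:
        return np.nan
    mu = float((w * x).sum() / W)
    m2 = float((w * (x - mu) ** 2).sum() / W)
    m3 = float((w * (x - mu) ** 3).sum() / W)
    if m2 <= 0:
        return np.nan
    return m3 / m2 ** 1.5


def field_profile(f: PlaceField, rm: RateMap, maze: MazeGeometry):
    """Width-averaged 1-D firing-rate profile of a field along the track.

    In-field bins sharing a run-coordinate bin are averaged across the track
    width; returns (u_centers, mean rates) ordered by run coordinate.
    """
    ii, jj = f.bins[:, 0], f.bins[:, 1]
    cx, cy = rm.grid.bin_centers()
    u, _, _ = maze.linearize(cx[ii], cy[jj])
    b = rm.grid.bin_size
    idx = np.round(u / b).astype(int)
    vals = rm.rate[ii, jj]
    uniq = np.unique(idx)
    prof = np.array([vals[idx == k].mean() for k in uniq])
    return uniq * b, prof


def field_skew(f: PlaceField, rm: RateMap, maze: MazeGeometry) -> float:
    """Skew of the field's rate profile, oriented along travel direction.

    The profile axis points in the direction of travel: toward-reward fields
    use increasing run coordinate, away-from-reward fields the reverse, so a
    positive skew always means a tail in front of the animal.
    """
    x, w = field_profile(f, rm, maze)
    if len(x) < 3:
        return np.nan
    if f.direction == "away_from_reward":
        x = -x
    return weighted_skew(x, w)


# ----------------------------------------------------------------------
# Kinematic regression control
# ----------------------------------------------------------------------

def speed_accel_regression(rm: RateMap, speed_map: np.ndarray,
                           accel_map: np.ndarray) -> float:
    """r^2 of per-bin firing rate regressed on bin speed and acceleration.

    Ordinary least squares with intercept over visited bins; a rank-
    deficient design drops the acceleration column with a log message.
    """
    import statsmodels.api as sm

    ok = rm.visited & np.isfinite(rm.rate) & np.isfinite(speed_map) & \
        np.isfinite(accel_map)
    if ok.sum() < 10:
        raise FieldError("need >= 10 visited bins for the kinematic regression")
    y = rm.rate[ok]
    X = np.column_stack([speed_map[ok], accel_map[ok]])
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(y)), X])) < 3:
        log.info("kinematic regression rank-deficient; dropping acceleration")
        X = X[:, :1]
    return float(sm.OLS(y, sm.add_constant(X)).fit().rsquared)


# ----------------------------------------------------------------------
# Per-unit orchestration
# ----------------------------------------------------------------------

def find_place_cells(session: Session, ctx: SessionContext,
                     info_results=None) -> dict:
    """Fields of units passing the full place-cell criteria.

    The study pipeline: rate floor -> track coverage -> 0.8 bits/spike
    cutoff -> field detection on the 2 cm all-travel map.  Returns a dict
    ``unit_id -> list of PlaceField`` containing only units that pass the
    cutoff; units with no qualifying field map to an empty list.
    """
    from .information import classify_units

    if info_results is None:
        info_results = classify_units(session, ctx.config, ctx)
    out = {}
    for r in info_results:
        if not r.passes_cutoff:
            continue
        train = session.unit(r.unit_id)
        rm = ctx.unit_rate_map(train.spike_times, "field", r.unit_id)
        out[r.unit_id] = detect_fields(rm, session.maze, ctx.config, "both",
                                       r.mean_rate)
    return out

def analyze_unit_fields(session: Session, unit_id: str, ctx: SessionContext):
    """Direction-split field detection and shape statistics for one unit.

    Returns the combined labeled field list (toward + away, bidirectional
    flags set) with skew, FRAI, traversal counts and lap stability filled in.
    """
    cfg = ctx.config
    train = session.unit(unit_id)
    fs = ctx.filtered_spikes(train.spike_times)
    mean_rate = len(fs) / ctx.fp.total_time
    (occ_t, rm_t), (occ_a, rm_a) = split_by_direction(
        session, train.spike_times, ctx, unit_id)
    ft = detect_fields(rm_t, session.maze, cfg, "toward_reward", mean_rate)
    fa = detect_fields(rm_a, session.maze, cfg, "away_from_reward", mean_rate)
    fields = classify_directionality(ft, fa, session.maze, cfg.match_radius)
    for f in fields:
        rm_dir = rm_t if f.direction == "toward_reward" else rm_a
        f.skew = field_skew(f, rm_dir, session.maze)
        travs = find_traversals(f, session, train.spike_times, ctx.field_grid)
        f.traversals = travs
        f.n_traversals = len(travs)
        f.frai = field_frai(travs)
        f.lap_center_distances = lap_stability(
            f, travs, session, session.maze, cfg.field_bin, cfg.min_traversals)
    return fields
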