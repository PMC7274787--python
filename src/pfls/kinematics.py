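"""Speed, acceleration, speed filtering, occupancy and firing-rate maps.

Speed at each tracked sample is the hypotenuse of the displacement between
the samples immediately before and after, divided by their time gap, then
Gaussian-smoothed over time (1 s SD by default) and converted to cm/s.
Occupancy and rate maps are 2-D (cm bins over the camera plane); rates are
spike count over dwell time per bin, smoothed with a visited-mask-normalized
Gaussian kernel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from .core import PositionSeries, ValidationError
from .geometry import MazeGeometry

DWELL_CAP = 1.0  # s; per-sample dwell = half-gap to neighbors, capped for dropouts


class MapError(ValueError):
    """Unusable map input (e.g. no above-threshold samples)."""


@dataclass
class KinematicsSeries:
    """Per-sample speed (cm/s) and acceleration (cm/s^2), aligned with positions."""

    t: np.ndarray
    speed: np.ndarray
    accel: Optional[np.ndarray] = None


def compute_speed(pos: PositionSeries, smooth_sd: float = 1.0) -> KinematicsSeries:
    """Instantaneous speed from central displacement, Gaussian-smoothed in time.

    Endpoints use one-sided differences.  Smoothing is done on a uniform grid
    at the nominal camera rate (linear interpolation across dropouts) with SD
    ``smooth_sd`` seconds, then sampled back at the tracked timestamps.
    """
    if len(pos) < 3:
        raise ValidationError("need at least 3 position samples for speed")
    t, x, y = pos.t, pos.x, pos.y
    i0, i1 = np.arange(len(t)), np.arange(len(t))
    i0[1:] -= 1            # previous sample (one-sided at the left edge)
    i1[:-1] += 1           # next sample (one-sided at the right edge)
    raw = np.hypot(x[i1] - x[i0], y[i1] - y[i0]) / (t[i1] - t[i0])  # px/s

    dt = 1.0 / pos.nominal_rate
    tg = np.arange(t[0], t[-1] + dt / 2, dt)
    vg = np.interp(tg, t, raw)
    vs = gaussian_filter1d(vg, sigma=smooth_sd / dt, mode="nearest")
    speed = np.interp(t, tg, vs) / pos.px_per_cm  # cm/s
    return KinematicsSeries(t=t, speed=speed)


def compute_acceleration(kin: KinematicsSeries) -> KinematicsSeries:
    """Central difference of the smoothed speed (one-sided at the edges)."""
    t, v = kin.t, kin.speed
    i0, i1 = np.arange(len(t)), np.arange(len(t))
    i0[1:] -= 1
    i1[:-1] += 1
    accel = (v[i1] - v[i0]) / (t[i1] - t[i0])
    return KinematicsSeries(t=t, speed=v, accel=accel)


def sample_dwell(t: np.ndarray, cap: float = DWELL_CAP) -> np.ndarray:
    """Dwell time credited to each sample: half-gap to each neighbor, capped.

    The cap guards against tracking dropouts crediting a sample with the
    whole occlusion interval.
    """
    t = np.asarray(t, dtype=float)
    if len(t) == 1:
        return np.array([0.0])
    gaps = np.minimum(np.diff(t), cap)
    dwell = np.zeros(len(t))
    dwell[:-1] += gaps / 2
    dwell[1:] += gaps / 2
    return dwell


@dataclass
class FilteredPositions:
    """Speed-filtered samples in cm, with per-sample dwell time."""

    t: np.ndarray
    x_cm: np.ndarray
    y_cm: np.ndarray
    dwell: np.ndarray
    speed: np.ndarray
    accel: Optional[np.ndarray] = None

    @property
    def total_time(self) -> float:
        return float(self.dwell.sum())


def interp_speed(kin: KinematicsSeries, times: np.ndarray) -> np.ndarray:
    return np.interp(times, kin.t, kin.speed)


def interp_position(pos: PositionSeries, times: np.ndarray):
    """Linear interpolation of position (cm) at arbitrary times."""
    x = np.interp(times, pos.t, pos.x_cm)
    y = np.interp(times, pos.t, pos.y_cm)
    return x, y


def speed_filter(pos: PositionSeries, kin: KinematicsSeries,
                 spike_times: Optional[np.ndarray], threshold: float,
                 time_mask: Optional[np.ndarray] = None):
    """Retain samples (and spikes) at speed >= threshold.

    ``time_mask`` optionally restricts to a subset of samples first (e.g.
    travel-direction segments); spikes use the speed interpolated at their
    times.  Returns ``(FilteredPositions, filtered_spike_times)``; the spike
    array is None when no spikes were given.
    """
    m = kin.speed >= threshold
    if time_mask is not None:
        m &= time_mask
    dwell = sample_dwell(pos.t)
    fp = FilteredPositions(
        t=pos.t[m], x_cm=pos.x_cm[m], y_cm=pos.y_cm[m], dwell=dwell[m],
        speed=kin.speed[m],
        accel=kin.accel[m] if kin.accel is not None else None)
    fs = None
    if spike_times is not None:
        spike_times = np.asarray(spike_times, dtype=float)
        sm = interp_speed(kin, spike_times) >= threshold
        if time_mask is not None:
            # keep spikes only inside retained-sample intervals
            inside = np.interp(spike_times, pos.t, time_mask.astype(float)) >= 0.5
            sm &= inside
        fs = spike_times[sm]
    return fp, fs


# ----------------------------------------------------------------------
# Binned maps
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class MapGrid:
    """Half-open 2-D bin grid: bin (i, j) covers [x0+i*b, x0+(i+1)*b) x [...)."""

    bin_size: float
    x0: float
    y0: float
    nx: int
    ny: int

    def bin_index(self, x_cm, y_cm):
        ix = np.clip(((np.asarray(x_cm) - self.x0) // self.bin_size).astype(int),
                     0, self.nx - 1)
        iy = np.clip(((np.asarray(y_cm) - self.y0) // self.bin_size).astype(int),
                     0, self.ny - 1)
        return ix, iy

    def bin_centers(self):
        cx = self.x0 + (np.arange(self.nx) + 0.5) * self.bin_size
        cy = self.y0 + (np.arange(self.ny) + 0.5) * self.bin_size
        return cx, cy


def grid_from_positions(pos: PositionSeries, bin_size: float,
                        pad: float = 2.0) -> MapGrid:
    """Grid covering the session's tracked extent (origin snapped to bin size)."""
    x, y = pos.x_cm, pos.y_cm
    x0 = np.floor((x.min() - pad) / bin_size) * bin_size
    y0 = np.floor((y.min() - pad) / bin_size) * bin_size
    nx = int(np.ceil((x.max() + pad - x0) / bin_size))
    ny = int(np.ceil((y.max() + pad - y0) / bin_size))
    return MapGrid(bin_size=bin_size, x0=x0, y0=y0, nx=max(nx, 1), ny=max(ny, 1))


@dataclass
class OccupancyMap:
    """Per-bin occupancy probability P_i over speed-filtered time."""

    grid: MapGrid
    dwell: np.ndarray     # seconds, shape (nx, ny)
    P: np.ndarray         # occupancy probability, sums to 1 over visited bins
    visited: np.ndarray   # bool mask
    total_time: float     # s


def occupancy_map(fp: FilteredPositions, bin_size: float,
                  grid: Optional[MapGrid] = None) -> OccupancyMap:
    """Dwell-time occupancy probability on the 2-D grid."""
    if len(fp.t) == 0 or fp.total_time <= 0:
        raise MapError("no above-threshold samples: unusable trial")
    if grid is None:
        x0 = np.floor(fp.x_cm.min() / bin_size) * bin_size
        y0 = np.floor(fp.y_cm.min() / bin_size) * bin_size
        grid = MapGrid(bin_size=bin_size, x0=x0, y0=y0,
                       nx=int(np.ceil((fp.x_cm.max() - x0) / bin_size)) + 1,
                       ny=int(np.ceil((fp.y_cm.max() - y0) / bin_size)) + 1)
    ix, iy = grid.bin_index(fp.x_cm, fp.y_cm)
    dwell = np.zeros((grid.nx, grid.ny))
    np.add.at(dwell, (ix, iy), fp.dwell)
    total = dwell.sum()
    return OccupancyMap(grid=grid, dwell=dwell, P=dwell / total,
                        visited=dwell > 0, total_time=float(total))


@dataclass
class RateMap:
    """Per-bin firing rate R_i (Hz) and the overall mean rate.

    ``rate`` is the mask-normalized Gaussian-smoothed map (NaN off-track);
    ``rate_raw`` the unsmoothed count/dwell map.  ``mean_rate`` is total
    filtered spikes over total filtered time, which equals sum(P_i * R_i^raw)
    exactly.
    """

    grid: MapGrid
    rate: np.ndarray
    rate_raw: np.ndarray
    visited: np.ndarray
    mean_rate: float
    smooth_sd: float
    unit_id: str = ""
    n_spikes: int = 0

    def visited_rates(self) -> np.ndarray:
        return self.rate[self.visited]


def smooth_masked(values: np.ndarray, mask: np.ndarray,
                  sigma_bins: float) -> np.ndarray:
    """Gaussian smoothing restricted to a support mask.

    Off-mask bins contribute nothing and the kernel is renormalized over the
    mask, so edges and the track border do not bleed zeros into the map.
    """
    v = np.where(mask, values, 0.0)
    num = gaussian_filter(v, sigma=sigma_bins, mode="constant")
    den = gaussian_filter(mask.astype(float), sigma=sigma_bins, mode="constant")
    out = np.full(values.shape, np.nan)
    np.divide(num, den, out=out, where=den > 0)
    out[~mask] = np.nan
    return out


def rate_map(spike_times: np.ndarray, spike_x_cm: np.ndarray,
             spike_y_cm: np.ndarray, occ: OccupancyMap, smooth_sd: float,
             unit_id: str = "") -> RateMap:
    """Firing rate per bin: spike count / dwell time, then smoothed."""
    if occ.total_time <= 0:
        raise MapError("zero total occupancy time")
    grid = occ.grid
    ix, iy = grid.bin_index(spike_x_cm, spike_y_cm)
    counts = np.zeros((grid.nx, grid.ny))
    if len(spike_times):
        # spikes interpolated into unvisited bins (tracking-gap corner cuts)
        # are snapped to the nearest visited bin so no spike mass is lost
        bad = ~occ.visited[ix, iy]
        if bad.any():
            vi, vj = np.nonzero(occ.visited)
            for k in np.nonzero(bad)[0]:
                d2 = (vi - ix[k]) ** 2 + (vj - iy[k]) ** 2
                m = int(np.argmin(d2))
                ix[k], iy[k] = vi[m], vj[m]
        np.add.at(counts, (ix, iy), 1.0)
    raw = np.zeros_like(counts)
    np.divide(counts, occ.dwell, out=raw, where=occ.visited)
    raw[~occ.visited] = 0.0
    sm = smooth_masked(raw, occ.visited, smooth_sd / grid.bin_size)
    mean_rate = float(len(spike_times) / occ.total_time)
    return RateMap(grid=grid, rate=sm, rate_raw=raw, visited=occ.visited,
                   mean_rate=mean_rate, smooth_sd=smooth_sd, unit_id=unit_id,
                   n_spikes=int(len(spike_times)))


def check_track_coverage(fp: FilteredPositions, maze: MazeGeometry,
                         bin_size: float = 2.0) -> bool:
    """True iff every linearized track bin holds >= 1 above-threshold sample."""
    if len(fp.t) == 0:
        return False
    u, _, _ = maze.linearize(fp.x_cm, fp.y_cm)
    n_bins = int(np.ceil(maze.run_length / bin_size))
    idx = np.clip((u // bin_size).astype(int), 0, n_bins - 1)
    return bool(len(np.unique(idx)) == n_bins)


def kinematic_maps(fp: FilteredPositions, occ: OccupancyMap):
    """Dwell-weighted per-bin mean speed and acceleration maps.

    Used by the speed/acceleration regression control for place fields.
    """
    grid = occ.grid
    ix, iy = grid.bin_index(fp.x_cm, fp.y_cm)
    wsum = np.zeros((grid.nx, grid.ny))
    vsum = np.zeros_like(wsum)
    asum = np.zeros_like(wsum)
    np.add.at(wsum, (ix, iy), fp.dwell)
    np.add.at(vsum, (ix, iy), fp.dwell * fp.speed)
    if fp.accel is not None:
        np.add.at(asum, (ix, iy), fp.dwell * fp.accel)
    speed_map = np.full(wsum.shape, np.nan)
    accel_map = np.full(wsum.shape, np.nan)
    ok = wsum > 0
    speed_map[ok] = vsum[ok] / wsum[ok]
    accel_map[ok] = asum[ok] / wsum[ok]
    return speed_map, accel_map
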