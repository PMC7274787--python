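"""Shared domain types for T-maze place-field analysis.

Units: time in seconds (float), positions stored in camera pixels with a
``px_per_cm`` scale, all analysis done in cm after a single conversion at
load/derivation time.  Spatial bins are half-open ``[lo, hi)`` indexed from 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .geometry import MazeGeometry

log = logging.getLogger("pfls")


class ValidationError(ValueError):
    """A domain invariant was violated."""


def as_seedseq(seed) -> np.random.SeedSequence:
    """Accept an int or an already-spawned SeedSequence."""
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


@dataclass
class PositionSeries:
    """Timestamped 2-D tracked position (overhead camera).

    Nominal sampling is ~30 Hz; occlusion dropouts (gaps) are permitted and
    must survive resampling downstream.
    """

    t: np.ndarray           # seconds, strictly increasing
    x: np.ndarray           # pixels
    y: np.ndarray           # pixels
    px_per_cm: float
    nominal_rate: float = 30.0

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValidationError("t, x, y must have equal length")
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            raise ValidationError("position timestamps must be strictly increasing")
        if self.px_per_cm <= 0:
            raise ValidationError("px_per_cm must be positive")

    def __len__(self):
        return len(self.t)

    @property
    def x_cm(self) -> np.ndarray:
        return self.x / self.px_per_cm

    @property
    def y_cm(self) -> np.ndarray:
        return self.y / self.px_per_cm


@dataclass
class SpikeTrain:
    """Sorted spike timestamps of one isolated unit."""

    unit_id: str
    region: str              # "HPC" or "LS"
    spike_times: np.ndarray  # seconds, ascending
    session_id: str = ""

    def __post_init__(self):
        if self.region not in ("HPC", "LS"):
            raise ValidationError(f"unknown region {self.region!r} for {self.unit_id}")
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if np.any(np.diff(self.spike_times) < 0):
            log.warning("unit %s: spike times were unsorted; sorting", self.unit_id)
            self.spike_times = np.sort(self.spike_times)

    def __len__(self):
        return len(self.spike_times)

    def restrict(self, t0: float, t1: float) -> "SpikeTrain":
        """Half-open time restriction [t0, t1)."""
        m = (self.spike_times >= t0) & (self.spike_times < t1)
        return replace(self, spike_times=self.spike_times[m])


@dataclass
class TrialEvent:
    """A timestamped behavioral event.

    kind: "trial_start" (departure from the forced-arm end) or "reward"
    (arrival at the reward site); ``side`` is the forced/chosen side and
    ``correct`` whether the choice matched the forced side.
    """

    kind: str
    time: float
    side: str = ""
    correct: bool = True


@dataclass
class Session:
    """One recording session: positions, spike trains, maze, trial events."""

    session_id: str
    positions: PositionSeries
    trains: list
    maze: MazeGeometry
    events: list = field(default_factory=list)

    def __post_init__(self):
        times = [e.time for e in self.events]
        if times != sorted(times):
            raise ValidationError("trial events must be temporally ordered")
        t0, t1 = self.bounds
        for tr in self.trains:
            if len(tr) and (tr.spike_times[0] < t0 - 1e-9 or
                            tr.spike_times[-1] > t1 + 1e-9):
                n_out = int(np.sum((tr.spike_times < t0) | (tr.spike_times > t1)))
                raise ValidationError(
                    f"unit {tr.unit_id}: {n_out} spikes outside session bounds "
                    f"[{t0:.3f}, {t1:.3f}] s")

    @property
    def bounds(self):
        """Session bounds: [first, last] position timestamp."""
        return float(self.positions.t[0]), float(self.positions.t[-1])

    @property
    def duration(self) -> float:
        t0, t1 = self.bounds
        return t1 - t0

    def unit(self, unit_id: str) -> SpikeTrain:
        for tr in self.trains:
            if tr.unit_id == unit_id:
                return tr
        raise KeyError(unit_id)

    def events_of(self, kind: str):
        return [e for e in self.events if e.kind == kind]


def drop_out_of_bounds_spikes(spike_times: np.ndarray, t0: float, t1: float,
                              unit_id: str = "?") -> np.ndarray:
    """Clip spikes to [t0, t1], logging how many were dropped."""
    spike_times = np.asarray(spike_times, dtype=float)
    m = (spike_times >= t0) & (spike_times <= t1)
    n_drop = int((~m).sum())
    if n_drop:
        log.info("unit %s: dropped %d spikes outside session bounds", unit_id, n_drop)
    return spike_times[m]


@dataclass(frozen=True)
class AnalysisConfig:
    """All analysis thresholds in one place.

    Defaults are the study constants: a 12 cm/s running-speed filter, 1 cm
    bins for spatial information and 2 cm bins for field maps, 10 cm map
    smoothing, 1 s speed smoothing, a 0.8 bits/spike place-information
    cutoff, 15 cm minimum field length, a 0.05 Hz rate floor, 20 cm field
    matching radius, and 10 ms cross-correlogram bins over +/-100 ms lags.
    """

    speed_threshold: float = 12.0    # cm/s
    info_bin: float = 1.0            # cm
    field_bin: float = 2.0           # cm
    map_smooth_sd: float = 10.0      # cm
    speed_smooth_sd: float = 1.0     # s
    bits_cutoff: float = 0.8         # bits/spike
    min_field_len: float = 15.0      # cm
    rate_floor: float = 0.05         # Hz
    match_radius: float = 20.0       # cm
    ccg_bin: float = 10.0            # ms
    ccg_maxlag: float = 100.0        # ms
    n_shuffles: int = 100
    rng_seed: int = 0
    # secondary knobs
    junction_halfwidth: float = 10.0  # cm, junction exclusion zone
    mi_kmax: int = 3                  # spike-count clip for mutual information
    min_traversals: int = 15          # lap-analysis inclusion
    ccg_normalization: str = "counts"  # counts | rate | pearson

    def __post_init__(self):
        for name in ("speed_threshold", "info_bin", "field_bin", "map_smooth_sd",
                     "speed_smooth_sd", "bits_cutoff", "min_field_len",
                     "rate_floor", "match_radius", "ccg_bin", "ccg_maxlag"):
            if getattr(self, name) <= 0 and name != "speed_threshold":
                raise ValidationError(f"{name} must be positive")
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be nonnegative")

    @classmethod
    def from_dict(cls, d: Optional[dict]) -> "AnalysisConfig":
        d = d or {}
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        unknown = set(d) - set(known)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)
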