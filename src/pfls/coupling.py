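"""HPC-LS pair matching and shuffle-corrected spike cross-correlograms.

Pairs are HPC and LS place fields recorded in the same session with centers
within 20 cm of track; among multiple candidates the LS unit with the most
similar mean firing rate is chosen.  Cross-correlograms use 10 ms bins over
lags of -100..+100 ms, positive lag meaning LS activity follows HPC.  The
control is the same correlogram against a circularly time-shifted LS train;
its mean over lags and shuffles is subtracted from every lag bin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import AnalysisConfig, Session, as_seedseq
from .geometry import MazeGeometry

log = logging.getLogger("pfls")

ARM_GROUPS = ("forced", "middle", "choice")


class CouplingError(ValueError):
    """Invalid cross-correlation input."""


@dataclass
class PairMatch:
    """A matched HPC-LS place-field pair."""

    hpc_unit: str
    ls_unit: str
    hpc_field_id: str
    ls_field_id: str
    hpc_center_u: float
    ls_center_u: float
    center_distance: float   # cm, along track
    rate_difference: float   # Hz, |mean rate difference|
    arm_group: str           # forced | middle | choice | forced_point | choice_point


@dataclass
class CrossCorrelogram:
    """Raw and shuffle-corrected cross-correlation at 10 ms lags."""

    lags_ms: np.ndarray
    raw: np.ndarray
    shuffle_mean: float
    corrected: np.ndarray
    n_shuffles: int
    seed: Optional[int] = None
    normalization: str = "counts"

    @property
    def mean_corrected(self) -> float:
        return float(self.corrected.mean())

    @property
    def peak_lag_ms(self) -> float:
        return float(self.lags_ms[int(np.argmax(self.corrected))])


def _zone_to_group(maze: MazeGeometry, u: float, arm_label: str,
                   junction_halfwidth: float) -> str:
    zone = maze.zone_label(u, arm_label, junction_halfwidth)
    return {"forced_side": "forced", "stem": "middle",
            "choice_side": "choice"}.get(zone, zone)


def match_pairs(hpc_fields, ls_fields, maze: MazeGeometry,
                config: Optional[AnalysisConfig] = None):
    """Match each HPC field to the best LS field within the match radius.

    Candidates are LS fields whose along-track center distance is <= the
    match radius (20 cm, inclusive); among candidates the one with the most
    similar unit mean firing rate wins (distance, then unit id, break exact
    rate ties deterministically).  Multi-field cells contribute one match
    per field; unmatched fields are excluded.
    """
    config = config or AnalysisConfig()
    pairs = []
    for hf in sorted(hpc_fields, key=lambda f: f.field_id):
        cands = []
        for lf in ls_fields:
            d = maze.track_distance(hf.center_u, hf.arm_label,
                                    lf.center_u, lf.arm_label)
            if d <= config.match_radius:
                dr = abs(hf.unit_mean_rate - lf.unit_mean_rate)
                cands.append((dr, d, lf.field_id, lf))
        if not cands:
            continue
        dr, d, _, lf = min(cands, key=lambda c: (c[0], c[1], c[2]))
        pairs.append(PairMatch(
            hpc_unit=hf.unit_id, ls_unit=lf.unit_id,
            hpc_field_id=hf.field_id, ls_field_id=lf.field_id,
            hpc_center_u=hf.center_u, ls_center_u=lf.center_u,
            center_distance=float(d), rate_difference=float(dr),
            arm_group=_zone_to_group(maze, hf.center_u, hf.arm_label,
                                     config.junction_halfwidth)))
    return pairs


# ----------------------------------------------------------------------
# Cross-correlograms
# ----------------------------------------------------------------------

def _lag_counts(hpc_idx: np.ndarray, ls_idx: np.ndarray,
                max_lag_bins: int) -> np.ndarray:
    """Pair counts by bin-index difference (ls bin - hpc bin).

    Identical to the lagged inner product of the dense binned count vectors,
    computed sparsely on the sorted spike bin indices.
    """
    lags = np.arange(-max_lag_bins, max_lag_bins + 1)
    out = np.empty(len(lags))
    for k, lag in enumerate(lags):
        v = hpc_idx + lag
        out[k] = (np.searchsorted(ls_idx, v, side="right")
                  - np.searchsorted(ls_idx, v, side="left")).sum()
    return out


def cross_correlogram(hpc_times: np.ndarray, ls_times: np.ndarray,
                      t0: float, t1: float,
                      config: Optional[AnalysisConfig] = None,
                      hpc_name: str = "hpc", ls_name: str = "ls"):
    """Raw cross-correlogram of two spike trains.

    Both trains are binned at ``ccg_bin`` ms over [t0, t1); the value at lag
    tau is the inner product of the HPC counts with the LS counts advanced
    by tau bins.  Positive lag = HPC leads.  Normalization: "counts" (pair
    counts per time bin, the default), "rate" (per bin per second) or
    "pearson" (lagged Pearson correlation of the binned counts).
    """
    config = config or AnalysisConfig()
    for name, arr in ((hpc_name, hpc_times), (ls_name, ls_times)):
        if len(arr) == 0:
            raise CouplingError(f"empty spike train: {name}")
    binw = config.ccg_bin / 1000.0
    max_lag_bins = int(round(config.ccg_maxlag / config.ccg_bin))
    n_bins = int(np.ceil((t1 - t0) / binw))
    hpc_idx = np.sort(((np.asarray(hpc_times) - t0) // binw).astype(np.int64))
    ls_idx = np.sort(((np.asarray(ls_times) - t0) // binw).astype(np.int64))
    counts = _lag_counts(hpc_idx, ls_idx, max_lag_bins)
    lags_ms = np.arange(-max_lag_bins, max_lag_bins + 1) * config.ccg_bin

    if config.ccg_normalization == "counts":
        vals = counts / n_bins
    elif config.ccg_normalization == "rate":
        vals = counts / (n_bins * binw)
    elif config.ccg_normalization == "pearson":
        nh, nl = len(hpc_idx), len(ls_idx)
        mh, ml = nh / n_bins, nl / n_bins
        # binned trains are 0/1-dominated; use count moments for sx, sy
        hc = np.bincount(hpc_idx, minlength=n_bins)[:n_bins]
        lc = np.bincount(ls_idx, minlength=n_bins)[:n_bins]
        sx, sy = hc.std(), lc.std()
        if sx == 0 or sy == 0:
            raise CouplingError("zero-variance binned train for pearson CCG")
        vals = (counts / n_bins - mh * ml) / (sx * sy)
    else:
        raise CouplingError(
            f"unknown ccg normalization {config.ccg_normalization!r}")
    return lags_ms, vals


def shuffle_correct(hpc_times: np.ndarray, ls_times: np.ndarray,
                    t0: float, t1: float, n_shuffles: int, seed,
                    config: Optional[AnalysisConfig] = None) -> CrossCorrelogram:
    """Shuffle-corrected cross-correlogram.

    The LS train is circularly time-shifted by a uniform offset of at least
    1 s, ``n_shuffles`` times; the scalar mean of the control correlograms
    over lags and shuffles is subtracted from every raw lag bin.
    """
    config = config or AnalysisConfig()
    if n_shuffles < 1:
        raise CouplingError("n_shuffles must be >= 1")
    lags_ms, raw = cross_correlogram(hpc_times, ls_times, t0, t1, config)
    rng = np.random.default_rng(seed)
    T = t1 - t0
    acc = 0.0
    for _ in range(n_shuffles):
        off = rng.uniform(1.0, T - 1.0)
        shifted = np.sort(((np.asarray(ls_times) - t0 + off) % T) + t0)
        _, ctrl = cross_correlogram(hpc_times, shifted, t0, t1, config)
        acc += ctrl.mean()
    shuffle_mean = acc / n_shuffles
    return CrossCorrelogram(lags_ms=lags_ms, raw=raw,
                            shuffle_mean=float(shuffle_mean),
                            corrected=raw - shuffle_mean,
                            n_shuffles=n_shuffles, seed=seed,
                            normalization=config.ccg_normalization)


# ----------------------------------------------------------------------
# Group summaries
# ----------------------------------------------------------------------

def pair_ccgs(session: Session, pairs, seed,
              config: Optional[AnalysisConfig] = None,
              t_range: Optional[tuple] = None):
    """Shuffle-corrected CCG for every matched pair (deterministic seeds)."""
    config = config or AnalysisConfig()
    t0, t1 = t_range if t_range is not None else session.bounds
    ccgs = []
    ss = as_seedseq(seed).spawn(len(pairs))
    for p, child in zip(pairs, ss):
        hpc = session.unit(p.hpc_unit).spike_times
        ls = session.unit(p.ls_unit).spike_times
        ccgs.append(shuffle_correct(hpc, ls, t0, t1, config.n_shuffles,
                                    child, config))
    return ccgs


def summarize_pairs(pairs, ccgs):
    """Per-arm mean corrected correlation (over +/-100 ms) and peak lags.

    Returns a dict keyed by arm group with mean, SE, n and mean peak lag;
    junction-labelled pairs are not part of the three arm groups.  Empty
    groups are omitted with a log message.
    """
    per_pair = np.array([c.mean_corrected for c in ccgs])
    peak = np.array([c.peak_lag_ms for c in ccgs])
    groups = {}
    for g in ARM_GROUPS:
        idx = [i for i, p in enumerate(pairs) if p.arm_group == g]
        if not idx:
            log.info("no pairs in arm group %s; omitted", g)
            continue
        v = per_pair[idx]
        groups[g] = {
            "n": len(idx),
            "mean_corrected": float(v.mean()),
            "se": float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else np.nan,
            "mean_peak_lag_ms": float(peak[idx].mean()),
            "values": v,
        }
    return groups


def session_thirds(session: Session, pairs, seed,
                   config: Optional[AnalysisConfig] = None):
    """CCG pipeline restricted to the first/middle/last third of the session.

    Thirds partition [t0, t1] half-open; a pair is dropped from a third in
    which either train has fewer than 2 spikes.  Returns a list of dicts
    (one per third) with the per-arm-group summaries.
    """
    config = config or AnalysisConfig()
    t0, t1 = session.bounds
    edges = t0 + (t1 - t0) * np.array([0.0, 1 / 3, 2 / 3, 1.0])
    out = []
    ss = as_seedseq(seed).spawn(3)
    for k in range(3):
        lo, hi = edges[k], edges[k + 1] + (1e-9 if k == 2 else 0.0)
        kept, ccgs = [], []
        children = ss[k].spawn(len(pairs))
        for p, child in zip(pairs, children):
            hpc = session.unit(p.hpc_unit).restrict(lo, hi).spike_times
            ls = session.unit(p.ls_unit).restrict(lo, hi).spike_times
            if len(hpc) < 2 or len(ls) < 2:
                continue
            kept.append(p)
            ccgs.append(shuffle_correct(hpc, ls, lo, min(hi, t1),
                                        config.n_shuffles, child, config))
        out.append({"third": k, "t_range": (float(lo), float(min(hi, t1))),
                    "groups": summarize_pairs(kept, ccgs),
                    "n_pairs": len(kept)})
    return out
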