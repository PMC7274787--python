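"""Double-sided T-maze geometry.

The maze is an end-to-end ("double-sided") T: two lateral *forced* arms join
the near junction (the forced point), a central stem runs to the far junction
(the choice point), and two lateral *choice* arms end at the reward sites.
A run from a forced-arm end to a reward site covers arm + stem + arm.

Every 2-D point on (or near) the track maps to a *run coordinate* ``u`` in cm:

    u = 0            at a forced-arm end
    u = arm_length   at the forced point
    u = arm_length + stem_length       at the choice point
    u = 2*arm_length + stem_length     at a reward site

Left and right arms mirror onto the same ``u`` range; the arm label keeps the
side.  Distance to reward is the along-track (geodesic) distance, which under
this parameterization is simply ``run_length - u`` for either reward context.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ARM_LABELS = ("forced_left", "forced_right", "stem", "choice_left", "choice_right")
ZONE_LABELS = ("forced_side", "stem", "choice_side", "forced_point", "choice_point")

#: Projection priority at junction ties (first match wins).
_SEGMENT_ORDER = ("stem", "forced_left", "forced_right", "choice_left", "choice_right")


class MazeError(ValueError):
    """Invalid maze parameter or off-track query."""


@dataclass(frozen=True)
class MazeGeometry:
    """Geometry and linearization map of the double-sided T maze."""

    arm_length: float
    stem_length: float
    #: per-segment (p0, p1, u0, u1): endpoints in cm and run coordinates there
    segments: dict = field(repr=False, default=None)
    off_track_tolerance: float = 10.0

    @property
    def run_length(self) -> float:
        """Length of the forced-end -> reward run path (cm)."""
        return 2.0 * self.arm_length + self.stem_length

    @property
    def total_track_length(self) -> float:
        """Summed physical length of all five segments (cm)."""
        return 4.0 * self.arm_length + self.stem_length

    @property
    def reward_sites(self) -> dict:
        a, s = self.arm_length, self.stem_length
        return {"left": np.array([s, a]), "right": np.array([s, -a])}

    # ------------------------------------------------------------------
    def linearize(self, x, y):
        """Project 2-D points onto the track.

        Parameters
        ----------
        x, y : array_like, cm

        Returns
        -------
        u : ndarray, run coordinate in cm
        labels : ndarray of str, one of ``ARM_LABELS``
        off_dist : ndarray, perpendicular distance to the chosen segment (cm)
        """
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        pts = np.stack([x, y], axis=-1)
        best_d = np.full(x.shape, np.inf)
        best_u = np.zeros(x.shape)
        best_lab = np.zeros(x.shape, dtype=int)
        for lab in _SEGMENT_ORDER:
            p0, p1, u0, u1 = self.segments[lab]
            v = p1 - p0
            t = np.clip((pts - p0) @ v / (v @ v), 0.0, 1.0)
            proj = p0 + t[..., None] * v
            d = np.hypot(*(pts - proj).T) if pts.ndim > 1 else np.hypot(*(pts - proj))
            u = u0 + t * (u1 - u0)
            better = d < best_d - 1e-12
            best_d = np.where(better, d, best_d)
            best_u = np.where(better, u, best_u)
            best_lab = np.where(better, ARM_LABELS.index(lab), best_lab)
        labels = np.array(ARM_LABELS, dtype=object)[best_lab]
        return best_u, labels, best_d

    def linearize_point(self, x: float, y: float):
        """Scalar convenience wrapper around :meth:`linearize`."""
        u, lab, d = self.linearize([x], [y])
        if d[0] > self.off_track_tolerance:
            raise MazeError(
                f"point ({x:.1f}, {y:.1f}) is {d[0]:.1f} cm off track "
                f"(tolerance {self.off_track_tolerance} cm)"
            )
        return float(u[0]), str(lab[0])

    def zone_label(self, u, arm_label, junction_halfwidth: float = 10.0):
        """Coarse location label with junction zones.

        Points within ``junction_halfwidth`` cm (run coordinate) of a T
        junction are labelled ``forced_point`` / ``choice_point``; junction
        fields are excluded from per-arm tallies downstream.
        """
        a, s = self.arm_length, self.stem_length
        if abs(u - a) <= junction_halfwidth:
            return "forced_point"
        if abs(u - (a + s)) <= junction_halfwidth:
            return "choice_point"
        if arm_label in ("forced_left", "forced_right"):
            return "forced_side"
        if arm_label in ("choice_left", "choice_right"):
            return "choice_side"
        return "stem"

    def distance_to_reward(self, u):
        """Along-track distance (cm) to the contextual reward site.

        Both reward sites sit at ``u = run_length``; on the mirror-collapsed
        run coordinate the path distance to the upcoming (toward travel) or
        just-visited (away travel) reward is ``run_length - u``.
        """
        return self.run_length - np.asarray(u, dtype=float)

    def track_distance(self, u1, label1, u2, label2) -> float:
        """Geodesic along-track distance between two linearized points.

        Points on opposite lateral arms of the same T must route through the
        junction; all other pairs differ only in run coordinate.
        """
        a, s = self.arm_length, self.stem_length

        def side(lab):
            return lab.split("_")[1] if "_" in lab else None

        def cls(lab):
            return lab.split("_")[0]

        if cls(label1) == cls(label2) != "stem" and side(label1) != side(label2):
            if cls(label1) == "forced":
                return (a - u1) + (a - u2)
            return (u1 - (a + s)) + (u2 - (a + s))
        return abs(u1 - u2)


def build_maze(arm_length: float, stem_length: float,
               off_track_tolerance: float = 10.0) -> MazeGeometry:
    """Construct the double-sided T maze.

    The forced point sits at the origin, the stem runs along +x, lateral arms
    along ±y.  Reward sites are the two choice-arm ends.
    """
    if arm_length <= 0 or stem_length <= 0:
        raise MazeError("arm_length and stem_length must be positive")
    a, s = float(arm_length), float(stem_length)
    segments = {
        "forced_left": (np.array([0.0, a]), np.array([0.0, 0.0]), 0.0, a),
        "forced_right": (np.array([0.0, -a]), np.array([0.0, 0.0]), 0.0, a),
        "stem": (np.array([0.0, 0.0]), np.array([s, 0.0]), a, a + s),
        "choice_left": (np.array([s, 0.0]), np.array([s, a]), a + s, 2 * a + s),
        "choice_right": (np.array([s, 0.0]), np.array([s, -a]), a + s, 2 * a + s),
    }
    return MazeGeometry(arm_length=a, stem_length=s, segments=segments,
                        off_track_tolerance=off_track_tolerance)


# ----------------------------------------------------------------------
# Field-location summaries
# ----------------------------------------------------------------------

def assign_field_locations(fields, maze: MazeGeometry,
                           junction_halfwidth: float = 10.0):
    """Label each field center with an arm zone and its reward distance.

    Parameters
    ----------
    fields : iterable of objects with ``center_u``, ``arm_label``,
        ``unit_id``, ``field_id`` and ``direction`` attributes
        (:class:`pfls.fields.PlaceField`).

    Returns
    -------
    list of dict rows (unit_id, field_id, arm_label, distance_to_reward_cm,
    direction); junction-labelled fields carry ``in_arm_tally = False``.
    """
    rows = []
    for f in fields:
        zone = maze.zone_label(f.center_u, f.arm_label, junction_halfwidth)
        rows.append({
            "unit_id": f.unit_id,
            "field_id": f.field_id,
            "arm_label": zone,
            "distance_to_reward_cm": float(maze.distance_to_reward(f.center_u)),
            "direction": f.direction,
            "in_arm_tally": zone in ("forced_side", "stem", "choice_side"),
        })
    return rows


def field_probability_by_distance(fields, maze: MazeGeometry,
                                  bin_width: float = 10.0,
                                  track_bin: float = 2.0):
    """Histogram of field-center probability vs distance from reward.

    Returns a dict of aligned arrays: ``distance_bin_cm`` (left edges),
    ``field_fraction`` (sums to 1 when any field exists) and ``track_bins``
    (how many physical ``track_bin``-cm track bins map into each distance
    bin — two lateral arms contribute twice per run coordinate), so that the
    probability can be normalized for track exposure.
    """
    if bin_width <= 0:
        raise MazeError("bin_width must be positive")
    edges = np.arange(0.0, maze.run_length + bin_width, bin_width)
    centers_d = np.array([maze.distance_to_reward(f.center_u) for f in fields])
    counts, _ = np.histogram(centers_d, bins=edges)
    frac = counts / len(fields) if len(fields) else counts.astype(float)

    # physical track exposure: each lateral arm counted on its own side
    u_grid = np.arange(track_bin / 2.0, maze.run_length, track_bin)
    a, s = maze.arm_length, maze.stem_length
    weights = np.where((u_grid < a) | (u_grid > a + s), 2.0, 1.0)
    exposure, _ = np.histogram(maze.distance_to_reward(u_grid), bins=edges,
                               weights=weights)
    return {
        "distance_bin_cm": edges[:-1],
        "field_fraction": frac,
        "track_bins": exposure,
    }
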