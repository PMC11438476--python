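"""Dyadic interpersonal coordination by vector coding.

For a dyad (pair of same-team players) and one pitch axis, each frame pair
yields a displacement vector (dA, dB): player A's frame-to-frame displacement
on the horizontal axis of the coding plane, player B's on the vertical.  The
coupling angle is the angle of that vector, mapped to [0, 360) degrees.

Angles on the positive diagonal — [22.5, 67.5) around 45 degrees and
[202.5, 247.5) around 225 — are in-phase (co-directed motion, e.g. both
players pressing forward).  Angles on the negative diagonal — [112.5, 157.5)
around 135 and [292.5, 337.5) around 315 — are anti-phase (opposed motion,
e.g. fullbacks splitting wide).  Everything else is "other".  Band bounds
are lower-inclusive.

Frames where BOTH displacements fall below a motion threshold epsilon are
excluded: the angle of a sub-noise vector is numerically meaningless.  If
only one player is quasi-static the angle is kept (it is a genuine axis
case).  Fractions are reported over valid frames; the excluded share is
reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .core import AlignmentError, CoordinationError, TrajectorySet, require_uniform_grid

AXES = ("longitudinal", "lateral")
_AXIS_COL = {"longitudinal": 0, "lateral": 1}

DEFAULT_EPSILON_M = 0.01  # meters per frame


@dataclass(frozen=True)
class PhaseBands:
    """Angular bands (degrees) for phase classification; lower-inclusive."""

    in_phase: tuple[tuple[float, float], ...] = ((22.5, 67.5), (202.5, 247.5))
    anti_phase: tuple[tuple[float, float], ...] = ((112.5, 157.5), (292.5, 337.5))

    def __post_init__(self) -> None:
        for lo, hi in self.in_phase + self.anti_phase:
            if not (0.0 <= lo < hi <= 360.0):
                raise ValueError("bands must lie within [0, 360)")


DEFAULT_BANDS = PhaseBands()


@dataclass
class DyadCoordination:
    dyad: tuple[str, str]
    axis: str
    coupling_angle_deg: np.ndarray  # NaN where excluded
    valid_frames: int
    excluded_frames: int
    pct_in_phase: float
    pct_anti_phase: float
    pct_other: float

    @property
    def pct_excluded(self) -> float:
        total = self.valid_frames + self.excluded_frames
        return 100.0 * self.excluded_frames / total if total else float("nan")


def displacement_series(values: np.ndarray, t: np.ndarray | None = None) -> np.ndarray:
    """Frame-to-frame displacement (first difference) of one coordinate.

    If ``t`` is given the grid must be uniform (displacements are only
    comparable across frames at a constant time step).
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size < 2:
        raise AlignmentError("need a 1-D series of at least 2 frames")
    if t is not None:
        require_uniform_grid(t)
    return np.diff(values)


def coupling_angle(d_a: np.ndarray, d_b: np.ndarray, epsilon_m: float = DEFAULT_EPSILON_M) -> np.ndarray:
    """Vector-coding coupling angle per frame, degrees in [0, 360).

    Player A's displacement lies on the horizontal axis, player B's on the
    vertical; the angle is measured counter-clockwise from the A-axis.
    Frames with both |dA| and |dB| below ``epsilon_m`` are NaN (excluded).
    """
    d_a = np.atleast_1d(np.asarray(d_a, dtype=float))
    d_b = np.atleast_1d(np.asarray(d_b, dtype=float))
    if d_a.shape != d_b.shape:
        raise AlignmentError("displacement series must be paired")
    ang = np.degrees(np.arctan2(d_b, d_a)) % 360.0
    still = (np.abs(d_a) < epsilon_m) & (np.abs(d_b) < epsilon_m)
    return np.where(still, np.nan, ang)


def classify_phase(angle, bands: PhaseBands = DEFAULT_BANDS) -> np.ndarray:
    """Classify angles (degrees in [0, 360)) as in_phase / anti_phase / other.

    NaN angles classify as "excluded".
    """
    a = np.atleast_1d(np.asarray(angle, dtype=float))
    if np.any((a < 0) | (a >= 360) & np.isfinite(a)):
        raise ValueError("angles must lie in [0, 360)")
    out = np.full(a.shape, "other", dtype=object)
    for lo, hi in bands.in_phase:
        out[(a >= lo) & (a < hi)] = "in_phase"
    for lo, hi in bands.anti_phase:
        out[(a >= lo) & (a < hi)] = "anti_phase"
    out[~np.isfinite(a)] = "excluded"
    return out if np.ndim(angle) else out.item()


def dyad_phase_fractions(
    xy_a: np.ndarray,
    xy_b: np.ndarray,
    axis: str,
    dyad: tuple[str, str] = ("A", "B"),
    epsilon_m: float = DEFAULT_EPSILON_M,
    bands: PhaseBands = DEFAULT_BANDS,
    t: np.ndarray | None = None,
) -> DyadCoordination:
    """Coupling-angle series and phase-class fractions for one dyad and axis.

    ``xy_a``/``xy_b`` are (n, 2) position series on a shared uniform grid.
    Fractions are percentages of valid (non-excluded) frames and sum to 100.
    """
    if axis not in _AXIS_COL:
        raise ValueError(f"axis must be one of {AXES}")
    col = _AXIS_COL[axis]
    d_a = displacement_series(np.asarray(xy_a, dtype=float)[:, col], t)
    d_b = displacement_series(np.asarray(xy_b, dtype=float)[:, col], t)
    finite = np.isfinite(d_a) & np.isfinite(d_b)
    ang = np.full(d_a.shape, np.nan)
    ang[finite] = coupling_angle(d_a[finite], d_b[finite], epsilon_m)
    valid = np.isfinite(ang)
    n_valid = int(valid.sum())
    n_excluded = int(finite.sum()) - n_valid
    if n_valid == 0:
        raise CoordinationError(
            f"dyad {dyad} has no valid coordination frames on axis {axis!r}"
        )
    labels = classify_phase(ang[valid], bands)
    n_in = int(np.sum(labels == "in_phase"))
    n_anti = int(np.sum(labels == "anti_phase"))
    return DyadCoordination(
        dyad=tuple(sorted(dyad)),
        axis=axis,
        coupling_angle_deg=ang,
        valid_frames=n_valid,
        excluded_frames=n_excluded,
        pct_in_phase=100.0 * n_in / n_valid,
        pct_anti_phase=100.0 * n_anti / n_valid,
        pct_other=100.0 * (n_valid - n_in - n_anti) / n_valid,
    )


def team_dyad_summary(
    traj: TrajectorySet,
    team: str,
    axis: str,
    epsilon_m: float = DEFAULT_EPSILON_M,
    bands: PhaseBands = DEFAULT_BANDS,
) -> tuple[list[DyadCoordination], dict[str, float]]:
    """All outfield dyads of a team plus the unweighted mean of the fractions.

    Four outfield players yield the 6 unordered pairs; the team-level value
    is the arithmetic mean of the dyad fractions (each dyad weighted
    equally, regardless of its valid-frame count).
    """
    idx = traj.team_indices(team, include_goalkeeper=False)
    if idx.size < 2:
        raise CoordinationError(f"team {team!r} needs >= 2 outfield players")
    dyads = []
    for i, j in combinations(idx, 2):
        dyads.append(
            dyad_phase_fractions(
                traj.xy[:, i, :],
                traj.xy[:, j, :],
                axis,
                dyad=(traj.players[i].player_id, traj.players[j].player_id),
                epsilon_m=epsilon_m,
                bands=bands,
                t=traj.t,
            )
        )
    team_mean = {
        "pct_in_phase": float(np.mean([d.pct_in_phase for d in dyads])),
        "pct_anti_phase": float(np.mean([d.pct_anti_phase for d in dyads])),
        "pct_other": float(np.mean([d.pct_other for d in dyads])),
        "pct_excluded": float(np.mean([d.pct_excluded for d in dyads])),
    }
    return dyads, team_mean


def coordination_table(
    traj: TrajectorySet,
    epsilon_m: float = DEFAULT_EPSILON_M,
    bands: PhaseBands = DEFAULT_BANDS,
    session: str = "s1",
    bout: str = "b1",
    condition: str = "FR",
) -> pd.DataFrame:
    """One row per (team, dyad, axis) for both teams and both axes."""
    recs = []
    for team in sorted({p.team for p in traj.players}):
        for axis in AXES:
            dyads, mean = team_dyad_summary(traj, team, axis, epsilon_m, bands)
            for d in dyads:
                recs.append(
                    {
                        "session": session,
                        "bout": bout,
                        "condition": condition,
                        "team": team,
                        "dyad": "-".join(d.dyad),
                        "axis": axis,
                        "pct_in_phase": d.pct_in_phase,
                        "pct_anti_phase": d.pct_anti_phase,
                        "pct_other": d.pct_other,
                        "pct_excluded": d.pct_excluded,
                        "valid_frames": d.valid_frames,
                        "excluded_frames": d.excluded_frames,
                    }
                )
    return pd.DataFrame(recs)
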