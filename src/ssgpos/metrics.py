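"""Collective and individual spatial-occupation metrics.

Per frame and per team (outfield players only, unless requested otherwise):

* length — longitudinal extent, ``max(x) - min(x)``;
* width — lateral extent, ``max(y) - min(y)``;
* LpW ratio — length / width, the team's preferred positional axis
  (> 1 means a deeper, elongated shape); undefined where width is zero;
* centroid — mean player position;
* stretch index — mean Euclidean distance of the players from the centroid
  (the conventional team-dispersion measure from the positional-analysis
  literature);
* inter-centroid distance — per-frame Euclidean distance between the two
  teams' centroids;
* SEI (spatial exploration index, per player) — mean Euclidean distance
  between the player's instantaneous position and their bout-mean position.

Frames on which any contributing player is unobserved (NaN) yield NaN
metrics and are excluded from bout means, as are frames where a ratio is
undefined; exclusion counts are reported rather than silently clamped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from .core import AlignmentError, CoordinationError, DataError, SSGPosError, TrajectorySet


@dataclass
class CollectiveMetricSeries:
    team: str
    t: np.ndarray
    length_m: np.ndarray
    width_m: np.ndarray
    lpw_ratio: np.ndarray  # NaN where width == 0
    centroid: np.ndarray  # (n, 2)
    stretch_index_m: np.ndarray
    n_players: int
    n_lpw_undefined: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_s": self.t,
                "team": self.team,
                "length_m": self.length_m,
                "width_m": self.width_m,
                "lpw": self.lpw_ratio,
                "centroid_x": self.centroid[:, 0],
                "centroid_y": self.centroid[:, 1],
                "stretch_m": self.stretch_index_m,
            }
        )


@dataclass
class InterTeamSeries:
    t: np.ndarray
    centroid_distance_m: np.ndarray


@dataclass
class SEIResult:
    player_id: str
    sei_m: float
    n_frames: int


@dataclass
class BoutSummary:
    """Time-averaged bout row feeding the repeated-measures stage."""

    session: str
    bout: str
    condition: str
    team_means: dict[str, dict[str, float]]  # team -> variable -> mean
    centroid_distance_mean_m: float
    sei: list[SEIResult]
    n_excluded: dict[str, int] = field(default_factory=dict)


def collective_frame_metrics(
    traj: TrajectorySet, team: str, include_goalkeeper: bool = False
) -> CollectiveMetricSeries:
    """Per-frame extent, centroid and stretch index for one team."""
    idx = traj.team_indices(team, include_goalkeeper=include_goalkeeper)
    if idx.size < 2:
        raise CoordinationError(
            f"team {team!r} needs at least 2 players on the grid, has {idx.size}"
        )
    pts = traj.xy[:, idx, :]  # (n, m, 2)
    observed = np.all(np.isfinite(pts), axis=(1, 2))
    x = pts[:, :, 0]
    y = pts[:, :, 1]
    with np.errstate(invalid="ignore"):
        length = np.nanmax(x, axis=1) - np.nanmin(x, axis=1)
        width = np.nanmax(y, axis=1) - np.nanmin(y, axis=1)
    length = np.where(observed, length, np.nan)
    width = np.where(observed, width, np.nan)
    centroid = np.where(observed[:, None], pts.mean(axis=1), np.nan)
    stretch = np.where(
        observed,
        np.linalg.norm(pts - centroid[:, None, :], axis=2).mean(axis=1),
        np.nan,
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        lpw = np.where(width > 0, length / width, np.nan)
    n_undef = int(np.sum(observed & ~(width > 0)))
    return CollectiveMetricSeries(
        team=team,
        t=traj.t.copy(),
        length_m=length,
        width_m=width,
        lpw_ratio=lpw,
        centroid=centroid,
        stretch_index_m=stretch,
        n_players=int(idx.size),
        n_lpw_undefined=n_undef,
    )


def centroid_distance(
    team_a: CollectiveMetricSeries, team_b: CollectiveMetricSeries
) -> InterTeamSeries:
    """Per-frame Euclidean distance between the two team centroids."""
    if team_a.t.shape != team_b.t.shape or not np.allclose(team_a.t, team_b.t):
        raise AlignmentError("team metric series are not on the same time grid")
    d = np.linalg.norm(team_a.centroid - team_b.centroid, axis=1)
    return InterTeamSeries(t=team_a.t.copy(), centroid_distance_m=d)


def spatial_exploration_index(xy: np.ndarray) -> float:
    """SEI of one position series: mean distance to the bout-mean position.

    Zero iff the player never moves.  NaN frames are ignored.
    """
    xy = np.asarray(xy, dtype=float)
    finite = np.all(np.isfinite(xy), axis=1)
    pts = xy[finite]
    if pts.shape[0] < 2:
        raise DataError("SEI needs at least 2 observed frames")
    mean_pos = pts.mean(axis=0)
    return float(np.linalg.norm(pts - mean_pos, axis=1).mean())


def sei(traj: TrajectorySet, include_goalkeeper: bool = False) -> list[SEIResult]:
    """Per-player SEI over the bout."""
    out = []
    for i, p in enumerate(traj.players):
        if p.role == "goalkeeper" and not include_goalkeeper:
            continue
        xy = traj.xy[:, i, :]
        n = int(np.all(np.isfinite(xy), axis=1).sum())
        out.append(SEIResult(p.player_id, spatial_exploration_index(xy), n))
    return out


def area_per_player(length_m: float, width_m: float, n_players: int) -> float:
    """Pitch area divided by the number of players (goalkeepers included)."""
    if length_m <= 0 or width_m <= 0:
        raise ValueError("pitch dimensions must be positive")
    if n_players < 1:
        raise ValueError("need at least one player")
    return length_m * width_m / n_players


def summarize_bout(
    traj: TrajectorySet,
    session: str = "s1",
    bout: str = "b1",
    condition: str = "FR",
    include_goalkeeper: bool = False,
) -> BoutSummary:
    """Time means of every collective variable per team, plus per-player SEI.

    Undefined frames (NaN metric, e.g. zero-width LpW) are excluded from the
    means; the exclusion count per variable is reported.
    """
    teams = sorted({p.team for p in traj.players})
    series = {
        tm: collective_frame_metrics(traj, tm, include_goalkeeper) for tm in teams
    }
    team_means: dict[str, dict[str, float]] = {}
    n_excluded: dict[str, int] = {}
    for tm, s in series.items():
        means = {}
        if not np.isfinite(s.length_m).any():
            raise SSGPosError(f"team {tm} has no fully observed frames")
        for name, arr in (
            ("length_m", s.length_m),
            ("width_m", s.width_m),
            ("lpw", s.lpw_ratio),
            ("stretch_m", s.stretch_index_m),
        ):
            finite = np.isfinite(arr)
            # a ratio can be undefined on every frame (zero width throughout)
            means[name] = float(arr[finite].mean()) if finite.any() else float("nan")
            n_excluded[f"{tm}:{name}"] = int((~finite).sum())
        team_means[tm] = means
    if len(teams) == 2:
        inter = centroid_distance(series[teams[0]], series[teams[1]])
        d = inter.centroid_distance_m
        cd_mean = float(d[np.isfinite(d)].mean())
    else:
        cd_mean = float("nan")
    return BoutSummary(
        session=session,
        bout=bout,
        condition=condition,
        team_means=team_means,
        centroid_distance_mean_m=cd_mean,
        sei=sei(traj, include_goalkeeper),
        n_excluded=n_excluded,
    )


def bout_summary_row(summary: BoutSummary, traj: TrajectorySet) -> pd.DataFrame:
    """Flatten a BoutSummary into one row per team (wide format)."""
    sei_by_player = {s.player_id: s.sei_m for s in summary.sei}
    recs = []
    for tm, means in summary.team_means.items():
        ids = [p.player_id for p in traj.players if p.team == tm and p.role == "outfield"]
        rec = {
            "session": summary.session,
            "bout": summary.bout,
            "condition": summary.condition,
            "team": tm,
            "length_mean_m": means["length_m"],
            "width_mean_m": means["width_m"],
            "lpw_mean": means["lpw"],
            "stretch_mean_m": means["stretch_m"],
            "centroid_dist_mean_m": summary.centroid_distance_mean_m,
            "sei_mean_m": float(np.mean([sei_by_player[i] for i in ids if i in sei_by_player])),
        }
        recs.append(rec)
    return pd.DataFrame(recs)
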