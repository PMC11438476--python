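"""Shared containers and error types for the tracking-analysis pipeline.

The central container is :class:`TrajectorySet`: all players of a bout on a
single uniform time grid, positions in planar meters.  Whether those meters
are raw UTM easting/northing or pitch-aligned field coordinates is a matter
of which stage produced the object; the container itself is frame-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

TEAMS = ("A", "B")
ROLES = ("outfield", "goalkeeper")


class SSGPosError(Exception):
    """Base class for all pipeline errors."""


class FormatError(SSGPosError):
    """Malformed input file (missing column, bad dialect)."""


class DataError(SSGPosError):
    """Input violates a data contract (duplicate/non-monotone timestamps...)."""


class CalibrationError(SSGPosError):
    """Field-vertex calibration is degenerate or not rectangular."""


class UnsupportedRegionError(SSGPosError):
    """Coordinates outside the supported projection domain."""


class CoverageError(SSGPosError):
    """A player's samples cover too little of the bout to be usable."""


class FilterError(SSGPosError):
    """A segment is too short to be filtered."""


class AlignmentError(SSGPosError):
    """Series are not on the same (uniform) time grid."""


class CoordinationError(SSGPosError):
    """A dyad or team has no usable coordination frames/players."""


class ParameterError(SSGPosError):
    """Invalid simulation or analysis parameters."""


class BalanceError(SSGPosError):
    """Repeated-measures table has missing cells."""


class DegenerateVarianceError(SSGPosError):
    """A statistic is undefined because the data have no variance."""


@dataclass(frozen=True)
class PlayerInfo:
    """Identity and role of one tracked player."""

    player_id: str
    team: str
    role: str = "outfield"

    def __post_init__(self) -> None:
        if self.team not in TEAMS:
            raise DataError(f"unknown team {self.team!r}; expected one of {TEAMS}")
        if self.role not in ROLES:
            raise DataError(f"unknown role {self.role!r}; expected one of {ROLES}")


@dataclass
class PlanarSeries:
    """One player's (possibly irregular) planar position samples, meters."""

    player: PlayerInfo
    t: np.ndarray  # (n,) seconds, strictly increasing
    xy: np.ndarray  # (n, 2) meters

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.xy = np.asarray(self.xy, dtype=float)
        if self.t.ndim != 1 or self.xy.shape != (self.t.size, 2):
            raise DataError("t must be (n,), xy must be (n, 2)")
        if self.t.size < 2:
            raise DataError("a series needs at least 2 samples")
        if np.any(np.diff(self.t) <= 0):
            raise DataError(f"non-monotone time for player {self.player.player_id!r}")


@dataclass
class TrajectorySet:
    """All players of a bout on one uniform grid.

    Attributes
    ----------
    players : list of PlayerInfo
    t : (n_frames,) seconds
    xy : (n_frames, n_players, 2) meters; NaN marks unobserved frames
    fs : sampling rate, Hz
    """

    players: list[PlayerInfo]
    t: np.ndarray
    xy: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.xy = np.asarray(self.xy, dtype=float)
        if self.xy.shape != (self.t.size, len(self.players), 2):
            raise DataError(
                f"xy shape {self.xy.shape} inconsistent with "
                f"{self.t.size} frames x {len(self.players)} players"
            )
        if self.fs <= 0:
            raise DataError("fs must be positive")

    @property
    def n_frames(self) -> int:
        return self.t.size

    def index_of(self, player_id: str) -> int:
        for i, p in enumerate(self.players):
            if p.player_id == player_id:
                return i
        raise KeyError(player_id)

    def team_indices(self, team: str, include_goalkeeper: bool = False) -> np.ndarray:
        idx = [
            i
            for i, p in enumerate(self.players)
            if p.team == team and (include_goalkeeper or p.role == "outfield")
        ]
        return np.asarray(idx, dtype=int)

    def player_xy(self, player_id: str) -> np.ndarray:
        return self.xy[:, self.index_of(player_id), :]

    def subset(self, indices: Sequence[int] | np.ndarray) -> "TrajectorySet":
        indices = np.asarray(indices, dtype=int)
        return TrajectorySet(
            players=[self.players[i] for i in indices],
            t=self.t.copy(),
            xy=self.xy[:, indices, :].copy(),
            fs=self.fs,
        )

    def to_dataframe(self) -> pd.DataFrame:
        """Long canonical form: t_s, player_id, team, role, x_m, y_m."""
        frames = []
        for i, p in enumerate(self.players):
            frames.append(
                pd.DataFrame(
                    {
                        "t_s": self.t,
                        "player_id": p.player_id,
                        "team": p.team,
                        "role": p.role,
                        "x_m": self.xy[:, i, 0],
                        "y_m": self.xy[:, i, 1],
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, fs: float) -> "TrajectorySet":
        required = {"t_s", "player_id", "team", "role", "x_m", "y_m"}
        missing = required - set(df.columns)
        if missing:
            raise FormatError(f"missing columns: {sorted(missing)}")
        t = np.sort(df["t_s"].unique())
        players: list[PlayerInfo] = []
        cols = []
        for pid, sub in df.groupby("player_id", sort=True):
            sub = sub.sort_values("t_s")
            if sub.shape[0] != t.size or not np.allclose(sub["t_s"].to_numpy(), t):
                raise AlignmentError(f"player {pid!r} not on the shared time grid")
            players.append(
                PlayerInfo(str(pid), str(sub["team"].iloc[0]), str(sub["role"].iloc[0]))
            )
            cols.append(sub[["x_m", "y_m"]].to_numpy())
        xy = np.stack(cols, axis=1)
        return cls(players=players, t=t, xy=xy, fs=fs)


def require_uniform_grid(t: np.ndarray, rtol: float = 1e-6) -> float:
    """Return the grid step of a uniform time vector, or raise AlignmentError."""
    t = np.asarray(t, dtype=float)
    if t.size < 2:
        raise AlignmentError("need at least 2 time samples")
    dt = np.diff(t)
    if dt.min() <= 0 or (dt.max() - dt.min()) > rtol * dt.mean():
        raise AlignmentError("time grid is not uniform")
    return float(dt.mean())
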