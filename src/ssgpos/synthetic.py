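"""Synthetic two-team tracking-data generator with known ground truth.

Each player's position is a discretized mean-reverting (Ornstein-Uhlenbeck
style) excursion around a moving target

    target_t = anchor + kappa * g_t * e_x,

where ``g_t`` is a team-shared, band-limited longitudinal drive (a sum of
low-frequency sinusoids with random phases, unit RMS, all spectral content
below the 0.5 Hz analysis cutoff so the preprocessing filter cannot destroy
the planted coupling).  The three generator dials map one-to-one onto the
three phenomena the analysis measures:

* ``coupling_gain`` (kappa, meters) — amplitude of the shared longitudinal
  drive; raising it raises within-team in-phase coordination;
* ``exploration_sd`` (sigma, meters) — stationary standard deviation of the
  per-player excursion; raising it raises the spatial exploration index;
* ``spread_gain`` — scales the anchor dispersion around the team center;
  raising it raises team length and width.

Positions are softly reflected into the pitch extended by a 2 m margin
(real GPS positions stray slightly out of bounds).  Identical seeds give
bit-identical output.

This is a phenomenological generator for exercising the pipeline, not a
model of player cognition: there is no ball, no opponent interaction, and
experimental conditions are emulated purely through parameter presets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import signal

from .core import ParameterError, PlayerInfo, TrajectorySet
from .coordination import coordination_table
from .ingest import RawGeoSeries, utm_forward, utm_inverse, utm_zone
from .metrics import bout_summary_row, summarize_bout

PITCH_LENGTH_M = 42.0
PITCH_WIDTH_M = 29.0
BOUND_MARGIN_M = 2.0

# Diamond formation offsets from the team center, one per outfield player.
_FORMATION = np.array([[-6.0, 0.0], [6.0, 0.0], [0.0, -6.0], [0.0, 6.0]])
_TEAM_CENTER_X = {"A": 14.0, "B": 28.0}
_GK_X = {"A": 1.0, "B": 41.0}


def default_anchors(
    spread_gain: float = 1.0, include_goalkeepers: bool = False
) -> dict[str, np.ndarray]:
    """Per-player home positions: a diamond per team, goalkeepers near goal."""
    anchors: dict[str, np.ndarray] = {}
    for team in ("A", "B"):
        center = np.array([_TEAM_CENTER_X[team], PITCH_WIDTH_M / 2.0])
        offs = _FORMATION * spread_gain
        if team == "B":
            offs = offs * np.array([-1.0, 1.0])  # mirror longitudinally
        for k in range(offs.shape[0]):
            anchors[f"{team}{k + 1}"] = center + offs[k]
        if include_goalkeepers:
            anchors[f"{team}GK"] = np.array([_GK_X[team], PITCH_WIDTH_M / 2.0])
    return anchors


@dataclass
class SimulationParams:
    """Study-condition parameters: 4 vs 4 (+GK) on 42 x 29 m, 10 Hz, 4 min."""

    length_m: float = PITCH_LENGTH_M
    width_m: float = PITCH_WIDTH_M
    n_outfield_per_team: int = 4
    include_goalkeepers: bool = False
    fs_hz: float = 10.0
    duration_s: float = 240.0
    spread_gain: float = 1.0
    coupling_gain: float = 2.0  # kappa, meters of shared longitudinal drive
    exploration_sd: float = 5.6  # sigma, meters, stationary excursion sd
    mean_reversion: float = 0.15  # theta, 1/s
    drive_freq_band_hz: tuple[float, float] = (0.04, 0.20)
    n_drive_components: int = 6
    anchors: dict[str, np.ndarray] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coupling_gain < 0 or self.exploration_sd < 0:
            raise ParameterError("gains must be non-negative")
        if self.mean_reversion <= 0:
            raise ParameterError("mean_reversion must be positive")
        if self.fs_hz <= 0 or self.duration_s <= 0:
            raise ParameterError("fs and duration must be positive")
        n_frames = self.duration_s * self.fs_hz
        if abs(n_frames - round(n_frames)) > 1e-9:
            raise ParameterError("duration_s * fs_hz must be an integer frame count")
        lo, hi = self.drive_freq_band_hz
        if not 0 < lo < hi < self.fs_hz / 2:
            raise ParameterError("drive band must lie in (0, Nyquist)")

    def resolved_anchors(self) -> dict[str, np.ndarray]:
        anchors = self.anchors or default_anchors(
            self.spread_gain, self.include_goalkeepers
        )
        for pid, a in anchors.items():
            a = np.asarray(a, dtype=float)
            if not (0 <= a[0] <= self.length_m and 0 <= a[1] <= self.width_m):
                raise ParameterError(f"anchor for {pid!r} outside the pitch: {a}")
        return {pid: np.asarray(a, dtype=float) for pid, a in anchors.items()}


@dataclass
class GroundTruth:
    """What the generator planted, for verification against recovered values."""

    params: SimulationParams
    drive: dict[str, np.ndarray]  # team -> g_t (unit RMS)
    anchors: dict[str, np.ndarray]
    expected_orderings: tuple[str, ...] = (
        "coupling_gain up -> longitudinal in-phase up",
        "exploration_sd up -> SEI up",
        "spread_gain up -> length and width up",
    )


def _band_limited_drive(
    rng: np.random.Generator, n: int, fs: float, band: tuple[float, float], k: int
) -> np.ndarray:
    """Unit-RMS sum of k sinusoids with random frequencies/phases in band."""
    t = np.arange(n) / fs
    freqs = rng.uniform(band[0], band[1], size=k)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=k)
    g = np.sum(np.sin(2.0 * np.pi * freqs[:, None] * t[None, :] + phases[:, None]), axis=0)
    rms = np.sqrt(np.mean(g**2))
    return g / rms if rms > 0 else g


def _soft_reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold positions into [lo, hi] by reflection (triangle-wave map)."""
    span = hi - lo
    y = np.mod(x - lo, 2.0 * span)
    return lo + np.where(y > span, 2.0 * span - y, y)


_EXPLORATION_CUTOFF_HZ = 0.45  # keep all planted motion below the 0.5 Hz analysis cutoff


def _exploration_filter(fs: float) -> np.ndarray:
    return signal.butter(2, _EXPLORATION_CUTOFF_HZ, fs=fs, output="sos")


def _smoothing_variance_factor(phi: float, fs: float, n: int) -> float:
    """Std retained when the band-limiting filter acts on a stationary AR(1).

    Computed from the AR(1) power spectrum and the zero-phase filter's
    squared magnitude response, so the generator can renormalize the smoothed
    excursions back to the requested stationary standard deviation.
    """
    w = np.linspace(0.0, np.pi, 2049)
    s_ar1 = 1.0 / (1.0 + phi * phi - 2.0 * phi * np.cos(w))  # shape only
    _, h = signal.sosfreqz(_exploration_filter(fs), worN=w)
    gain2 = np.abs(h) ** 4  # forward-backward pass
    return float(np.sqrt(np.trapezoid(s_ar1 * gain2, w) / np.trapezoid(s_ar1, w)))


def simulate_bout(params: SimulationParams) -> tuple[TrajectorySet, GroundTruth]:
    """Simulate one bout; identical params (incl. seed) give identical output."""
    rng = np.random.default_rng(params.seed)
    n = int(round(params.duration_s * params.fs_hz))
    dt = 1.0 / params.fs_hz
    anchors = params.resolved_anchors()
    players = [
        PlayerInfo(pid, pid[0], "goalkeeper" if pid.endswith("GK") else "outfield")
        for pid in anchors
    ]

    drive = {
        team: _band_limited_drive(
            rng, n, params.fs_hz, params.drive_freq_band_hz, params.n_drive_components
        )
        for team in ("A", "B")
    }

    phi = np.exp(-params.mean_reversion * dt)  # AR(1) coefficient
    innov_sd = np.sqrt(max(0.0, 1.0 - phi * phi))
    sos = _exploration_filter(params.fs_hz)
    retain = _smoothing_variance_factor(phi, params.fs_hz, n)
    padlen = min(int(3 * params.fs_hz / _EXPLORATION_CUTOFF_HZ), n - 1)

    xy = np.empty((n, len(players), 2))
    for j, p in enumerate(players):
        sigma = params.exploration_sd
        kappa = params.coupling_gain
        if p.role == "goalkeeper":
            sigma = 0.15 * params.exploration_sd  # goalkeepers barely roam
            kappa = 0.0
        # stationary AR(1) excursion (exact OU discretization), band-limited
        # like real smoothed trajectories, renormalized to stationary sd sigma
        z = rng.standard_normal((n, 2))
        z[0] *= 1.0 / innov_sd if innov_sd > 0 else 0.0  # stationary start
        if sigma > 0 and innov_sd > 0:
            e = signal.lfilter([innov_sd], [1.0, -phi], z, axis=0)
            e = signal.sosfiltfilt(sos, e, axis=0, padlen=padlen) * (sigma / retain)
        else:
            e = np.zeros((n, 2))
        pos = anchors[p.player_id][None, :] + e
        pos[:, 0] += kappa * drive[p.team]
        xy[:, j, 0] = _soft_reflect(pos[:, 0], -BOUND_MARGIN_M, params.length_m + BOUND_MARGIN_M)
        xy[:, j, 1] = _soft_reflect(pos[:, 1], -BOUND_MARGIN_M, params.width_m + BOUND_MARGIN_M)

    traj = TrajectorySet(players=players, t=np.arange(n) * dt, xy=xy, fs=params.fs_hz)
    return traj, GroundTruth(params=params, drive=drive, anchors=anchors)


# ---------------------------------------------------------------------------
# Condition presets and repeated-measures fixtures
# ---------------------------------------------------------------------------

CONDITIONS = ("FR", "R1", "R2", "R3")


def condition_presets(base: SimulationParams | None = None) -> dict[str, SimulationParams]:
    """Parameter presets emulating the four experimental conditions.

    FR is free play.  R1 (explicit high-press rule) plants the strongest
    shared longitudinal drive, the widest exploration and a slightly larger
    spread; R2 (implicit rule) plants a strong drive with near-baseline
    exploration; R3 (both rules) sits between R1 and FR.  The orderings —
    not the absolute values — are the emulated phenomena.
    """
    base = base or SimulationParams()
    knobs = {
        "FR": dict(coupling_gain=2.0, exploration_sd=5.6, spread_gain=1.00),
        "R1": dict(coupling_gain=3.6, exploration_sd=6.3, spread_gain=1.15),
        "R2": dict(coupling_gain=2.8, exploration_sd=5.7, spread_gain=1.00),
        "R3": dict(coupling_gain=2.2, exploration_sd=5.9, spread_gain=1.05),
    }
    return {cond: replace(base, **kw) for cond, kw in knobs.items()}


def _child_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


def make_condition_dataset(
    params_by_condition: Mapping[str, SimulationParams] | None = None,
    n_sessions: int = 4,
    n_bouts: int = 1,
    base_seed: int = 0,
    with_coordination: bool = True,
) -> pd.DataFrame:
    """Balanced repeated-measures table of bout summaries per (team, condition).

    Each session contributes two units (teams A and B); every unit meets
    every condition ``n_bouts`` times with seeds derived deterministically
    from ``base_seed``.  Returns one wide row per (session, team, condition,
    bout) with the collective means, team-mean SEI and (optionally) the
    team-mean coordination fractions per axis.
    """
    if params_by_condition is None:
        params_by_condition = condition_presets()
    if len(params_by_condition) < 2:
        raise ParameterError("need at least 2 conditions")
    if n_bouts < 1 or n_sessions < 1:
        raise ParameterError("n_sessions and n_bouts must be >= 1")

    root = np.random.SeedSequence(base_seed)
    rows = []
    for s_idx, child_s in enumerate(root.spawn(n_sessions)):
        cond_seeds = child_s.spawn(len(params_by_condition))
        for (cond, params), cs in zip(params_by_condition.items(), cond_seeds):
            for b_idx, bs in enumerate(cs.spawn(n_bouts)):
                p = replace(params, seed=_child_seed(bs))
                traj, _ = simulate_bout(p)
                summary = summarize_bout(
                    traj,
                    session=f"s{s_idx + 1}",
                    bout=f"b{b_idx + 1}",
                    condition=cond,
                )
                wide = bout_summary_row(summary, traj)
                if with_coordination:
                    coord = coordination_table(
                        traj, session=f"s{s_idx + 1}", bout=f"b{b_idx + 1}", condition=cond
                    )
                    team_axis = (
                        coord.groupby(["team", "axis"])[["pct_in_phase", "pct_anti_phase"]]
                        .mean()
                        .reset_index()
                    )
                    for _, r in team_axis.iterrows():
                        ax = "long" if r["axis"] == "longitudinal" else "lat"
                        wide.loc[wide["team"] == r["team"], f"in_phase_{ax}_pct"] = r[
                            "pct_in_phase"
                        ]
                        wide.loc[wide["team"] == r["team"], f"anti_phase_{ax}_pct"] = r[
                            "pct_anti_phase"
                        ]
                rows.append(wide)
    return pd.concat(rows, ignore_index=True)


def condition_matrix(
    dataset: pd.DataFrame, variable: str, conditions: tuple[str, ...] | None = None
) -> tuple[np.ndarray, list[str]]:
    """Pivot a condition dataset to a units x k matrix (bouts averaged).

    The unit of analysis is (session, team).  Raises if any cell is missing.
    """
    conditions = conditions or tuple(sorted(dataset["condition"].unique()))
    piv = dataset.pivot_table(
        index=["session", "team"], columns="condition", values=variable, aggfunc="mean"
    )
    missing = [c for c in conditions if c not in piv.columns]
    if missing or piv[list(conditions)].isna().any().any():
        raise ParameterError("condition dataset is not balanced")
    units = ["/".join(map(str, ix)) for ix in piv.index]
    return piv[list(conditions)].to_numpy(), units


# ---------------------------------------------------------------------------
# Inverse projection: field meters -> raw WGS84, for round-trip tests
# ---------------------------------------------------------------------------


def to_raw_geo(
    traj: TrajectorySet, anchor_lat: float, anchor_lon: float
) -> list[RawGeoSeries]:
    """Express field coordinates as WGS84 lat/lon around an anchor corner.

    The field x axis is laid along UTM grid east and y along grid north with
    the (0, 0) pitch corner at the anchor, then positions are inverse-
    projected.  Round-tripping through ingestion recovers planar positions
    to well under a centimeter for pitch-sized extents.
    """
    if abs(anchor_lat) >= 84.0:
        from .core import UnsupportedRegionError

        raise UnsupportedRegionError("polar anchors are outside the UTM domain")
    zone = utm_zone(anchor_lon)
    e0, n0, _ = utm_forward(anchor_lat, anchor_lon, zone=zone)
    out = []
    for j, p in enumerate(traj.players):
        e = e0 + traj.xy[:, j, 0]
        n = n0 + traj.xy[:, j, 1]
        lat, lon = utm_inverse(e, n, zone=zone, northern=anchor_lat >= 0)
        out.append(RawGeoSeries(player=p, t=traj.t.copy(), lat=lat, lon=lon))
    return out


def write_raw_geo_csv(series: list[RawGeoSeries], path) -> None:
    """Write raw series in the canonical geographic CSV dialect."""
    frames = [
        pd.DataFrame(
            {
                "t_s": s.t,
                "player_id": s.player.player_id,
                "team": s.player.team,
                "role": s.player.role,
                "lat": s.lat,
                "lon": s.lon,
            }
        )
        for s in series
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
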