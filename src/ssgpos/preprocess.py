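"""Temporal regularization and trajectory smoothing.

Players are re-gridded onto a common uniform 10 Hz time base (small dropouts
linearly interpolated, long dropouts split into segments) and then smoothed
with a second-order 0.5 Hz Butterworth low-pass, the standard treatment for
10 Hz GPS position streams.  Zero-phase (forward-backward) filtering is the
default so positions are not lagged; a causal mode is kept for sensitivity
checks.  Zero-phase filtering applies the filter twice, so the effective
magnitude response is the squared single-pass response.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal

from .core import (
    CoverageError,
    FilterError,
    PlanarSeries,
    TrajectorySet,
    require_uniform_grid,
)


@dataclass
class FilterSpec:
    """Butterworth low-pass specification."""

    order: int = 2
    cutoff_hz: float = 0.5
    fs_hz: float = 10.0
    mode: str = "zero_phase"  # or "causal"

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("filter order must be >= 1")
        if not 0.0 < self.cutoff_hz < self.fs_hz / 2.0:
            raise ValueError("cutoff must lie in (0, fs/2)")
        if self.mode not in ("zero_phase", "causal"):
            raise ValueError(f"unknown filter mode {self.mode!r}")

    def sos(self) -> np.ndarray:
        return signal.butter(self.order, self.cutoff_hz, fs=self.fs_hz, output="sos")


@dataclass
class GapEvent:
    player_id: str
    gap_start_s: float
    gap_len_s: float
    action: str  # "interpolated" | "segment_split"


@dataclass
class GapReport:
    events: list[GapEvent] = field(default_factory=list)
    unfiltered_segments: list[tuple[str, float, float]] = field(default_factory=list)

    def for_player(self, player_id: str) -> list[GapEvent]:
        return [e for e in self.events if e.player_id == player_id]

    def to_json(self) -> str:
        return json.dumps(
            {
                "events": [vars(e) for e in self.events],
                "unfiltered_segments": [
                    {"player_id": p, "start_s": a, "end_s": b}
                    for p, a, b in self.unfiltered_segments
                ],
            },
            indent=2,
        )


def regularize(
    series: Sequence[PlanarSeries],
    fs_hz: float = 10.0,
    max_gap_s: float = 0.5,
    min_coverage: float = 0.5,
) -> tuple[TrajectorySet, GapReport]:
    """Resample all players onto one uniform grid spanning the bout.

    The grid runs from the earliest to the latest observed sample at
    ``fs_hz``.  Within a player's observed span, sample-to-sample gaps no
    longer than ``max_gap_s`` are bridged by linear interpolation; longer
    gaps leave NaN frames and are reported as segment splits (downstream
    metrics treat NaN frames as unobserved).  Interpolation never
    extrapolates: frames before a player's first or after their last sample
    stay NaN.
    """
    if not series:
        raise CoverageError("no series to regularize")
    t0 = min(float(s.t[0]) for s in series)
    t1 = max(float(s.t[-1]) for s in series)
    n = int(round((t1 - t0) * fs_hz)) + 1
    grid = t0 + np.arange(n) / fs_hz

    report = GapReport()
    xy = np.full((n, len(series), 2), np.nan)
    for j, s in enumerate(series):
        pid = s.player.player_id
        inside = (grid >= s.t[0] - 1e-9) & (grid <= s.t[-1] + 1e-9)
        for k in range(2):
            xy[inside, j, k] = np.interp(grid[inside], s.t, s.xy[:, k])
        # gaps between consecutive observed samples
        dts = np.diff(s.t)
        step = 1.0 / fs_hz
        for i, dt in enumerate(dts):
            if dt <= step * (1 + 1e-6):
                continue
            action = "interpolated" if dt <= max_gap_s + 1e-9 else "segment_split"
            if action == "segment_split":
                inner = (grid > s.t[i] + 1e-9) & (grid < s.t[i + 1] - 1e-9)
                xy[inner, j, :] = np.nan
            report.events.append(GapEvent(pid, float(s.t[i]), float(dt), action))
        coverage = np.isfinite(xy[:, j, 0]).mean()
        if coverage < min_coverage:
            raise CoverageError(
                f"player {pid!r} covers {coverage:.0%} of the bout (< {min_coverage:.0%})"
            )
    traj = TrajectorySet(
        players=[s.player for s in series], t=grid, xy=xy, fs=fs_hz
    )
    return traj, report


def _contiguous_segments(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, stop) index pairs of True runs."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return list(zip(idx[0::2], idx[1::2]))


def lowpass(traj: TrajectorySet, spec: FilterSpec | None = None) -> tuple[TrajectorySet, GapReport]:
    """Filter every coordinate channel, per contiguous observed segment.

    Segments shorter than ~3 filter orders cannot be filtered stably; they
    are left unfiltered and flagged in the report rather than dropped.
    Reflective padding of about three filter time constants suppresses edge
    transients at segment boundaries.
    """
    spec = spec or FilterSpec(fs_hz=traj.fs)
    sos = spec.sos()
    out = traj.xy.copy()
    report = GapReport()
    min_len = 3 * spec.order + 1
    padlen = int(3.0 * spec.fs_hz / spec.cutoff_hz)
    for j, p in enumerate(traj.players):
        finite = np.isfinite(traj.xy[:, j, 0]) & np.isfinite(traj.xy[:, j, 1])
        for a, b in _contiguous_segments(finite):
            seg = traj.xy[a:b, j, :]
            if b - a <= min_len:
                report.unfiltered_segments.append(
                    (p.player_id, float(traj.t[a]), float(traj.t[b - 1]))
                )
                continue
            if spec.mode == "zero_phase":
                out[a:b, j, :] = signal.sosfiltfilt(
                    sos, seg, axis=0, padtype="even", padlen=min(padlen, b - a - 1)
                )
            else:
                # causal: initialize at the first sample's steady state so the
                # filter does not ring in from zero
                zi = signal.sosfilt_zi(sos)[:, :, None] * seg[0][None, None, :]
                out[a:b, j, :], _ = signal.sosfilt(sos, seg, axis=0, zi=zi)
    filtered = TrajectorySet(
        players=list(traj.players), t=traj.t.copy(), xy=out, fs=traj.fs
    )
    return filtered, report


def butterworth_gain(f_hz: float, spec: FilterSpec) -> float:
    """Closed-form magnitude response of the digital Butterworth filter.

    The bilinear design (cutoff-prewarped) has exactly
    |H| = 1 / sqrt(1 + (tan(pi f/fs) / tan(pi fc/fs))^(2*order)),
    which reduces to the analog 1 / sqrt(1 + (f/fc)^(2*order)) for
    frequencies well below Nyquist and keeps the -3 dB point at the cutoff.
    Squared in zero-phase mode because the filter runs forward and backward.
    """
    ratio = np.tan(np.pi * f_hz / spec.fs_hz) / np.tan(
        np.pi * spec.cutoff_hz / spec.fs_hz
    )
    g = 1.0 / np.sqrt(1.0 + ratio ** (2 * spec.order))
    return float(g * g) if spec.mode == "zero_phase" else float(g)
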