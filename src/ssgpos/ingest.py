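"""Raw tracking ingestion: CSV reading, UTM projection, field-frame alignment.

Wearable GPS units report WGS84 latitude/longitude.  Tactical metrics need
planar meters in a pitch-aligned frame (x along the pitch length, y along the
width), so ingestion proceeds: read per-player samples, project to UTM
easting/northing, then re-express in a frame calibrated from the four pitch
vertices.

The transverse Mercator projection is implemented with the Krüger series in
the third flattening (6th order), accurate to well under a millimeter for
UTM's 3-degree half-width; zone and false easting follow the UTM convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    CalibrationError,
    DataError,
    FormatError,
    PlanarSeries,
    PlayerInfo,
    TrajectorySet,
    UnsupportedRegionError,
)

# ---------------------------------------------------------------------------
# WGS84 / UTM constants
# ---------------------------------------------------------------------------

WGS84_A = 6378137.0
WGS84_F = 1.0 / 298.257223563
UTM_K0 = 0.9996
UTM_FALSE_EASTING = 500_000.0
UTM_FALSE_NORTHING_SOUTH = 10_000_000.0
UTM_LAT_LIMIT = 84.0  # UTM is undefined in the polar caps

_N = WGS84_F / (2.0 - WGS84_F)  # third flattening
_E2 = WGS84_F * (2.0 - WGS84_F)  # first eccentricity squared
_E = np.sqrt(_E2)

# Rectifying-radius prefactor and the Krüger alpha/beta coefficients
# (series in the third flattening n, 6th order).
_A_RECT = WGS84_A / (1.0 + _N) * (
    1.0 + _N**2 / 4.0 + _N**4 / 64.0 + _N**6 / 256.0
)

_ALPHA = np.array(
    [
        _N / 2 - 2 * _N**2 / 3 + 5 * _N**3 / 16 + 41 * _N**4 / 180
        - 127 * _N**5 / 288 + 7891 * _N**6 / 37800,
        13 * _N**2 / 48 - 3 * _N**3 / 5 + 557 * _N**4 / 1440
        + 281 * _N**5 / 630 - 1983433 * _N**6 / 1935360,
        61 * _N**3 / 240 - 103 * _N**4 / 140 + 15061 * _N**5 / 26880
        + 167603 * _N**6 / 181440,
        49561 * _N**4 / 161280 - 179 * _N**5 / 168 + 6601661 * _N**6 / 7257600,
        34729 * _N**5 / 80640 - 3418889 * _N**6 / 1995840,
        212378941 * _N**6 / 319334400,
    ]
)

_BETA = np.array(
    [
        _N / 2 - 2 * _N**2 / 3 + 37 * _N**3 / 96 - _N**4 / 360
        - 81 * _N**5 / 512 + 96199 * _N**6 / 604800,
        _N**2 / 48 + _N**3 / 15 - 437 * _N**4 / 1440 + 46 * _N**5 / 105
        - 1118711 * _N**6 / 3870720,
        17 * _N**3 / 480 - 37 * _N**4 / 840 - 209 * _N**5 / 4480
        + 5569 * _N**6 / 90720,
        4397 * _N**4 / 161280 - 11 * _N**5 / 504 - 830251 * _N**6 / 7257600,
        4583 * _N**5 / 161280 - 108847 * _N**6 / 3991680,
        20648693 * _N**6 / 638668800,
    ]
)

_J = np.arange(1, 7)


def utm_zone(lon: float) -> int:
    """UTM zone number from longitude in degrees (standard 6-degree bands)."""
    lon = float(lon)
    if not -180.0 <= lon <= 180.0:
        raise UnsupportedRegionError(f"longitude {lon} out of range")
    zone = int((lon + 180.0) // 6.0) + 1
    return min(zone, 60)  # lon == 180 wraps into zone 60


def utm_central_meridian(zone: int) -> float:
    return -183.0 + 6.0 * zone


def utm_forward(lat, lon, zone: int | None = None):
    """Project WGS84 latitude/longitude (degrees) to UTM meters.

    Parameters
    ----------
    lat, lon : scalar or array, degrees
    zone : force a zone (needed when a session straddles a zone boundary);
        default: zone of the mean longitude.

    Returns
    -------
    (easting, northing, zone) with easting/northing in meters.  Northing uses
    the hemisphere convention (false northing 10,000,000 m south of the
    equator) based on the mean latitude.
    """
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if np.any(np.abs(lat) >= UTM_LAT_LIMIT):
        raise UnsupportedRegionError(
            f"latitude beyond +/-{UTM_LAT_LIMIT} deg is outside the UTM domain"
        )
    if np.any(np.abs(lon) > 180.0) or np.any(np.abs(lat) > 90.0):
        raise DataError("coordinates out of WGS84 range")
    if zone is None:
        zone = utm_zone(float(np.mean(lon)))

    lam0 = np.radians(utm_central_meridian(zone))
    phi = np.radians(lat)
    lam = np.radians(lon) - lam0

    sphi = np.sin(phi)
    # conformal latitude
    t = np.sinh(np.arctanh(sphi) - _E * np.arctanh(_E * sphi))
    xi_p = np.arctan2(t, np.cos(lam))
    eta_p = np.arcsinh(np.sin(lam) / np.hypot(t, np.cos(lam)))

    two_j_xi = 2.0 * np.multiply.outer(_J, xi_p)
    two_j_eta = 2.0 * np.multiply.outer(_J, eta_p)
    alpha = _ALPHA.reshape((6,) + (1,) * xi_p.ndim)
    xi = xi_p + np.sum(alpha * np.sin(two_j_xi) * np.cosh(two_j_eta), axis=0)
    eta = eta_p + np.sum(alpha * np.cos(two_j_xi) * np.sinh(two_j_eta), axis=0)

    easting = UTM_FALSE_EASTING + UTM_K0 * _A_RECT * eta
    northing = UTM_K0 * _A_RECT * xi
    if float(np.mean(lat)) < 0.0:
        northing = northing + UTM_FALSE_NORTHING_SOUTH
    if np.ndim(easting) == 0:
        return float(easting), float(northing), zone
    return easting, northing, zone


def utm_inverse(easting, northing, zone: int, northern: bool = True):
    """Invert :func:`utm_forward`; returns (lat, lon) in degrees."""
    easting = np.asarray(easting, dtype=float)
    northing = np.asarray(northing, dtype=float)
    if not northern:
        northing = northing - UTM_FALSE_NORTHING_SOUTH

    xi = northing / (UTM_K0 * _A_RECT)
    eta = (easting - UTM_FALSE_EASTING) / (UTM_K0 * _A_RECT)

    two_j_xi = 2.0 * np.multiply.outer(_J, xi)
    two_j_eta = 2.0 * np.multiply.outer(_J, eta)
    beta = _BETA.reshape((6,) + (1,) * xi.ndim)
    xi_p = xi - np.sum(beta * np.sin(two_j_xi) * np.cosh(two_j_eta), axis=0)
    eta_p = eta - np.sum(beta * np.cos(two_j_xi) * np.sinh(two_j_eta), axis=0)

    # tau' = tan(conformal latitude); invert by Newton on tau
    tau_p = np.sin(xi_p) / np.hypot(np.sinh(eta_p), np.cos(xi_p))
    lam = np.arctan2(np.sinh(eta_p), np.cos(xi_p))

    tau = tau_p / (1.0 - _E2)  # first guess
    for _ in range(6):
        sigma = np.sinh(_E * np.arctanh(_E * tau / np.hypot(1.0, tau)))
        f_tau = tau * np.hypot(1.0, sigma) - sigma * np.hypot(1.0, tau) - tau_p
        d_tau = (
            (np.hypot(1.0, sigma) * np.hypot(1.0, tau) - sigma * tau)
            * (1.0 - _E2)
            * np.hypot(1.0, tau)
            / (1.0 + (1.0 - _E2) * tau**2)
        )
        tau = tau - f_tau / d_tau

    lat = np.degrees(np.arctan(tau))
    lon = np.degrees(lam) + utm_central_meridian(zone)
    if np.ndim(lat) == 0:
        return float(lat), float(lon)
    return lat, lon


# ---------------------------------------------------------------------------
# Raw series and CSV reading
# ---------------------------------------------------------------------------


@dataclass
class RawGeoSeries:
    """One player's raw GPS samples: time (s) and WGS84 lat/lon (degrees)."""

    player: PlayerInfo
    t: np.ndarray
    lat: np.ndarray
    lon: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        if not (self.t.shape == self.lat.shape == self.lon.shape):
            raise DataError("t, lat, lon must have equal length")
        if self.t.size < 2:
            raise DataError("a raw series needs at least 2 samples")
        if np.any(np.diff(self.t) <= 0):
            raise DataError(
                f"non-monotone or duplicate timestamps for {self.player.player_id!r}"
            )
        if np.any(np.abs(self.lat) > 90.0) or np.any(np.abs(self.lon) > 180.0):
            raise DataError("lat/lon out of WGS84 range")


@dataclass
class ColumnMapping:
    """Maps the manufacturer CSV dialect onto the canonical columns.

    ``players`` declares team and role per player id; ids absent from the
    table default to team A outfield (single-file, single-player exports).
    """

    time: str = "t_s"
    lat: str = "lat"
    lon: str = "lon"
    player_id: str | None = "player_id"
    players: dict[str, dict[str, str]] = field(default_factory=dict)
    default_player_id: str = "p1"

    def info_for(self, pid: str) -> PlayerInfo:
        meta = self.players.get(pid, {})
        return PlayerInfo(pid, meta.get("team", "A"), meta.get("role", "outfield"))


def read_position_csv(path: str | Path, mapping: ColumnMapping | None = None) -> list[RawGeoSeries]:
    """Read a raw tracking CSV into one :class:`RawGeoSeries` per player.

    Rows are sorted by time within player; duplicate timestamps are a data
    error (the device emits one fix per sample).
    """
    mapping = mapping or ColumnMapping()
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path, comment="#")

    needed = [mapping.time, mapping.lat, mapping.lon]
    if mapping.player_id is not None and mapping.player_id in df.columns:
        groups = list(df.groupby(mapping.player_id, sort=True))
    else:
        if mapping.player_id is not None and mapping.players:
            # an explicit player column was promised but is absent
            raise FormatError(f"missing column: {mapping.player_id!r}")
        groups = [(mapping.default_player_id, df)]
    for col in needed:
        if col not in df.columns:
            raise FormatError(f"missing column: {col!r}")

    out: list[RawGeoSeries] = []
    for pid, sub in groups:
        sub = sub.sort_values(mapping.time)
        t = sub[mapping.time].to_numpy(dtype=float)
        if np.any(np.diff(t) == 0):
            raise DataError(f"duplicate timestamps for player {pid!r}")
        out.append(
            RawGeoSeries(
                player=mapping.info_for(str(pid)),
                t=t,
                lat=sub[mapping.lat].to_numpy(dtype=float),
                lon=sub[mapping.lon].to_numpy(dtype=float),
            )
        )
    return out


def project_series(
    raw: Sequence[RawGeoSeries], zone: int | None = None
) -> tuple[list[PlanarSeries], int]:
    """Project raw geographic series to UTM planar meters.

    All series of a session are forced to one zone (a pitch never spans
    zones; mixing zones would corrupt distances).  The zone defaults to that
    of the overall mean longitude.
    """
    if not raw:
        raise DataError("no series to project")
    if zone is None:
        zone = utm_zone(float(np.mean([np.mean(r.lon) for r in raw])))
    out = []
    for r in raw:
        e, n, _ = utm_forward(r.lat, r.lon, zone=zone)
        out.append(PlanarSeries(player=r.player, t=r.t, xy=np.column_stack([e, n])))
    return out, zone


# ---------------------------------------------------------------------------
# Field frame
# ---------------------------------------------------------------------------


@dataclass
class FieldFrame:
    """Pitch-aligned planar frame.

    ``origin`` is one pitch corner in projected meters; ``unit_x`` points
    along the pitch length, ``unit_y`` along the width, and (unit_x, unit_y)
    is right-handed, so the mapping to field coordinates is a proper isometry.
    """

    origin: np.ndarray
    unit_x: np.ndarray
    unit_y: np.ndarray
    length_m: float
    width_m: float

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.unit_x = np.asarray(self.unit_x, dtype=float)
        self.unit_y = np.asarray(self.unit_y, dtype=float)
        for v in (self.unit_x, self.unit_y):
            if abs(np.linalg.norm(v) - 1.0) > 1e-9:
                raise CalibrationError("frame axes must be unit vectors")
        if abs(float(self.unit_x @ self.unit_y)) > 1e-9:
            raise CalibrationError("frame axes must be orthogonal")
        if self.length_m <= 0 or self.width_m <= 0:
            raise CalibrationError("pitch dimensions must be positive")

    @property
    def rotation(self) -> np.ndarray:
        """2x2 matrix whose rows are the field axes (det = +1)."""
        return np.stack([self.unit_x, self.unit_y])

    def to_field(self, points: np.ndarray) -> np.ndarray:
        """Projected meters -> field coordinates (broadcast over leading axes)."""
        points = np.asarray(points, dtype=float)
        return (points - self.origin) @ self.rotation.T

    def to_projected(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return points @ self.rotation + self.origin


def build_field_frame(
    vertices: np.ndarray,
    length_m: float | None = None,
    width_m: float | None = None,
    side_tol: float = 0.05,
) -> FieldFrame:
    """Calibrate a :class:`FieldFrame` from the four pitch corners.

    Vertices may come in any order; they must form an approximate rectangle
    (opposite-side length mismatch below ``side_tol``).  The longer side pair
    defines the length axis.  Of the two admissible corners the one with the
    smaller (y, x) projected coordinates becomes the origin, which makes the
    exported coordinates reproducible.
    """
    v = np.asarray(vertices, dtype=float)
    if v.shape != (4, 2):
        raise CalibrationError("need exactly 4 planar vertices")
    c = v.mean(axis=0)
    order = np.argsort(np.arctan2(v[:, 1] - c[1], v[:, 0] - c[0]))
    p = v[order]  # counter-clockwise polygon
    sides = np.roll(p, -1, axis=0) - p
    slen = np.hypot(sides[:, 0], sides[:, 1])
    if np.any(slen < 1e-9):
        raise CalibrationError("degenerate vertices (coincident points)")
    # collinearity: the quad must have nonzero area
    area = 0.5 * abs(np.sum(p[:, 0] * np.roll(p[:, 1], -1) - np.roll(p[:, 0], -1) * p[:, 1]))
    if area < 1e-9 * slen.max() ** 2:
        raise CalibrationError("degenerate vertices (collinear)")
    for i, j in ((0, 2), (1, 3)):
        mismatch = abs(slen[i] - slen[j]) / max(slen[i], slen[j])
        if mismatch > side_tol:
            raise CalibrationError(
                f"opposite sides differ by {mismatch:.1%} (> {side_tol:.0%}): "
                "vertices do not form a rectangle"
            )
    long_pair = (0, 2) if slen[[0, 2]].mean() >= slen[[1, 3]].mean() else (1, 3)
    measured_len = float(slen[list(long_pair)].mean())
    measured_wid = float(slen[[i for i in range(4) if i not in long_pair]].mean())

    # two candidate origins (the start vertex of either long side); pick the
    # one with the smaller (y, then x) to make the choice deterministic
    candidates = []
    for k in long_pair:
        ux = sides[k] / slen[k]
        uy = np.array([-ux[1], ux[0]])  # +90 deg: right-handed, CCW polygon => interior on +y
        candidates.append((tuple(np.round(p[k][::-1], 6)), p[k], ux, uy))
    _, origin, unit_x, unit_y = min(candidates, key=lambda c: c[0])

    return FieldFrame(
        origin=origin,
        unit_x=unit_x,
        unit_y=unit_y,
        length_m=float(length_m) if length_m is not None else measured_len,
        width_m=float(width_m) if width_m is not None else measured_wid,
    )


def to_field_coords(traj: TrajectorySet, frame: FieldFrame) -> TrajectorySet:
    """Re-express a projected-meters trajectory set in the field frame.

    Positions slightly outside [0, length] x [0, width] (GPS noise) are kept
    as-is: clipping would bias the extent metrics.
    """
    xy = frame.to_field(traj.xy)
    return TrajectorySet(players=list(traj.players), t=traj.t.copy(), xy=xy, fs=traj.fs)


def field_frame_from_geo(
    vertices_latlon: np.ndarray,
    length_m: float | None = None,
    width_m: float | None = None,
    zone: int | None = None,
) -> tuple[FieldFrame, int]:
    """Convenience: calibrate from four lat/lon corners (projected first)."""
    v = np.asarray(vertices_latlon, dtype=float)
    if v.shape != (4, 2):
        raise CalibrationError("need exactly 4 (lat, lon) vertices")
    if zone is None:
        zone = utm_zone(float(np.mean(v[:, 1])))
    e, n, _ = utm_forward(v[:, 0], v[:, 1], zone=zone)
    return build_field_frame(np.column_stack([e, n]), length_m, width_m), zone
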