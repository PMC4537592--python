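"""Tailwind/crosswind annotation of flight segments from layered wind fields.

Wind directions are stored internally in the direction-TO convention (the
compass heading toward which the air moves), so that the tailwind component
``V_w * cos(beta)`` is positive when the wind blows along the track.
Meteorological direction-FROM inputs are converted on read (from = to + 180).

Interpolation is inverse-distance weighting on the u/v vector components
(never on circular direction scalars) over a combined space-time distance,
with the lattice resolutions (32 km, 3 h) as the default scalings.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import (
    angle_difference,
    great_circle_midpoint,
    haversine_km,
    wrap_bearing,
)

__all__ = [
    "WindSample",
    "TrackWindAnnotation",
    "wind_components",
    "uv_from_speed_direction",
    "speed_direction_from_uv",
    "idw_interpolate",
    "segment_midpoint",
    "level_mean_altitude",
    "annotate_segment",
    "DEFAULT_LEVELS",
    "WindDataError",
]

logger = logging.getLogger(__name__)

#: 10 m, 30 m, then fifteen pressure levels at 25-mbar steps (17 levels).
DEFAULT_LEVELS: tuple[str, ...] = ("10m", "30m") + tuple(
    f"{p}mb" for p in range(1000, 649, -25)
)

#: Default space-time scalings for the combined IDW distance.
SPACE_SCALE_KM = 32.0
TIME_SCALE_S = 3.0 * 3600.0


class WindDataError(ValueError):
    pass


@dataclass(frozen=True)
class WindSample:
    level_id: str
    lat: float
    lon: float
    time: float  # seconds since the Unix epoch, UTC
    wind_speed_ms: float
    wind_direction_to_deg: float
    geopotential_height_m: float | None = None

    def __post_init__(self):
        if self.wind_speed_ms < 0:
            raise WindDataError("wind speed must be nonnegative")
        object.__setattr__(
            self, "wind_direction_to_deg", float(wrap_bearing(self.wind_direction_to_deg))
        )


@dataclass(frozen=True)
class TrackWindAnnotation:
    tag_id: str
    stage: str
    level_id: str
    tailwind_ms: float
    crosswind_ms: float
    beta_deg: float
    level_altitude_m: float | None = None

    def __post_init__(self):
        v2 = self.tailwind_ms**2 + self.crosswind_ms**2
        # tailwind^2 + crosswind^2 == V_w^2 by construction; guard anyway
        if v2 < 0 or not math.isfinite(v2):
            raise WindDataError("non-finite wind components")


def wind_components(wind_speed_ms, wind_direction_to_deg, track_direction_deg):
    """Tailwind and crosswind components of a wind vector along a track.

    beta is the wind-minus-track angle wrapped to (-180, 180]; tailwind is
    ``V_w cos(beta)`` (positive = supportive) and crosswind ``V_w sin(beta)``.
    """
    v = np.asarray(wind_speed_ms, dtype=float)
    if np.any(v < 0):
        raise WindDataError("wind speed must be nonnegative")
    beta = np.radians(angle_difference(wind_direction_to_deg, track_direction_deg))
    tail = v * np.cos(beta)
    cross = v * np.sin(beta)
    if np.ndim(tail) == 0:
        return float(tail), float(cross)
    return tail, cross


def uv_from_speed_direction(speed_ms, direction_to_deg):
    """Eastward (u) and northward (v) components of a direction-to wind."""
    th = np.radians(np.asarray(direction_to_deg, dtype=float))
    s = np.asarray(speed_ms, dtype=float)
    return s * np.sin(th), s * np.cos(th)


def speed_direction_from_uv(u, v):
    """Speed and direction-to (degrees from north) from vector components."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    speed = np.hypot(u, v)
    direction = wrap_bearing(np.degrees(np.arctan2(u, v)))
    if np.ndim(speed) == 0:
        return float(speed), float(direction)
    return speed, direction


def idw_interpolate(
    samples: pd.DataFrame,
    lat: float,
    lon: float,
    time: float,
    *,
    power: float = 1.0,
    space_scale_km: float = SPACE_SCALE_KM,
    time_scale_s: float = TIME_SCALE_S,
    k_nearest: int | None = 8,
) -> tuple[float, float]:
    """Inverse-distance-weighted (u, v) wind at a space-time query point.

    ``samples`` must carry columns lat, lon, time, u, v for a single level.
    The combined distance is ``hypot(d_space/space_scale, d_time/time_scale)``
    and weights are ``1/d**power``.  A query coinciding with a sample returns
    that sample exactly.  ``k_nearest`` restricts the weighting to the nearest
    samples (None = use all).
    """
    if len(samples) == 0:
        raise WindDataError("no wind samples to interpolate from")
    d_space = haversine_km(
        samples["lat"].to_numpy(), samples["lon"].to_numpy(), lat, lon
    )
    d_time = np.abs(samples["time"].to_numpy() - time)
    d = np.hypot(
        np.asarray(d_space) / space_scale_km, d_time / time_scale_s
    )
    u = samples["u"].to_numpy(dtype=float)
    v = samples["v"].to_numpy(dtype=float)
    exact = d < 1e-12
    if np.any(exact):
        i = int(np.argmax(exact))
        return float(u[i]), float(v[i])
    if k_nearest is not None and k_nearest < len(d):
        idx = np.argpartition(d, k_nearest)[:k_nearest]
        d, u, v = d[idx], u[idx], v[idx]
    w = 1.0 / d**power
    w /= w.sum()
    return float(w @ u), float(w @ v)


def segment_midpoint(segment, origin_time: float, dest_time: float):
    """Spatial and temporal midpoint of a segment's track.

    Returns ``(lat, lon, time)``; the spatial midpoint lies on the
    great-circle path and the temporal midpoint is the mean event time.
    """
    if dest_time <= origin_time:
        raise WindDataError("destination time must postdate origin time")
    lat, lon = great_circle_midpoint(
        segment.origin_lat, segment.origin_lon, segment.dest_lat, segment.dest_lon
    )
    return lat, lon, 0.5 * (origin_time + dest_time)


def level_mean_altitude(heights) -> tuple[float, float]:
    """Mean and sample standard deviation of geopotential heights (m)."""
    h = np.asarray(list(heights), dtype=float)
    if h.size == 0:
        raise WindDataError("no geopotential heights supplied")
    mean = float(h.mean())
    sd = float(h.std(ddof=1)) if h.size > 1 else 0.0
    return mean, sd


def annotate_segment(
    segment,
    winds: pd.DataFrame,
    origin_time: float,
    dest_time: float,
    *,
    levels: tuple[str, ...] | None = None,
    power: float = 1.0,
    space_scale_km: float = SPACE_SCALE_KM,
    time_scale_s: float = TIME_SCALE_S,
    k_nearest: int | None = 8,
) -> list[TrackWindAnnotation]:
    """Per-level tailwind/crosswind at a segment's space-time midpoint.

    ``winds`` is a long-format table with columns level_id, lat, lon, time,
    u, v and optionally geopotential_height_m.  Missing levels are skipped
    with a logged warning; one annotation is returned per available level.
    """
    if levels is None:
        levels = tuple(dict.fromkeys(winds["level_id"]))
    lat, lon, tmid = segment_midpoint(segment, origin_time, dest_time)
    out: list[TrackWindAnnotation] = []
    grouped = dict(tuple(winds.groupby("level_id", sort=False)))
    for level in levels:
        if level not in grouped:
            logger.warning(
                "wind level %s missing for tag %s (%s stage); skipped",
                level, segment.tag_id, segment.stage,
            )
            continue
        sub = grouped[level]
        u, v = idw_interpolate(
            sub, lat, lon, tmid,
            power=power, space_scale_km=space_scale_km,
            time_scale_s=time_scale_s, k_nearest=k_nearest,
        )
        speed, direction = speed_direction_from_uv(u, v)
        tail, cross = wind_components(speed, direction, segment.track_direction_deg)
        beta = float(angle_difference(direction, segment.track_direction_deg))
        altitude = None
        if "geopotential_height_m" in sub.columns:
            h = sub["geopotential_height_m"].dropna()
            if len(h):
                altitude = float(h.mean())
        out.append(
            TrackWindAnnotation(
                tag_id=segment.tag_id,
                stage=segment.stage,
                level_id=level,
                tailwind_ms=tail,
                crosswind_ms=cross,
                beta_deg=beta,
                level_altitude_m=altitude,
            )
        )
    return out
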