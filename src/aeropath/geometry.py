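"""Great-circle geometry on a spherical Earth.

All coordinates are decimal degrees (latitude positive north, longitude
positive east, so western hemisphere longitudes are negative).  Bearings are
degrees clockwise from geographic north.  Distances are kilometres on a
sphere of radius 6371.0 km.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0

__all__ = [
    "EARTH_RADIUS_KM",
    "haversine_km",
    "initial_bearing_deg",
    "destination_point",
    "great_circle_midpoint",
    "wrap_bearing",
    "angle_difference",
]


class GeometryError(ValueError):
    """Invalid geometric input."""


def _validate(lat, lon) -> None:
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if not (np.all(np.isfinite(lat)) and np.all(np.isfinite(lon))):
        raise GeometryError("coordinates must be finite")
    if np.any(lat < -90.0) or np.any(lat > 90.0):
        raise GeometryError("latitude out of [-90, 90]")
    if np.any(lon < -180.0) or np.any(lon >= 360.0):
        raise GeometryError("longitude out of range")


def wrap_bearing(deg):
    """Normalize a bearing to [0, 360)."""
    return np.mod(deg, 360.0)


def angle_difference(a_deg, b_deg):
    """Signed difference a - b wrapped to (-180, 180]."""
    d = np.mod(np.asarray(a_deg, dtype=float) - np.asarray(b_deg, dtype=float), 360.0)
    return np.where(d > 180.0, d - 360.0, d)


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km between two points (vectorized)."""
    _validate(lat1, lon1)
    _validate(lat2, lon2)
    p1, l1, p2, l2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    dphi = p2 - p1
    dlam = l2 - l1
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2.0) ** 2
    a = np.clip(a, 0.0, 1.0)
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))
    return d if d.ndim else float(d)


def initial_bearing_deg(lat1, lon1, lat2, lon2):
    """Initial great-circle bearing from point 1 to point 2, in [0, 360).

    Raises :class:`GeometryError` for coincident points (bearing undefined).
    """
    _validate(lat1, lon1)
    _validate(lat2, lon2)
    scalar = np.isscalar(lat1) or np.asarray(lat1).ndim == 0
    p1, l1, p2, l2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    if scalar and np.allclose([p1, l1], [p2, l2], atol=1e-15):
        raise GeometryError("bearing undefined for identical points")
    y = np.sin(l2 - l1) * np.cos(p2)
    x = np.cos(p1) * np.sin(p2) - np.sin(p1) * np.cos(p2) * np.cos(l2 - l1)
    b = wrap_bearing(np.degrees(np.arctan2(y, x)))
    return b if b.ndim else float(b)


def destination_point(lat, lon, bearing_deg, distance_km):
    """Point reached travelling ``distance_km`` along the initial bearing."""
    _validate(lat, lon)
    dist = np.asarray(distance_km, dtype=float)
    if np.any(dist < 0.0):
        raise GeometryError("distance must be nonnegative")
    phi = np.radians(np.asarray(lat, dtype=float))
    lam = np.radians(np.asarray(lon, dtype=float))
    theta = np.radians(np.asarray(bearing_deg, dtype=float))
    delta = dist / EARTH_RADIUS_KM
    phi2 = np.arcsin(np.sin(phi) * np.cos(delta) + np.cos(phi) * np.sin(delta) * np.cos(theta))
    lam2 = lam + np.arctan2(
        np.sin(theta) * np.sin(delta) * np.cos(phi),
        np.cos(delta) - np.sin(phi) * np.sin(phi2),
    )
    lat2 = np.degrees(phi2)
    lon2 = np.degrees(np.mod(lam2 + np.pi, 2.0 * np.pi) - np.pi)
    if np.ndim(lat2) == 0:
        return float(lat2), float(lon2)
    return lat2, lon2


def great_circle_midpoint(lat1, lon1, lat2, lon2):
    """Spatial midpoint of the great-circle arc between two points."""
    _validate(lat1, lon1)
    _validate(lat2, lon2)
    p1, l1, p2, l2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    bx = np.cos(p2) * np.cos(l2 - l1)
    by = np.cos(p2) * np.sin(l2 - l1)
    phi_m = np.arctan2(np.sin(p1) + np.sin(p2), np.sqrt((np.cos(p1) + bx) ** 2 + by**2))
    lam_m = l1 + np.arctan2(by, np.cos(p1) + bx)
    lat_m = np.degrees(phi_m)
    lon_m = np.degrees(np.mod(lam_m + np.pi, 2.0 * np.pi) - np.pi)
    if np.ndim(lat_m) == 0:
        return float(lat_m), float(lon_m)
    return lat_m, lon_m
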