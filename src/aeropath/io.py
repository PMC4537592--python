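"""Readers and writers for the pipeline's plain-text formats.

Timestamps are ISO-8601 in the files and UTC epoch seconds internally; wind
files declare their direction convention per row (``to`` or ``from``) and
are normalized to direction-to on read.  Parse errors carry line numbers.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .telemetry import AntennaSpec, StationSpec
from .wind import uv_from_speed_direction

__all__ = [
    "ParseError",
    "read_stations",
    "write_stations",
    "read_detections",
    "write_detections",
    "read_winds",
    "write_winds",
    "read_metadata",
    "write_metadata",
    "read_segments",
    "write_segments",
    "write_selection_table",
    "write_dataset",
    "epoch_to_iso",
    "iso_to_epoch",
]

FLOAT_FMT = "%.6f"


class ParseError(ValueError):
    pass


def epoch_to_iso(t) -> pd.Series:
    """Epoch seconds -> ISO-8601 UTC strings with microsecond precision."""
    ts = pd.to_datetime(np.asarray(t, dtype=float) * 1e6, unit="us", utc=True)
    return pd.Series(ts).dt.strftime("%Y-%m-%dT%H:%M:%S.%f+00:00")


def iso_to_epoch(s, *, context: str = "timestamp") -> np.ndarray:
    """ISO-8601 strings (with or without timezone suffix) -> UTC epoch seconds."""
    try:
        ts = pd.to_datetime(pd.Series(s), utc=True, format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise ParseError(f"unparseable {context}: {exc}") from exc
    return (ts.astype("int64") / 1e9).to_numpy()


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")


# ---------------------------------------------------------------------------
# stations


def read_stations(path) -> list[StationSpec]:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    stations = []
    for entry in raw["stations"]:
        antennas = tuple(
            AntennaSpec(a["boresight_deg"], a.get("elements", 9)) for a in entry["antennas"]
        )
        stations.append(
            StationSpec(
                name=entry["name"],
                lat=float(entry["lat"]),
                lon=float(entry["lon"]),
                antennas=antennas,
                scan_on_s=float(entry.get("scan_on_s", 14.0)),
                scan_period_s=float(entry.get("scan_period_s", 28.0)),
                detection_range_km=float(entry.get("detection_range_km", 15.0)),
            )
        )
    return stations


def write_stations(stations: list[StationSpec], path) -> None:
    payload = {
        "stations": [
            {
                "name": s.name,
                "lat": s.lat,
                "lon": s.lon,
                "scan_on_s": s.scan_on_s,
                "scan_period_s": s.scan_period_s,
                "detection_range_km": s.detection_range_km,
                "antennas": [
                    {"boresight_deg": a.boresight_deg, "elements": a.elements}
                    for a in s.antennas
                ],
            }
            for s in stations
        ]
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# detections


DETECTION_COLUMNS = ["tag_id", "station", "antenna_index", "timestamp_utc", "signal_strength"]


def read_detections(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, DETECTION_COLUMNS, path)
    bad = df["signal_strength"].isna() | ~np.isfinite(df["signal_strength"].astype(float))
    if bad.any():
        lines = (np.flatnonzero(bad) + 2).tolist()
        raise ParseError(f"{path}: non-finite signal strength at lines {lines[:10]}")
    out = df.copy()
    out["time"] = iso_to_epoch(df["timestamp_utc"], context=f"{path} timestamp_utc")
    out["antenna_index"] = out["antenna_index"].astype(int)
    return out[["tag_id", "station", "antenna_index", "time", "signal_strength"]]


def write_detections(df: pd.DataFrame, path) -> None:
    out = pd.DataFrame(
        {
            "tag_id": df["tag_id"],
            "station": df["station"],
            "antenna_index": df["antenna_index"].astype(int),
            "timestamp_utc": epoch_to_iso(df["time"]).to_numpy(),
            "signal_strength": df["signal_strength"],
        }
    )
    out.to_csv(path, index=False, float_format=FLOAT_FMT)


# ---------------------------------------------------------------------------
# winds


WIND_COLUMNS = ["level_id", "lat", "lon", "timestamp_utc", "wind_speed_ms", "wind_dir_deg"]


def read_winds(path) -> pd.DataFrame:
    """Read a layered wind table, normalizing directions to direction-to.

    Rows may declare ``dir_convention`` ``to`` (vector heading) or ``from``
    (meteorological); ``from`` directions are flipped by 180 degrees.
    """
    df = pd.read_csv(path)
    _require_columns(df, WIND_COLUMNS, path)
    if (df["wind_speed_ms"] < 0).any():
        lines = (np.flatnonzero(df["wind_speed_ms"] < 0) + 2).tolist()
        raise ParseError(f"{path}: negative wind speed at lines {lines[:10]}")
    if (df["lat"].abs() > 90).any():
        lines = (np.flatnonzero(df["lat"].abs() > 90) + 2).tolist()
        raise ParseError(f"{path}: latitude out of range at lines {lines[:10]}")
    conv = df["dir_convention"] if "dir_convention" in df.columns else pd.Series("to", index=df.index)
    bad = ~conv.isin(["to", "from"])
    if bad.any():
        lines = (np.flatnonzero(bad) + 2).tolist()
        raise ParseError(f"{path}: dir_convention must be 'to' or 'from' at lines {lines[:10]}")
    direction = np.mod(
        df["wind_dir_deg"].astype(float) + np.where(conv == "from", 180.0, 0.0), 360.0
    )
    out = pd.DataFrame(
        {
            "level_id": df["level_id"],
            "lat": df["lat"].astype(float),
            "lon": df["lon"].astype(float),
            "time": iso_to_epoch(df["timestamp_utc"], context=f"{path} timestamp_utc"),
            "wind_speed_ms": df["wind_speed_ms"].astype(float),
            "wind_dir_to_deg": direction,
        }
    )
    if "geopotential_height_m" in df.columns:
        out["geopotential_height_m"] = df["geopotential_height_m"].astype(float)
    out["u"], out["v"] = uv_from_speed_direction(out["wind_speed_ms"], out["wind_dir_to_deg"])
    return out


def write_winds(df: pd.DataFrame, path) -> None:
    out = pd.DataFrame(
        {
            "level_id": df["level_id"],
            "lat": df["lat"],
            "lon": df["lon"],
            "timestamp_utc": epoch_to_iso(df["time"]).to_numpy(),
            "wind_speed_ms": df["wind_speed_ms"],
            "wind_dir_deg": df["wind_dir_to_deg"],
            "dir_convention": "to",
            "geopotential_height_m": df.get("geopotential_height_m", np.nan),
        }
    )
    out.to_csv(path, index=False, float_format=FLOAT_FMT)


# ---------------------------------------------------------------------------
# bird metadata and segments


def read_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["tag_id", "age", "nest_id"], path)
    bad = ~df["age"].isin(["adult", "juvenile"])
    if bad.any():
        lines = (np.flatnonzero(bad) + 2).tolist()
        raise ParseError(f"{path}: age must be adult/juvenile at lines {lines[:10]}")
    return df


def write_metadata(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


SEGMENT_COLUMNS = [
    "tag_id", "stage", "origin_lat", "origin_lon", "dest_lat", "dest_lon",
    "track_deg", "distance_km", "duration_min", "groundspeed_ms",
    "age", "nest_id", "individual_id", "origin_time", "dest_time",
]


def write_segments(df: pd.DataFrame, path) -> None:
    out = df[[c for c in SEGMENT_COLUMNS if c in df.columns]].copy()
    out["origin_time"] = epoch_to_iso(df["origin_time"]).to_numpy()
    out["dest_time"] = epoch_to_iso(df["dest_time"]).to_numpy()
    out.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_segments(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["tag_id", "stage", "distance_km", "duration_min"], path)
    for col in ("origin_time", "dest_time"):
        if col in df.columns and df[col].dtype == object:
            df[col] = iso_to_epoch(df[col], context=f"{path} {col}")
    return df


# ---------------------------------------------------------------------------
# model-selection tables


def write_selection_table(table: pd.DataFrame, path) -> None:
    """Selection table CSV: equations, K, AICc, dAICc, W, cumW, Fisher's C.

    Rows are sorted ascending by AICc and numeric columns rounded to two
    decimals, matching the published table layout.
    """
    if len(table) == 0:
        raise ValueError("selection table must be nonempty")
    out = table.sort_values("AICc", kind="mergesort").copy()
    for col in ("AICc", "dAICc", "W", "cumW", "fishers_C"):
        out[col] = out[col].astype(float).round(2)
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# synthetic bundle


def write_dataset(dataset, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_stations(dataset.stations, outdir / "stations.yaml")
    write_winds(dataset.winds, outdir / "winds.csv")
    write_detections(dataset.detections, outdir / "detections.csv")
    write_metadata(dataset.birds, outdir / "birds.csv")
    truth = dataset.truth.copy()
    for col in ("origin_time", "dest_time"):
        truth[col] = epoch_to_iso(truth[col]).to_numpy()
    truth.to_csv(outdir / "truth.csv", index=False, float_format=FLOAT_FMT)
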