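"""End-to-end orchestration: detections -> segments -> winds -> models.

The reconstruction walks each tag through the array: the departure event is
the signal peak at the best island station, arrival events at the coastal
stations are classified into crossing points from the antenna pattern around
the peak, and consecutive events become ocean and coastal flight segments.
Segments are annotated with per-level wind components at their space-time
midpoints, each stage's wind altitude is selected by the AICc scan, and the
path models are backward-eliminated for flight duration and log groundspeed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .altitude import AltitudeScanResult, altitude_scan
from .pathmodel import EliminationResult, backward_eliminate, standardize_table
from .telemetry import (
    CrossingEvent,
    Detection,
    DetectionSeries,
    NoEventError,
    StationSpec,
    build_flight_segment,
    classify_crossing,
    event_time_from_peak,
    filter_false_positives,
)
from .wind import annotate_segment

__all__ = [
    "PipelineConfig",
    "reconstruct_segments",
    "annotate_segments",
    "probe_stage",
    "build_path_table",
    "run_pipeline",
    "RunReport",
]

logger = logging.getLogger(__name__)

FIXED_LEVEL_ALTITUDES = {"10m": 10.0, "30m": 30.0}


@dataclass
class PipelineConfig:
    stations_path: str = "stations.yaml"
    detections_path: str = "detections.csv"
    winds_path: str = "winds.csv"
    metadata_path: str = "birds.csv"
    outdir: str = "out"
    seed: int = 1
    pulse_rate_s: float = 5.0
    pulse_tolerance_s: float = 0.25
    pattern_window_s: float = 180.0
    min_detections: int = 3
    idw_power: float = 1.0
    idw_k_nearest: int = 8
    levels: list[str] | None = None
    island_prefix: str = "KentIs"
    coastal_order: list[str] = field(
        default_factory=lambda: ["InnerDoubleHeadshotIs", "PetitMananPt"]
    )
    stage_names: list[str] = field(default_factory=lambda: ["ocean", "coast"])
    ocean_random_effects: list[str] = field(default_factory=lambda: ["nest_id"])
    coast_random_effects: list[str] = field(default_factory=list)
    path_random_effects: list[str] = field(
        default_factory=lambda: ["nest_id", "individual_id"]
    )
    make_plots: bool = True

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


# ---------------------------------------------------------------------------
# reconstruction


def _series_for(df: pd.DataFrame, tag: str, station: str) -> DetectionSeries:
    sub = df[(df["tag_id"] == tag) & (df["station"] == station)].sort_values("time")
    dets = [
        Detection(tag, station, int(r.antenna_index), float(r.time), float(r.signal_strength))
        for r in sub.itertuples()
    ]
    return DetectionSeries(tag, station, dets)


def _peak_quality(series: DetectionSeries, top: int = 5) -> float:
    s = sorted((d.signal_strength for d in series.detections), reverse=True)
    return float(np.mean(s[:top]))


def _pattern_near_peak(
    series: DetectionSeries, peak_time: float, window_s: float
) -> str:
    counts = {0: 0, 1: 0}
    for d in series.detections:
        if abs(d.time - peak_time) <= window_s and d.antenna_index in counts:
            counts[d.antenna_index] += 1
    present = {a for a, c in counts.items() if c >= 2}
    if not present:
        present = {a for a, c in counts.items() if c >= 1}
    if present == {0}:
        return "first_antenna_only"
    if present == {1}:
        return "second_antenna_only"
    return "both"


def reconstruct_segments(
    detections: pd.DataFrame,
    stations: list[StationSpec],
    metadata: pd.DataFrame,
    *,
    pulse_rate_s: float = 5.0,
    pulse_tolerance_s: float = 0.25,
    pattern_window_s: float = 180.0,
    min_detections: int = 3,
    island_prefix: str = "KentIs",
    coastal_order: tuple[str, ...] = ("InnerDoubleHeadshotIs", "PetitMananPt"),
    stage_names: tuple[str, ...] = ("ocean", "coast"),
) -> pd.DataFrame:
    """Event extraction and segment assembly for every tag.

    Birds missing a downstream detection are retained for the upstream
    segments they completed.  Returns one row per (tag, stage).
    """
    by_name = {s.name: s for s in stations}
    island_names = [s.name for s in stations if s.name.startswith(island_prefix)]
    meta = metadata.set_index("tag_id")
    rows = []
    for tag in sorted(detections["tag_id"].unique()):
        # departure: best island station by peak signal
        best_series, best_q = None, -np.inf
        for name in island_names:
            series = filter_false_positives(
                _series_for(detections, tag, name), pulse_rate_s, pulse_tolerance_s
            )
            if len(series) >= min_detections and _peak_quality(series) > best_q:
                best_series, best_q = series, _peak_quality(series)
        if best_series is None:
            logger.info("tag %s: no usable island detections; skipped", tag)
            continue
        st = by_name[best_series.station]
        dep_time = event_time_from_peak(best_series)
        events: list[CrossingEvent] = [
            CrossingEvent(st.name, "departure", st.lat, st.lon, 0.0, dep_time)
        ]
        for name in coastal_order:
            series = filter_false_positives(
                _series_for(detections, tag, name), pulse_rate_s, pulse_tolerance_s
            )
            if len(series) < min_detections:
                break  # downstream stations cannot be reached without this one
            try:
                t = event_time_from_peak(series)
            except NoEventError:
                break
            pattern = _pattern_near_peak(series, t, pattern_window_s)
            events.append(classify_crossing(pattern, by_name[name], t))
        if tag in meta.index:
            age = str(meta.loc[tag, "age"])
            nest = str(meta.loc[tag, "nest_id"])
        else:
            logger.warning("tag %s missing from metadata", tag)
            age, nest = "", ""
        for i, (origin, dest) in enumerate(zip(events, events[1:])):
            stage = stage_names[i] if i < len(stage_names) else f"stage{i}"
            seg = build_flight_segment(
                origin, dest, tag_id=tag, stage=stage,
                age=age, nest_id=nest, individual_id=tag,
            )
            rows.append(
                {
                    "tag_id": tag, "stage": stage,
                    "origin_lat": seg.origin_lat, "origin_lon": seg.origin_lon,
                    "dest_lat": seg.dest_lat, "dest_lon": seg.dest_lon,
                    "track_deg": seg.track_direction_deg,
                    "distance_km": seg.distance_km,
                    "duration_min": seg.duration_min,
                    "groundspeed_ms": seg.groundspeed_ms,
                    "age": age, "nest_id": nest, "individual_id": tag,
                    "origin_time": origin.time, "dest_time": dest.time,
                    "origin_station": origin.station, "dest_station": dest.station,
                    "pattern": dest.pattern,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# annotation


@dataclass
class _SegmentShim:
    tag_id: str
    stage: str
    origin_lat: float
    origin_lon: float
    dest_lat: float
    dest_lon: float
    track_direction_deg: float


def annotate_segments(
    segments: pd.DataFrame,
    winds: pd.DataFrame,
    *,
    levels: tuple[str, ...] | None = None,
    power: float = 1.0,
    k_nearest: int | None = 8,
) -> pd.DataFrame:
    """Per-level wind annotations for every segment (long format)."""
    out = []
    for row in segments.itertuples():
        shim = _SegmentShim(
            row.tag_id, row.stage, row.origin_lat, row.origin_lon,
            row.dest_lat, row.dest_lon, row.track_deg,
        )
        anns = annotate_segment(
            shim, winds, row.origin_time, row.dest_time,
            levels=levels, power=power, k_nearest=k_nearest,
        )
        for a in anns:
            alt = a.level_altitude_m
            if alt is None or not np.isfinite(alt):
                alt = FIXED_LEVEL_ALTITUDES.get(a.level_id, np.nan)
            out.append(
                {
                    "tag_id": a.tag_id, "stage": a.stage, "level_id": a.level_id,
                    "level_altitude_m": alt, "tailwind_ms": a.tailwind_ms,
                    "crosswind_ms": a.crosswind_ms, "beta_deg": a.beta_deg,
                }
            )
    return pd.DataFrame(out)


def probe_stage(
    segments: pd.DataFrame,
    annotations: pd.DataFrame,
    stage: str,
    *,
    random_effects: tuple[str, ...] = (),
) -> AltitudeScanResult:
    """Altitude scan for one flight stage."""
    seg = segments[segments["stage"] == stage]
    ann = annotations[annotations["stage"] == stage].merge(
        seg[["tag_id", "duration_min", "nest_id"]], on="tag_id", how="inner"
    )
    return altitude_scan(ann, stage=stage, random_effects=random_effects)


def build_path_table(
    segments: pd.DataFrame,
    annotations: pd.DataFrame,
    selected_levels: dict[str, str],
) -> pd.DataFrame:
    """One row per segment with winds taken from its stage's selected level."""
    parts = []
    for stage, level in selected_levels.items():
        ann = annotations[
            (annotations["stage"] == stage) & (annotations["level_id"] == level)
        ][["tag_id", "tailwind_ms", "crosswind_ms"]]
        seg = segments[segments["stage"] == stage][
            ["tag_id", "stage", "age", "nest_id", "individual_id",
             "duration_min", "groundspeed_ms"]
        ]
        parts.append(seg.merge(ann, on="tag_id", how="inner"))
    return pd.concat(parts, ignore_index=True)


# ---------------------------------------------------------------------------
# full run


@dataclass
class RunReport:
    segments: pd.DataFrame
    annotations: pd.DataFrame
    scans: dict[str, AltitudeScanResult]
    selected_levels: dict[str, str]
    path_table: pd.DataFrame
    eliminations: dict[str, EliminationResult]


def _plot_scan(scans: dict[str, AltitudeScanResult], path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    markers = {"ocean": "o--", "coast": "s-"}
    for stage, scan in scans.items():
        t = scan.table.sort_values("altitude_m")
        ax.plot(t["altitude_m"], t["daicc"], markers.get(stage, "o-"),
                mfc="none", label=stage)
    ax.set_xlabel("altitude (m)")
    ax.set_ylabel(r"$\Delta$AICc")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run the full analysis and write the report bundle to ``config.outdir``."""
    from . import io as _io

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stations = _io.read_stations(config.stations_path)
    detections = _io.read_detections(config.detections_path)
    winds = _io.read_winds(config.winds_path)
    metadata = _io.read_metadata(config.metadata_path)

    segments = reconstruct_segments(
        detections, stations, metadata,
        pulse_rate_s=config.pulse_rate_s,
        pulse_tolerance_s=config.pulse_tolerance_s,
        pattern_window_s=config.pattern_window_s,
        min_detections=config.min_detections,
        island_prefix=config.island_prefix,
        coastal_order=tuple(config.coastal_order),
        stage_names=tuple(config.stage_names),
    )
    if segments.empty:
        raise RuntimeError("reconstruction produced no segments")
    _io.write_segments(segments, outdir / "segments.csv")

    levels = tuple(config.levels) if config.levels else None
    annotations = annotate_segments(
        segments, winds, levels=levels,
        power=config.idw_power, k_nearest=config.idw_k_nearest,
    )
    annotations.to_csv(outdir / "annotations.csv", index=False, float_format="%.6f")

    scans: dict[str, AltitudeScanResult] = {}
    selected: dict[str, str] = {}
    re_by_stage = {
        "ocean": tuple(config.ocean_random_effects),
        "coast": tuple(config.coast_random_effects),
    }
    for stage in config.stage_names:
        scan = probe_stage(
            segments, annotations, stage, random_effects=re_by_stage.get(stage, ())
        )
        scans[stage] = scan
        scan.table.to_csv(outdir / f"scan_{stage}.csv", index=False, float_format="%.4f")
        if scan.selected_level is None:
            logger.warning("stage %s: all levels uninformative", stage)
        else:
            selected[stage] = scan.selected_level
    if config.make_plots:
        _plot_scan(scans, outdir / "scan_daicc.png")

    path_table_raw = build_path_table(segments, annotations, selected)
    table = standardize_table(path_table_raw)
    eliminations: dict[str, EliminationResult] = {}
    for response in ("flight_duration", "log_groundspeed"):
        res = backward_eliminate(
            table, response, random_effects=tuple(config.path_random_effects)
        )
        eliminations[response] = res
        _io.write_selection_table(
            res.selection_table, outdir / f"selection_{response}.csv"
        )
        res.final.coefficient_table().to_csv(
            outdir / f"coefficients_{response}.csv", index=False, float_format="%.4f"
        )

    log = {
        "aeropath_version": __version__,
        "seed": config.seed,
        "n_segments": int(len(segments)),
        "selected_levels": selected,
        "settings": {
            "pulse_rate_s": config.pulse_rate_s,
            "pulse_tolerance_s": config.pulse_tolerance_s,
            "idw_power": config.idw_power,
            "idw_k_nearest": config.idw_k_nearest,
            "pattern_window_s": config.pattern_window_s,
        },
    }
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2)
    return RunReport(
        segments=segments,
        annotations=annotations,
        scans=scans,
        selected_levels=selected,
        path_table=table,
        eliminations=eliminations,
    )
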