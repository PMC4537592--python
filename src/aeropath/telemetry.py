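"""Flight-segment reconstruction from automated-telemetry detections.

A two-antenna coastal station classifies a passing bird into one of three
crossing patterns (first antenna only / both / second antenna only).  A
single-antenna pattern places the crossing point half a detection range out
along that antenna's boresight; a both-antenna pattern places it directly
over the station.  Event times come from the peak of the signal-strength
passage curve; false positives are removed with a pulse-rate filter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .geometry import (
    destination_point,
    haversine_km,
    initial_bearing_deg,
    wrap_bearing,
)

__all__ = [
    "AntennaSpec",
    "StationSpec",
    "Detection",
    "DetectionSeries",
    "CrossingEvent",
    "FlightSegment",
    "filter_false_positives",
    "event_time_from_peak",
    "classify_crossing",
    "build_flight_segment",
    "TelemetryError",
    "ChronologyError",
    "NoEventError",
]

PATTERNS = ("first_antenna_only", "both", "second_antenna_only")


class TelemetryError(ValueError):
    pass


class ChronologyError(TelemetryError):
    """Destination event does not postdate the origin event."""


class NoEventError(TelemetryError):
    """No detections from which to derive an event time."""


@dataclass(frozen=True)
class AntennaSpec:
    """A single Yagi antenna: boresight in degrees clockwise from north."""

    boresight_deg: float
    elements: int = 9

    def __post_init__(self):
        object.__setattr__(self, "boresight_deg", float(wrap_bearing(self.boresight_deg)))
        if self.elements < 1:
            raise TelemetryError("antenna must have >= 1 element")


@dataclass(frozen=True)
class StationSpec:
    name: str
    lat: float
    lon: float
    antennas: tuple[AntennaSpec, ...]
    scan_on_s: float = 14.0
    scan_period_s: float = 28.0
    detection_range_km: float = 15.0

    def __post_init__(self):
        if not (-90.0 <= self.lat <= 90.0):
            raise TelemetryError(f"latitude {self.lat} out of [-90, 90]")
        if not (-180.0 <= self.lon < 180.0):
            raise TelemetryError(f"longitude {self.lon} out of [-180, 180)")
        if self.scan_on_s > self.scan_period_s:
            raise TelemetryError("scan_on must not exceed scan_period")
        if self.detection_range_km <= 0:
            raise TelemetryError("detection_range_km must be positive")
        object.__setattr__(self, "antennas", tuple(self.antennas))


@dataclass(frozen=True)
class Detection:
    tag_id: str
    station: str
    antenna_index: int
    time: float  # seconds since the Unix epoch, UTC
    signal_strength: float

    def __post_init__(self):
        if not (math.isfinite(self.time) and math.isfinite(self.signal_strength)):
            raise TelemetryError("detection time and signal strength must be finite")


@dataclass
class DetectionSeries:
    """Time-ordered detections of one tag at one station."""

    tag_id: str
    station: str
    detections: list[Detection] = field(default_factory=list)

    def __post_init__(self):
        times = [d.time for d in self.detections]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise TelemetryError("detections must be in nondecreasing time order")

    def __len__(self):
        return len(self.detections)

    @property
    def times(self) -> list[float]:
        return [d.time for d in self.detections]

    @property
    def antenna_indices(self) -> set[int]:
        return {d.antenna_index for d in self.detections}


@dataclass(frozen=True)
class CrossingEvent:
    station: str
    pattern: str
    lat: float
    lon: float
    offset_km: float
    time: float


@dataclass(frozen=True)
class FlightSegment:
    tag_id: str
    stage: str  # "ocean" | "coast"
    origin_lat: float
    origin_lon: float
    dest_lat: float
    dest_lon: float
    track_direction_deg: float
    distance_km: float
    duration_min: float
    groundspeed_ms: float
    age: str = ""
    nest_id: str = ""
    individual_id: str = ""

    def __post_init__(self):
        if self.duration_min <= 0:
            raise ChronologyError("flight duration must be positive")
        if self.distance_km <= 0:
            raise TelemetryError("flight distance must be positive")
        expected = (self.distance_km * 1000.0) / (self.duration_min * 60.0)
        if abs(self.groundspeed_ms - expected) > 1e-9 * max(1.0, abs(expected)):
            raise TelemetryError("groundspeed inconsistent with distance/duration")
        if not (0.0 <= self.track_direction_deg < 360.0):
            raise TelemetryError("track direction must be in [0, 360)")


def _interval_is_pulse_multiple(dt: float, pulse_rate: float, tolerance: float) -> bool:
    if dt <= 0:
        return True  # coincident timestamps belong to the same burst
    k = max(1.0, round(dt / pulse_rate))
    return abs(dt - k * pulse_rate) <= tolerance


def filter_false_positives(
    series: DetectionSeries, pulse_rate: float, tolerance: float = 0.25
) -> DetectionSeries:
    """Drop detections whose spacing is not a multiple of the tag's pulse rate.

    Detections are grouped into maximal runs in which every consecutive
    inter-detection interval is within ``tolerance`` of an integer multiple
    of ``pulse_rate``.  Runs of length one (isolated hits) are removed; the
    scan is then repeated on the survivors until stable, so spurious hits
    sandwiched inside a genuine run do not split it.  The filter is
    idempotent and an empty series passes through unchanged.
    """
    if pulse_rate <= 0:
        raise TelemetryError("pulse_rate must be positive")
    if tolerance < 0:
        raise TelemetryError("tolerance must be nonnegative")
    dets = list(series.detections)
    while True:
        if len(dets) <= 1:
            kept = [] if len(dets) == 1 else dets
            # a lone detection has no valid interval evidence: drop it
            break
        runs: list[list[Detection]] = [[dets[0]]]
        for prev, cur in zip(dets, dets[1:]):
            if _interval_is_pulse_multiple(cur.time - prev.time, pulse_rate, tolerance):
                runs[-1].append(cur)
            else:
                runs.append([cur])
        kept = [d for run in runs if len(run) >= 2 for d in run]
        if len(kept) == len(dets):
            break
        dets = kept
    return DetectionSeries(series.tag_id, series.station, list(kept))


def event_time_from_peak(series: DetectionSeries) -> float:
    """Time of maximum signal strength; ties broken by the earliest time."""
    if len(series) == 0:
        raise NoEventError(f"no detections for tag {series.tag_id} at {series.station}")
    best = max(series.detections, key=lambda d: (d.signal_strength, -d.time))
    return best.time


def classify_crossing(pattern: str, station: StationSpec, time: float) -> CrossingEvent:
    """Locate a track crossing from the antenna detection pattern.

    ``both`` puts the crossing directly over the station (offset 0); a
    single-antenna pattern puts it ``detection_range_km / 2`` out along that
    antenna's boresight.  The signed offset is measured along the first
    antenna's boresight axis: +range/2 for the first antenna, -range/2 for
    the second.
    """
    if pattern not in PATTERNS:
        raise TelemetryError(f"unknown crossing pattern {pattern!r}")
    if len(station.antennas) != 2:
        raise TelemetryError(
            f"crossing classification needs a two-antenna station, "
            f"{station.name} has {len(station.antennas)}"
        )
    half = station.detection_range_km / 2.0
    if pattern == "both":
        return CrossingEvent(station.name, pattern, station.lat, station.lon, 0.0, time)
    idx = 0 if pattern == "first_antenna_only" else 1
    boresight = station.antennas[idx].boresight_deg
    lat, lon = destination_point(station.lat, station.lon, boresight, half)
    offset = half if idx == 0 else -half
    return CrossingEvent(station.name, pattern, lat, lon, offset, time)


def build_flight_segment(
    origin: CrossingEvent,
    destination: CrossingEvent,
    *,
    tag_id: str,
    stage: str,
    age: str = "",
    nest_id: str = "",
    individual_id: str = "",
) -> FlightSegment:
    """Assemble a segment between two events: distance, duration, groundspeed."""
    if destination.time <= origin.time:
        raise ChronologyError("destination event must postdate the origin event")
    distance = haversine_km(origin.lat, origin.lon, destination.lat, destination.lon)
    if distance <= 0:
        raise TelemetryError("degenerate track: origin and destination coincide")
    duration_min = (destination.time - origin.time) / 60.0
    groundspeed = (distance * 1000.0) / (duration_min * 60.0)
    track = initial_bearing_deg(origin.lat, origin.lon, destination.lat, destination.lon)
    return FlightSegment(
        tag_id=tag_id,
        stage=stage,
        origin_lat=origin.lat,
        origin_lon=origin.lon,
        dest_lat=destination.lat,
        dest_lon=destination.lon,
        track_direction_deg=track,
        distance_km=distance,
        duration_min=duration_min,
        groundspeed_ms=groundspeed,
        age=age,
        nest_id=nest_id,
        individual_id=individual_id,
    )


def segment_event_times(segment: FlightSegment, origin_time: float) -> tuple[float, float]:
    """Origin and destination epoch times implied by a segment's duration."""
    return origin_time, origin_time + segment.duration_min * 60.0
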