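"""Seeded synthetic datasets: array, winds, birds, flights, detections.

The generator produces paired (truth, observables) bundles with the
statistical structure the analysis assumes: a five-station coastal array,
layered wind fields on a 32 km / 3 h lattice with level-specific means,
age-dependent departure choosiness (adults wait for supportive tailwinds),
groundspeeds from the wind-triangle relation with an ocean-stage climb
penalty, and signal-strength passage curves sampled on each station's scan
cycle.  Everything is reproducible from (seed, config).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .geometry import destination_point, haversine_km, initial_bearing_deg, angle_difference
from .telemetry import AntennaSpec, StationSpec, classify_crossing
from .wind import DEFAULT_LEVELS, uv_from_speed_direction, wind_components

__all__ = [
    "SimulationConfig",
    "TrueFlight",
    "SyntheticDataset",
    "default_array",
    "base_level_altitude",
    "simulate_wind_field",
    "simulate_departures",
    "simulate_flight",
    "wind_triangle_groundspeed",
    "render_detections",
    "generate_dataset",
    "simulate_probe_table",
    "simulate_path_table",
]

logger = logging.getLogger(__name__)

SEASON_START_EPOCH = 1285027200.0  # 2010-09-21 00:00:00 UTC
DAY_S = 86400.0

#: Default per-level mean wind speed (m/s); direction-to is shared.
DEFAULT_LEVEL_SPEEDS: dict[str, float] = {
    "10m": 2.0, "30m": 2.5, "1000mb": 3.0, "975mb": 3.8, "950mb": 4.8,
    "925mb": 6.5, "900mb": 5.6, "875mb": 5.0, "850mb": 4.6, "825mb": 4.2,
    "800mb": 3.9, "775mb": 3.7, "750mb": 3.5, "725mb": 3.4, "700mb": 3.3,
    "675mb": 3.2, "650mb": 3.1,
}

#: Printed standardized path coefficients used as generating defaults.
DEFAULT_PATH_COEFFICIENTS: dict[str, float] = {
    "tailwind_intercept": -0.13,
    "tailwind_age": 0.80,
    "tailwind_stage": -0.70,
    "duration_intercept": -0.23,
    "duration_tailwind": -0.69,
    "duration_tailwind2": 0.23,
    "log_gs_intercept": 0.51,
    "log_gs_tailwind": 0.58,
    "log_gs_stage": -0.87,
}


def base_level_altitude(level_id: str) -> float:
    """Climatological default altitude label (m) for a level."""
    if level_id.endswith("mb"):
        p = float(level_id[:-2])
        return 164.0 + (1000.0 - p) * 8.7
    return float(level_id[:-1])


@dataclass
class SimulationConfig:
    seed: int = 1
    n_adults: int = 19
    n_juveniles: int = 9
    n_nest_pairs: int = 8
    # flight mechanics
    airspeed_ms: float = 12.0
    climb_rate_ms: float = 1.5
    cruise_altitude_m: float = 800.0
    climb_penalty: bool = True
    ocean_airspeed_ms: float = 9.0  # climbing/searching airspeed over the ocean
    # departure behaviour
    adult_tailwind_threshold_ms: float = 4.0
    juvenile_tailwind_threshold_ms: float = -math.inf
    departure_level: str = "1000mb"
    departure_track_deg: float = 276.0
    departure_hour_utc: float = 22.5
    departure_center_evening: float = 13.0
    departure_spread_evenings: float = 6.0
    # wind field
    levels: tuple[str, ...] = DEFAULT_LEVELS
    level_speeds: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_LEVEL_SPEEDS))
    level_direction_to_deg: float = 260.0
    shared_evening_sd: float = 1.0
    level_evening_sd: float = 2.0
    node_noise_sd: float = 0.3
    geopotential_noise_sd_m: float = 45.0
    lattice_spacing_km: float = 32.0
    wind_time_step_s: float = 3.0 * 3600.0
    season_start: float = SEASON_START_EPOCH
    n_evenings: int = 30
    # stage wind levels (generating truth)
    ocean_wind_level: str = "1000mb"
    coast_wind_level: str = "925mb"
    # stochastic observation model
    duration_noise_s: float = 120.0
    p_missing_coast: float = 0.2
    crossing_offset_probs: tuple[float, float, float] = (25 / 28, 2 / 28, 1 / 28)
    pulse_rate_s: float = 5.0
    spurious_per_series: float = 0.0
    pattern_strength_s0: float = 100.0
    strength_decay_per_min2: float = 10.0
    strength_dist_per_km: float = 1.0
    strength_noise_sd: float = 0.8
    ground_strength: float = 60.0
    antenna_half_beam_deg: float = 45.0
    close_range_km: float = 2.0
    render_margin_s: float = 600.0

    def threshold(self, age: str) -> float:
        return (
            self.adult_tailwind_threshold_ms
            if age == "adult"
            else self.juvenile_tailwind_threshold_ms
        )


def default_array() -> list[StationSpec]:
    """The five-station array: three island stations and two coastal ones."""
    island_kw = dict(scan_on_s=21.6, scan_period_s=43.2, detection_range_km=15.0)
    quad = tuple(AntennaSpec(b, elements=4) for b in (45.0, 135.0, 225.0, 315.0))
    return [
        StationSpec("KentIs-N", 44.5917, -66.7583, quad, **island_kw),
        StationSpec("KentIs-C", 44.5833, -66.75, quad, **island_kw),
        StationSpec("KentIs-S", 44.575, -66.7417, quad, **island_kw),
        StationSpec(
            "InnerDoubleHeadshotIs", 44.6, -67.266667,
            (AntennaSpec(55.0), AntennaSpec(235.0)),
            scan_on_s=14.0, scan_period_s=28.0, detection_range_km=15.0,
        ),
        StationSpec(
            "PetitMananPt", 44.4, -67.9,
            (AntennaSpec(330.0), AntennaSpec(150.0)),
            scan_on_s=14.0, scan_period_s=28.0, detection_range_km=15.0,
        ),
    ]


# ---------------------------------------------------------------------------
# wind field


def _evening_vectors(config: SimulationConfig, rng: np.random.Generator):
    """Per (level, evening) wind vectors: level mean + shared + level effect."""
    levels = list(config.levels)
    n_l, n_d = len(levels), config.n_evenings
    u0 = np.array([
        uv_from_speed_direction(
            config.level_speeds.get(lev, 3.0), config.level_direction_to_deg
        )
        for lev in levels
    ])  # (n_l, 2)
    shared = rng.normal(0.0, config.shared_evening_sd, size=(n_d, 2))
    level_eff = rng.normal(0.0, config.level_evening_sd, size=(n_l, n_d, 2))
    vec = u0[:, None, :] + shared[None, :, :] + level_eff
    heights = np.empty((n_l, n_d))
    for i, lev in enumerate(levels):
        base = base_level_altitude(lev)
        if lev.endswith("mb"):
            heights[i] = base + rng.normal(0.0, config.geopotential_noise_sd_m, size=n_d)
        else:
            heights[i] = base
    return levels, vec, heights


def simulate_wind_field(
    config: SimulationConfig,
    rng: np.random.Generator,
    stations: list[StationSpec] | None = None,
):
    """Layered wind lattice plus the per-evening truth vectors.

    Returns ``(winds, evening)`` where ``winds`` is a long DataFrame with one
    row per (level, lattice node, time) carrying speed/direction, u/v and
    geopotential height, and ``evening`` holds the noiseless per-(level,
    evening) wind vectors the flights are generated from.
    """
    stations = stations or default_array()
    levels, vec, heights = _evening_vectors(config, rng)
    lats = np.array([s.lat for s in stations])
    lons = np.array([s.lon for s in stations])
    dlat = config.lattice_spacing_km / 111.195
    dlon = config.lattice_spacing_km / (111.195 * math.cos(math.radians(lats.mean())))
    lat_nodes = np.arange(lats.min() - 0.3, lats.max() + 0.3 + dlat, dlat)
    lon_nodes = np.arange(lons.min() - 0.3, lons.max() + 0.3 + dlon, dlon)
    times = config.season_start + np.arange(
        0.0, (config.n_evenings + 1) * DAY_S, config.wind_time_step_s
    )
    # nights run noon-to-noon so a post-midnight flight keeps its evening's wind
    days = np.clip(
        ((times - config.season_start - 0.5 * DAY_S) // DAY_S).astype(int),
        0,
        config.n_evenings - 1,
    )

    glat, glon = np.meshgrid(lat_nodes, lon_nodes, indexing="ij")
    glat, glon = glat.ravel(), glon.ravel()
    n_nodes, n_t = glat.size, times.size
    frames = []
    for i, lev in enumerate(levels):
        u = vec[i, days, 0][None, :] + rng.normal(0.0, config.node_noise_sd, (n_nodes, n_t))
        v = vec[i, days, 1][None, :] + rng.normal(0.0, config.node_noise_sd, (n_nodes, n_t))
        frames.append(
            pd.DataFrame(
                {
                    "level_id": lev,
                    "lat": np.repeat(glat, n_t),
                    "lon": np.repeat(glon, n_t),
                    "time": np.tile(times, n_nodes),
                    "u": u.ravel(),
                    "v": v.ravel(),
                    "geopotential_height_m": (
                        np.tile(heights[i, days], n_nodes)
                        if lev.endswith("mb")
                        else np.nan
                    ),
                }
            )
        )
    winds = pd.concat(frames, ignore_index=True)
    speed = np.hypot(winds["u"], winds["v"])
    winds["wind_speed_ms"] = speed
    winds["wind_dir_to_deg"] = np.mod(np.degrees(np.arctan2(winds["u"], winds["v"])), 360.0)
    evening = {
        "levels": levels,
        "vectors": vec,        # (level, evening, uv)
        "heights": heights,    # (level, evening)
    }
    return winds, evening


def _evening_tailwind(evening, level: str, track_deg: float) -> np.ndarray:
    i = evening["levels"].index(level)
    u, v = evening["vectors"][i, :, 0], evening["vectors"][i, :, 1]
    speed = np.hypot(u, v)
    direction = np.mod(np.degrees(np.arctan2(u, v)), 360.0)
    tail, _ = wind_components(speed, direction, track_deg)
    return np.asarray(tail)


# ---------------------------------------------------------------------------
# birds and departures


def make_birds(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    ages = ["adult"] * config.n_adults + ["juvenile"] * config.n_juveniles
    tags = [f"T{i + 1:03d}" for i in range(len(ages))]
    nests = []
    for i, age in enumerate(ages):
        if age == "adult":
            nests.append(f"N{i + 1:03d}")
        else:
            j = i - config.n_adults  # juvenile index
            if j < config.n_nest_pairs and j < config.n_adults:
                nests.append(f"N{j + 1:03d}")  # shares a nest with adult j
            else:
                nests.append(f"N{i + 1:03d}")
    mass = np.where(
        np.array(ages) == "adult",
        rng.normal(19.4, 1.2, len(ages)),
        rng.normal(18.5, 1.5, len(ages)),
    )
    return pd.DataFrame({"tag_id": tags, "age": ages, "nest_id": nests, "mass_g": mass.round(2)})


def simulate_departures(
    birds: pd.DataFrame,
    evening_tailwinds: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """First-qualifying-evening departure rule.

    Each bird becomes ready on a random evening and departs on the first
    subsequent evening whose departure-level tailwind meets its age-specific
    threshold (juveniles by default accept anything).  Birds with no
    qualifying evening left in the season are marked non-departed.
    """
    n_e = len(evening_tailwinds)
    out = []
    for _, bird in birds.iterrows():
        ready = int(
            np.clip(
                round(rng.normal(config.departure_center_evening, config.departure_spread_evenings)),
                0, n_e - 1,
            )
        )
        thr = config.threshold(bird["age"])
        evening = next(
            (e for e in range(ready, n_e) if evening_tailwinds[e] >= thr), None
        )
        if evening is None:
            logger.info("bird %s never met its departure threshold", bird["tag_id"])
        out.append({"tag_id": bird["tag_id"], "ready_evening": ready, "departure_evening": evening})
    return birds.merge(pd.DataFrame(out), on="tag_id")


# ---------------------------------------------------------------------------
# flights


def wind_triangle_groundspeed(
    airspeed_ms: float, tailwind_ms: float, crosswind_ms: float, climb_rate_ms: float = 0.0
) -> float:
    """Along-track groundspeed under full drift compensation.

    ``tailwind + sqrt(airspeed^2 - climb^2 - crosswind^2)``; raises if the
    crosswind exceeds the horizontal airspeed (the track cannot be held).
    """
    h2 = airspeed_ms**2 - climb_rate_ms**2
    if h2 <= 0:
        raise ValueError("climb rate exceeds airspeed")
    rem = h2 - crosswind_ms**2
    if rem <= 0:
        raise ValueError("crosswind exceeds horizontal airspeed; track cannot be held")
    return tailwind_ms + math.sqrt(rem)


@dataclass
class TrueFlight:
    tag_id: str
    age: str
    nest_id: str
    kent_station: str
    departure_time: float
    # ocean stage
    ocean_pattern: str
    ocean_origin: tuple[float, float]
    ocean_crossing: tuple[float, float]
    ocean_track_deg: float
    ocean_distance_km: float
    ocean_duration_s: float
    ocean_tailwind_ms: float
    ocean_crosswind_ms: float
    arrival_idh_time: float
    # coastal stage (None-filled when the bird misses the southern station)
    detected_pm: bool = True
    coast_pattern: str = ""
    coast_crossing: tuple[float, float] | None = None
    coast_track_deg: float = math.nan
    coast_distance_km: float = math.nan
    coast_duration_s: float = math.nan
    coast_tailwind_ms: float = math.nan
    coast_crosswind_ms: float = math.nan
    arrival_pm_time: float = math.nan

    @property
    def ocean_groundspeed_ms(self) -> float:
        return self.ocean_distance_km * 1000.0 / self.ocean_duration_s

    @property
    def coast_groundspeed_ms(self) -> float:
        return self.coast_distance_km * 1000.0 / self.coast_duration_s


def _draw_crossing(station: StationSpec, probs, rng: np.random.Generator, time: float):
    pattern = rng.choice(
        ["first_antenna_only", "both", "second_antenna_only"], p=np.asarray(probs) / np.sum(probs)
    )
    ev = classify_crossing(str(pattern), station, time)
    return str(pattern), (ev.lat, ev.lon)


def _stage_wind(evening, config, level: str, evening_idx: int, track_deg: float):
    i = evening["levels"].index(level)
    u, v = evening["vectors"][i, evening_idx]
    speed = math.hypot(u, v)
    direction = math.degrees(math.atan2(u, v)) % 360.0
    return wind_components(speed, direction, track_deg)


def simulate_flight(
    bird: pd.Series,
    evening: dict,
    config: SimulationConfig,
    rng: np.random.Generator,
    stations: list[StationSpec],
) -> TrueFlight | None:
    """Generate one bird's two-stage flight from its departure evening."""
    if bird["departure_evening"] is None or (
        isinstance(bird["departure_evening"], float) and math.isnan(bird["departure_evening"])
    ):
        return None
    e = int(bird["departure_evening"])
    by_name = {s.name: s for s in stations}
    kent_names = [s.name for s in stations if s.name.startswith("KentIs")]
    kent = by_name[str(rng.choice(kent_names))]
    idh = by_name["InnerDoubleHeadshotIs"]
    pm = by_name["PetitMananPt"]

    dep_time = (
        config.season_start
        + e * DAY_S
        + config.departure_hour_utc * 3600.0
        + rng.normal(0.0, 1800.0)
    )
    ocean_pattern, ocean_cross = _draw_crossing(idh, config.crossing_offset_probs, rng, dep_time)
    ocean_track = initial_bearing_deg(kent.lat, kent.lon, *ocean_cross)
    ocean_dist = haversine_km(kent.lat, kent.lon, *ocean_cross)
    tail_o, cross_o = _stage_wind(evening, config, config.ocean_wind_level, e, ocean_track)
    va_ocean = config.ocean_airspeed_ms if config.climb_penalty else config.airspeed_ms
    climb = config.climb_rate_ms if config.climb_penalty else 0.0
    try:
        gs_o = wind_triangle_groundspeed(va_ocean, tail_o, cross_o, climb)
    except ValueError:
        logger.warning("bird %s aborted: crosswind exceeds airspeed", bird["tag_id"])
        return None
    dur_o = ocean_dist * 1000.0 / gs_o + rng.normal(0.0, config.duration_noise_s)
    dur_o = max(dur_o, 0.5 * ocean_dist * 1000.0 / gs_o)
    arr_idh = dep_time + dur_o

    flight = TrueFlight(
        tag_id=bird["tag_id"],
        age=bird["age"],
        nest_id=bird["nest_id"],
        kent_station=kent.name,
        departure_time=dep_time,
        ocean_pattern=ocean_pattern,
        ocean_origin=(kent.lat, kent.lon),
        ocean_crossing=ocean_cross,
        ocean_track_deg=ocean_track,
        ocean_distance_km=ocean_dist,
        ocean_duration_s=dur_o,
        ocean_tailwind_ms=tail_o,
        ocean_crosswind_ms=cross_o,
        arrival_idh_time=arr_idh,
    )

    detected_pm = bool(rng.random() >= config.p_missing_coast)
    if detected_pm:
        coast_pattern, coast_cross = _draw_crossing(pm, config.crossing_offset_probs, rng, arr_idh)
    else:
        # the bird turns elsewhere: aim well outside the southern station's range
        coast_pattern, coast_cross = "", destination_point(pm.lat, pm.lon, 150.0, 25.0)
    coast_track = initial_bearing_deg(*ocean_cross, *coast_cross)
    coast_dist = haversine_km(*ocean_cross, *coast_cross)
    tail_c, cross_c = _stage_wind(evening, config, config.coast_wind_level, e, coast_track)
    try:
        gs_c = wind_triangle_groundspeed(config.airspeed_ms, tail_c, cross_c, 0.0)
    except ValueError:
        logger.warning("bird %s coastal leg aborted: crosswind too strong", bird["tag_id"])
        return flight
    dur_c = coast_dist * 1000.0 / gs_c + rng.normal(0.0, config.duration_noise_s)
    dur_c = max(dur_c, 0.5 * coast_dist * 1000.0 / gs_c)
    flight.detected_pm = detected_pm
    flight.coast_pattern = coast_pattern
    flight.coast_crossing = coast_cross
    flight.coast_track_deg = coast_track
    flight.coast_distance_km = coast_dist
    flight.coast_duration_s = dur_c
    flight.coast_tailwind_ms = tail_c
    flight.coast_crosswind_ms = cross_c
    flight.arrival_pm_time = arr_idh + dur_c
    return flight


# ---------------------------------------------------------------------------
# detection rendering


def _positions(flight: TrueFlight, times: np.ndarray):
    """Piecewise position of a bird along its (extended) true path."""
    lat = np.empty_like(times)
    lon = np.empty_like(times)
    grounded = times < flight.departure_time
    lat[grounded], lon[grounded] = flight.ocean_origin

    def leg(mask, origin, track, speed_ms, t0):
        if not np.any(mask):
            return
        d_km = speed_ms * (times[mask] - t0) / 1000.0
        la, lo = destination_point(origin[0], origin[1], track, d_km)
        lat[mask], lon[mask] = la, lo

    gs_o = flight.ocean_distance_km * 1000.0 / flight.ocean_duration_s
    m1 = (~grounded) & (times <= flight.arrival_idh_time)
    leg(m1, flight.ocean_origin, flight.ocean_track_deg, gs_o, flight.departure_time)
    m2 = times > flight.arrival_idh_time
    if flight.coast_crossing is not None and np.isfinite(flight.coast_duration_s):
        gs_c = flight.coast_distance_km * 1000.0 / flight.coast_duration_s
        leg(m2, flight.ocean_crossing, flight.coast_track_deg, gs_c, flight.arrival_idh_time)
    else:
        leg(m2, flight.ocean_crossing, flight.ocean_track_deg, gs_o, flight.arrival_idh_time)
    return lat, lon


def render_detections(
    flights: list[TrueFlight],
    stations: list[StationSpec],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Signal-strength passage curves sampled on each station's scan cycle.

    Pulses occur at the tag's pulse rate within the receiver's on-windows;
    an antenna registers a pulse when the bird lies in its beam (or within
    the close-range radius, where both antennas hear it) and inside the
    detection range.  Strength peaks at the station's true event time.
    Optional spurious detections are injected at uniform random times.
    """
    rows = []
    margin = config.render_margin_s
    for fi, fl in enumerate(flights):
        freq_idx = fi % 3
        phase = rng.uniform(0.0, config.pulse_rate_s)
        t_end = (
            fl.arrival_pm_time if np.isfinite(fl.arrival_pm_time) else fl.arrival_idh_time + 2400.0
        ) + margin
        t0 = fl.departure_time - 300.0
        times = np.arange(t0 + phase, t_end, config.pulse_rate_s)
        lat, lon = _positions(fl, times)
        grounded = times < fl.departure_time
        for st in stations:
            in_on = (
                np.mod(times - freq_idx * st.scan_on_s, st.scan_period_s) < st.scan_on_s
            )
            d = np.asarray(haversine_km(lat, lon, st.lat, st.lon))
            in_range = d <= st.detection_range_km
            if st.name == fl.kent_station:
                t_event = fl.departure_time
            elif st.name == "InnerDoubleHeadshotIs":
                t_event = fl.arrival_idh_time
            elif st.name == "PetitMananPt":
                t_event = fl.arrival_pm_time if fl.detected_pm else None
            else:
                t_event = fl.departure_time  # neighbouring island stations
            if t_event is None:
                t_event = np.inf  # no passage peak; range gate removes everything
            usable = in_on & in_range & ~(grounded & (d > 1.5))
            if not np.any(usable):
                continue
            dt_min = (times[usable] - t_event) / 60.0
            strength = (
                config.pattern_strength_s0
                - config.strength_decay_per_min2 * dt_min**2
                - config.strength_dist_per_km * d[usable]
            )
            strength = np.where(
                grounded[usable], config.ground_strength - d[usable], strength
            )
            strength = strength + rng.normal(0.0, config.strength_noise_sd, strength.shape)
            keep = strength > 20.0
            if not np.any(keep):
                continue
            tt = times[usable][keep]
            ss = strength[keep]
            blat, blon = lat[usable][keep], lon[usable][keep]
            bearings = np.degrees(
                np.arctan2(
                    np.radians(blon - st.lon) * np.cos(np.radians(st.lat)),
                    np.radians(blat - st.lat),
                )
            ) % 360.0
            dd = d[usable][keep]
            for ai, ant in enumerate(st.antennas):
                diff = np.abs(angle_difference(bearings, ant.boresight_deg))
                hear = (diff <= config.antenna_half_beam_deg) | (dd <= config.close_range_km)
                for t, s in zip(tt[hear], ss[hear]):
                    rows.append((fl.tag_id, st.name, ai, float(t), float(s)))
            if config.spurious_per_series > 0:
                n_sp = rng.poisson(config.spurious_per_series)
                for _ in range(n_sp):
                    rows.append(
                        (
                            fl.tag_id,
                            st.name,
                            int(rng.integers(0, len(st.antennas))),
                            float(rng.uniform(tt.min(), tt.max())),
                            float(rng.uniform(40.0, 80.0)),
                        )
                    )
    det = pd.DataFrame(
        rows, columns=["tag_id", "station", "antenna_index", "time", "signal_strength"]
    )
    return det.sort_values(["tag_id", "station", "time"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# end-to-end bundle


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    stations: list[StationSpec]
    winds: pd.DataFrame
    birds: pd.DataFrame
    detections: pd.DataFrame
    flights: list[TrueFlight]
    truth: pd.DataFrame

    def write(self, outdir) -> None:
        from . import io as _io

        _io.write_dataset(self, outdir)


def _truth_frame(flights: list[TrueFlight]) -> pd.DataFrame:
    rows = []
    for fl in flights:
        rows.append(
            {
                "tag_id": fl.tag_id, "stage": "ocean", "age": fl.age, "nest_id": fl.nest_id,
                "origin_time": fl.departure_time, "dest_time": fl.arrival_idh_time,
                "origin_lat": fl.ocean_origin[0], "origin_lon": fl.ocean_origin[1],
                "dest_lat": fl.ocean_crossing[0], "dest_lon": fl.ocean_crossing[1],
                "track_deg": fl.ocean_track_deg, "distance_km": fl.ocean_distance_km,
                "duration_min": fl.ocean_duration_s / 60.0,
                "groundspeed_ms": fl.ocean_groundspeed_ms,
                "tailwind_ms": fl.ocean_tailwind_ms, "crosswind_ms": fl.ocean_crosswind_ms,
                "pattern": fl.ocean_pattern,
            }
        )
        if fl.detected_pm and fl.coast_crossing is not None:
            rows.append(
                {
                    "tag_id": fl.tag_id, "stage": "coast", "age": fl.age, "nest_id": fl.nest_id,
                    "origin_time": fl.arrival_idh_time, "dest_time": fl.arrival_pm_time,
                    "origin_lat": fl.ocean_crossing[0], "origin_lon": fl.ocean_crossing[1],
                    "dest_lat": fl.coast_crossing[0], "dest_lon": fl.coast_crossing[1],
                    "track_deg": fl.coast_track_deg, "distance_km": fl.coast_distance_km,
                    "duration_min": fl.coast_duration_s / 60.0,
                    "groundspeed_ms": fl.coast_groundspeed_ms,
                    "tailwind_ms": fl.coast_tailwind_ms, "crosswind_ms": fl.coast_crosswind_ms,
                    "pattern": fl.coast_pattern,
                }
            )
    return pd.DataFrame(rows)


def generate_dataset(config: SimulationConfig | None = None, seed: int | None = None) -> SyntheticDataset:
    """Full paired (observables, truth) bundle from a simulation config."""
    config = config or SimulationConfig()
    if seed is not None:
        config = SimulationConfig(**{**asdict(config), "seed": seed})
    for attr in ("departure_level", "ocean_wind_level", "coast_wind_level"):
        if getattr(config, attr) not in config.levels:
            raise ValueError(f"{attr} {getattr(config, attr)!r} not in config.levels")
    rng = np.random.default_rng(config.seed)
    stations = default_array()
    winds, evening = simulate_wind_field(config, rng, stations)
    birds = make_birds(config, rng)
    dep_tail = _evening_tailwind(evening, config.departure_level, config.departure_track_deg)
    birds = simulate_departures(birds, dep_tail, config, rng)
    flights = []
    for _, bird in birds.iterrows():
        fl = simulate_flight(bird, evening, config, rng, stations)
        if fl is not None:
            flights.append(fl)
    detections = render_detections(flights, stations, config, rng)
    return SyntheticDataset(
        config=config,
        stations=stations,
        winds=winds,
        birds=birds,
        detections=detections,
        flights=flights,
        truth=_truth_frame(flights),
    )


# ---------------------------------------------------------------------------
# lightweight statistical generators for recovery studies


def simulate_probe_table(
    seed: int,
    *,
    n_segments: int = 24,
    levels: tuple[str, ...] = ("10m", "30m", "1000mb", "975mb", "950mb", "925mb", "900mb"),
    true_level: str = "925mb",
    slope_min_per_ms: float = -6.0,
    base_duration_min: float = 75.0,
    tailwind_sd_ms: float = 3.0,
    level_correlation: float = 0.5,
    noise_min: float = 8.0,
    with_nests: bool = True,
) -> pd.DataFrame:
    """Segments x levels table where duration is driven by one level's wind.

    Winds across levels share a common component (``level_correlation`` is
    the cross-level correlation); flight duration responds linearly to the
    tailwind at ``true_level`` only.  Long format suitable for
    :func:`aeropath.altitude.altitude_scan`.
    """
    if true_level not in levels:
        raise ValueError("true_level must be among levels")
    rng = np.random.default_rng(seed)
    n_l = len(levels)
    rho = math.sqrt(level_correlation)
    shared = rng.normal(0.0, 1.0, n_segments)
    z = rng.normal(0.0, 1.0, (n_l, n_segments))
    tail = tailwind_sd_ms * (rho * shared + math.sqrt(1.0 - rho**2) * z)
    shared_c = rng.normal(0.0, 1.0, n_segments)
    zc = rng.normal(0.0, 1.0, (n_l, n_segments))
    cross = tailwind_sd_ms * (rho * shared_c + math.sqrt(1.0 - rho**2) * zc)
    i_true = levels.index(true_level)
    duration = (
        base_duration_min
        + slope_min_per_ms * tail[i_true]
        + rng.normal(0.0, noise_min, n_segments)
    )
    nest = (
        np.array([f"N{i // 2:02d}" for i in range(n_segments)])
        if with_nests
        else np.array([f"N{i:02d}" for i in range(n_segments)])
    )
    frames = []
    for i, lev in enumerate(levels):
        frames.append(
            pd.DataFrame(
                {
                    "tag_id": [f"T{j:03d}" for j in range(n_segments)],
                    "nest_id": nest,
                    "level_id": lev,
                    "level_altitude_m": base_level_altitude(lev),
                    "tailwind_ms": tail[i],
                    "crosswind_ms": cross[i],
                    "duration_min": duration,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_path_table(
    seed: int,
    *,
    n_individuals: int = 100,
    coefficients: dict[str, float] | None = None,
    tailwind_noise_sd: float = 0.85,
    response_noise_sd: float = 0.5,
    nest_sd: float = 0.2,
    individual_sd: float = 0.2,
    age_effect: bool = True,
    stage_effect_on_response: bool | None = None,
) -> pd.DataFrame:
    """Analysis-scale table generated from the path-diagram structure.

    Each individual contributes one ocean and one coastal row (n = 2 x
    ``n_individuals``).  Tailwind responds to age and stage; flight duration
    responds to tailwind (with curvature); log groundspeed responds to
    tailwind and, by default, directly to stage.  Columns are already on the
    standardized analysis scale and feed :func:`aeropath.pathmodel.fit_path`
    directly.
    """
    c = dict(DEFAULT_PATH_COEFFICIENTS)
    c.update(coefficients or {})
    rng = np.random.default_rng(seed)
    n = n_individuals
    age = (rng.random(n) < 0.5).astype(float)
    nest = np.arange(n) // 2
    b_nest = rng.normal(0.0, nest_sd, nest.max() + 1)
    b_ind = rng.normal(0.0, individual_sd, n)
    rows = []
    beta_age = c["tailwind_age"] if age_effect else 0.0
    gs_stage = c["log_gs_stage"]
    if stage_effect_on_response is False:
        gs_stage = 0.0
    for stage_name, stage_val in (("ocean", 1.0), ("coast", 0.0)):
        tail = (
            c["tailwind_intercept"]
            + beta_age * age
            + c["tailwind_stage"] * stage_val
            + b_nest[nest]
            + b_ind
            + rng.normal(0.0, tailwind_noise_sd, n)
        )
        cross = rng.normal(0.0, 1.0, n)
        duration = (
            c["duration_intercept"]
            + c["duration_tailwind"] * tail
            + c["duration_tailwind2"] * tail**2
            + 0.5 * b_nest[nest]
            + 0.5 * b_ind
            + rng.normal(0.0, response_noise_sd, n)
        )
        log_gs = (
            c["log_gs_intercept"]
            + c["log_gs_tailwind"] * tail
            + gs_stage * stage_val
            + 0.5 * b_nest[nest]
            + 0.5 * b_ind
            + rng.normal(0.0, response_noise_sd, n)
        )
        for i in range(n):
            rows.append(
                {
                    "individual_id": f"I{i:03d}",
                    "nest_id": f"N{nest[i]:03d}",
                    "age": age[i],
                    "stage": stage_val,
                    "tailwind": tail[i],
                    "crosswind": cross[i],
                    "flight_duration": duration[i],
                    "log_groundspeed": log_gs[i],
                }
            )
    return pd.DataFrame(rows)
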