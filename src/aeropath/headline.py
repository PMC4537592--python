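"""Small derived-quantity helpers used in reporting.

These turn summary statistics (median movement rates and groundspeeds) into
the headline comparisons a report prints: the extra distance covered per
flight night, the coast/ocean speed ratio, and the adult-juvenile speed gap.
"""

from __future__ import annotations

__all__ = [
    "extra_nightly_distance_km",
    "stage_speed_ratio",
    "age_speed_difference_ms",
]


def extra_nightly_distance_km(
    adult_rate_kmh: float, juvenile_rate_kmh: float, flight_hours: float
) -> float:
    """Extra distance (km) the faster age class covers over one flight night."""
    if flight_hours < 0:
        raise ValueError("flight_hours must be nonnegative")
    return (adult_rate_kmh - juvenile_rate_kmh) * flight_hours


def stage_speed_ratio(coast_speed_ms: float, ocean_speed_ms: float) -> float:
    """Ratio of coastal to ocean groundspeed."""
    if ocean_speed_ms <= 0:
        raise ValueError("ocean speed must be positive")
    return coast_speed_ms / ocean_speed_ms


def age_speed_difference_ms(adult_speed_ms: float, juvenile_speed_ms: float) -> float:
    """Adult minus juvenile groundspeed (m/s)."""
    return adult_speed_ms - juvenile_speed_ms
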