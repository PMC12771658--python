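"""Solar periods, completeness filtering, and time-activity budgets.

Every burst or scan observation is assigned to a diurnal or nocturnal period
from the local solar day (NOAA solar-position computation; civil twilight
for dawn/dusk). Diurnal is the half-open interval [sunrise, sunset); every
instant belongs to exactly one period. Bird-days missing more than 5% of
their expected bursts are dropped before aggregation. Budgets are counts and
proportions of the four behavior classes (feeding, flying, preening,
resting) per scope (bird, period, or pooled).

Scan-sample budgets are summarised two ways — a mean of per-scan proportion
vectors, and pooled counts — because the two conventions genuinely differ
when scans vary in flock size; both are returned and neither is privileged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bioenergetics import BEHAVIORS


@dataclass(frozen=True)
class SolarDay:
    """Sunlight phases (UTC) for one date at one site."""

    date: object
    lat: float
    lon: float
    dawn: pd.Timestamp
    sunrise: pd.Timestamp
    solar_noon: pd.Timestamp
    sunset: pd.Timestamp
    dusk: pd.Timestamp

    @property
    def daylight_hours(self) -> float:
        return (self.sunset - self.sunrise).total_seconds() / 3600.0


def _solar_geometry(jd: float) -> tuple[float, float]:
    """(declination deg, equation of time min) for a Julian day (NOAA)."""
    jc = (jd - 2451545.0) / 36525.0
    gmls = (280.46646 + jc * (36000.76983 + jc * 0.0003032)) % 360.0
    gmas = 357.52911 + jc * (35999.05029 - 0.0001537 * jc)
    eeo = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)
    seqc = (
        math.sin(math.radians(gmas)) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
        + math.sin(math.radians(2 * gmas)) * (0.019993 - 0.000101 * jc)
        + math.sin(math.radians(3 * gmas)) * 0.000289
    )
    stl = gmls + seqc
    omega = 125.04 - 1934.136 * jc
    sal = stl - 0.00569 - 0.00478 * math.sin(math.radians(omega))
    moe = (
        23.0 + (26.0 + (21.448 - jc * (46.815 + jc * (0.00059 - jc * 0.001813))) / 60.0) / 60.0
    )
    oc = moe + 0.00256 * math.cos(math.radians(omega))
    decl = math.degrees(
        math.asin(math.sin(math.radians(oc)) * math.sin(math.radians(sal)))
    )
    vary = math.tan(math.radians(oc / 2.0)) ** 2
    eot = 4.0 * math.degrees(
        vary * math.sin(2.0 * math.radians(gmls))
        - 2.0 * eeo * math.sin(math.radians(gmas))
        + 4.0 * eeo * vary * math.sin(math.radians(gmas)) * math.cos(2.0 * math.radians(gmls))
        - 0.5 * vary**2 * math.sin(4.0 * math.radians(gmls))
        - 1.25 * eeo**2 * math.sin(2.0 * math.radians(gmas))
    )
    return decl, eot


def _hour_angle(lat: float, decl: float, zenith: float) -> float:
    """Sunrise hour angle (deg) for a given zenith; raises if sun never there."""
    cos_ha = (
        math.cos(math.radians(zenith))
        - math.sin(math.radians(lat)) * math.sin(math.radians(decl))
    ) / (math.cos(math.radians(lat)) * math.cos(math.radians(decl)))
    if not -1.0 <= cos_ha <= 1.0:
        raise ValueError("sun never reaches the requested zenith at this latitude/date")
    return math.degrees(math.acos(cos_ha))


def solar_phases(date, lat: float, lon: float) -> SolarDay:
    """Dawn, sunrise, solar noon, sunset and dusk (UTC) for one date.

    Sunrise/sunset at zenith 90.833 deg (refraction + solar radius), civil
    twilight (zenith 96 deg) for dawn/dusk. Latitudes poleward of 66 deg are
    rejected: polar day/night is out of scope.
    """
    if abs(lat) >= 66.0:
        raise ValueError("polar latitudes (|lat| >= 66 deg) are unsupported")
    date = pd.Timestamp(date).normalize()
    # Julian day at civil midnight UTC, then iterate geometry at solar noon
    jd0 = date.to_julian_date() + 0.5  # .to_julian_date() of midnight ends in .5
    decl, eot = _solar_geometry(jd0 + 0.5 - lon / 360.0)
    noon_min = 720.0 - 4.0 * lon - eot
    decl, eot = _solar_geometry(jd0 + noon_min / 1440.0)
    noon_min = 720.0 - 4.0 * lon - eot
    ha_sun = _hour_angle(lat, decl, 90.833)
    ha_civil = _hour_angle(lat, decl, 96.0)

    def at(minutes: float) -> pd.Timestamp:
        return date + pd.Timedelta(minutes=minutes)

    return SolarDay(
        date=date.date(),
        lat=lat,
        lon=lon,
        dawn=at(noon_min - 4.0 * ha_civil),
        sunrise=at(noon_min - 4.0 * ha_sun),
        solar_noon=at(noon_min),
        sunset=at(noon_min + 4.0 * ha_sun),
        dusk=at(noon_min + 4.0 * ha_civil),
    )


def assign_period(timestamp: pd.Timestamp, solar: SolarDay) -> str:
    """'diurnal' iff sunrise <= t < sunset, else 'nocturnal'."""
    return "diurnal" if solar.sunrise <= timestamp < solar.sunset else "nocturnal"


def assign_periods(timestamps: pd.Series, lat: float, lon: float) -> pd.Series:
    """Vectorised period assignment; solar phases cached per date."""
    ts = pd.to_datetime(timestamps)
    out = pd.Series("nocturnal", index=ts.index)
    for date, idx in ts.groupby(ts.dt.normalize()).groups.items():
        sol = solar_phases(date, lat, lon)
        sub = ts.loc[idx]
        out.loc[idx[(sub >= sol.sunrise) & (sub < sol.sunset)]] = "diurnal"
    return out


def completeness_filter(
    bursts: pd.DataFrame,
    expected_per_day: int = 144,
    min_fraction: float = 0.95,
) -> pd.DataFrame:
    """Keep bird-days with >= ``min_fraction`` of the expected burst count.

    At the 10-min cadence a full day holds 144 bursts, so the default keeps
    days with >= 137 bursts (137/144 = 0.9514) and drops 136 (0.9444).
    """
    if expected_per_day <= 0:
        raise ValueError("expected_per_day must be positive")
    df = bursts.copy()
    day = df["timestamp_utc"].dt.normalize()
    counts = df.groupby([df["bird_id"], day]).transform("size")
    return df[counts / expected_per_day >= min_fraction]


@dataclass(frozen=True)
class TimeBudget:
    """Behavior counts and proportions for one scope (bird/period/pooled)."""

    scope: str
    counts: dict[str, int]
    n_total: int

    @property
    def proportions(self) -> dict[str, float]:
        if self.n_total == 0:
            return {b: float("nan") for b in BEHAVIORS}
        return {b: self.counts.get(b, 0) / self.n_total for b in BEHAVIORS}

    @classmethod
    def from_counts(cls, counts: dict[str, int], scope: str = "pooled") -> "TimeBudget":
        unknown = set(counts) - set(BEHAVIORS)
        if unknown:
            raise ValueError(f"unknown behaviors: {sorted(unknown)}")
        return cls(scope=scope, counts=dict(counts), n_total=int(sum(counts.values())))


def aggregate_budget(
    records: pd.DataFrame, scope: str = "pooled"
) -> dict[str, TimeBudget]:
    """Time budgets from records with ``behavior`` (+ ``period``/``bird_id``).

    scope 'pooled' returns one budget; 'period' one per period; 'bird' one
    per bird. Pooled totals are the sum over periods by construction.
    """
    if scope == "pooled":
        groups = {"pooled": records}
    elif scope == "period":
        groups = {k: g for k, g in records.groupby("period")}
    elif scope == "bird":
        groups = {k: g for k, g in records.groupby("bird_id")}
    else:
        raise ValueError(f"unknown scope {scope!r}")
    out = {}
    for key, g in groups.items():
        counts = g["behavior"].value_counts().to_dict()
        out[str(key)] = TimeBudget.from_counts(counts, scope=str(key))
    return out


def scan_budget(scans: pd.DataFrame) -> dict[str, object]:
    """Scan-sample budget: per-scan proportion vectors and pooled counts.

    Returns ``per_scan`` (DataFrame of proportion vectors, one row per
    scan), ``mean_of_scans`` (their unweighted mean, the mean +- SE
    reporting convention), and ``pooled`` (a TimeBudget over all
    observations, the contingency-table convention). Scans with zero birds
    are skipped.
    """
    counts = (
        scans.groupby(["scan_id", "behavior"]).size().unstack(fill_value=0)
    )
    for b in BEHAVIORS:
        if b not in counts.columns:
            counts[b] = 0
    counts = counts[list(BEHAVIORS)]
    sizes = counts.sum(axis=1)
    counts = counts[sizes > 0]
    per_scan = counts.div(counts.sum(axis=1), axis=0)
    pooled = TimeBudget.from_counts(counts.sum(axis=0).to_dict(), scope="pooled_scans")
    return {
        "per_scan": per_scan,
        "mean_of_scans": per_scan.mean(axis=0).to_dict(),
        "pooled": pooled,
    }
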