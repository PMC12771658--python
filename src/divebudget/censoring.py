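"""Post-release censoring of transmitter data from GPS displacement.

Birds carrying freshly implanted transmitters move abnormally for the first
days after release. Daily path length (km/day from hourly GPS fixes) is
screened for mean-shift change-points; bursts up to and including the last
detected shift are censored, and birds that survived 14 days or fewer, or
that left the study-area bounding box, are excluded outright.

Change-point detection is binary segmentation on the mean with a normal
(sum-of-squared-error) cost. A split is reported when the standardized mean
difference between the adjacent segments — Cohen's d with the pooled SD —
is at least 0.5. The reported change-point day is the last day of the
pre-shift segment, so a series that shifts after day 2 and after day 4
yields change-points {2, 4} and a censored-through day of 4.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0

#: approximate Maryland portion of the Chesapeake Bay (lat/lon box)
DEFAULT_BBOX = (37.9, 39.7, -77.5, -75.6)  # lat_min, lat_max, lon_min, lon_max


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray | float:
    """Great-circle distance in km (Earth radius 6371.0 km). Vectorised."""
    lat1, lon1, lat2, lon2 = (np.asarray(v, dtype=float) for v in (lat1, lon1, lat2, lon2))
    if np.any(np.abs(lat1) > 90) or np.any(np.abs(lat2) > 90) or np.any(
        np.abs(lon1) > 180
    ) or np.any(np.abs(lon2) > 180):
        raise ValueError("coordinates out of range (|lat| <= 90, |lon| <= 180)")
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2) ** 2
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))
    return float(d) if d.ndim == 0 else d


def daily_displacement(
    fixes: pd.DataFrame,
    release_date=None,
    max_gap: pd.Timedelta = pd.Timedelta(hours=3),
) -> pd.DataFrame:
    """Daily path length (km) for one bird from hourly GPS fixes.

    Consecutive-fix distances are summed by UTC calendar day of the segment's
    start fix; segments spanning a gap longer than ``max_gap`` contribute
    nothing. Day index is relative to ``release_date`` (default: date of the
    first fix), with the release day as day 0.

    Returns columns day (1-based from release, release day = 0) and km.
    """
    fixes = fixes.sort_values("timestamp_utc")
    if len(fixes) < 2:
        import warnings

        warnings.warn("fewer than 2 fixes: empty displacement series")
        return pd.DataFrame({"day": pd.Series(dtype=int), "km": pd.Series(dtype=float)})
    ts = fixes["timestamp_utc"].reset_index(drop=True)
    if ts.duplicated().any() or not ts.is_monotonic_increasing:
        raise ValueError("per-bird timestamps must be strictly increasing")
    lat = fixes["lat"].to_numpy(dtype=float)
    lon = fixes["lon"].to_numpy(dtype=float)
    seg_km = haversine_km(lat[:-1], lon[:-1], lat[1:], lon[1:])
    gaps = ts.diff().iloc[1:].reset_index(drop=True)
    seg_km = np.where(gaps <= max_gap, seg_km, 0.0)
    release = pd.Timestamp(release_date).normalize() if release_date is not None else ts.iloc[0].normalize()
    seg_day = ((ts.iloc[:-1].dt.normalize() - release).dt.days).to_numpy()
    days = np.arange(seg_day.min(), seg_day.max() + 1)
    km = np.zeros(len(days))
    np.add.at(km, seg_day - seg_day.min(), seg_km)
    return pd.DataFrame({"day": days, "km": km})


def _cohens_d(left: np.ndarray, right: np.ndarray) -> float:
    """Standardized mean difference with pooled (n-1 weighted) SD."""
    n1, n2 = len(left), len(right)
    v1 = left.var(ddof=1) if n1 > 1 else 0.0
    v2 = right.var(ddof=1) if n2 > 1 else 0.0
    denom_df = n1 + n2 - 2
    pooled = np.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / denom_df) if denom_df > 0 else 0.0
    diff = abs(left.mean() - right.mean())
    if pooled == 0:
        return np.inf if diff > 0 else 0.0
    return diff / pooled


def detect_changepoints(
    series: np.ndarray | pd.Series,
    max_cps: int = 5,
    min_effect: float = 0.5,
    min_size: int = 1,
) -> list[tuple[int, float]]:
    """Mean-shift change-points in a daily-displacement series.

    Binary segmentation: each segment is split at the point minimising the
    two-segment sum of squared errors; the split is kept (and both halves
    recursed) only if the adjacent-segment Cohen's d >= ``min_effect``.
    Returns [(day_index, effect_size), ...] sorted by day, where day_index is
    1-based and names the last day of the pre-shift segment. Constant series
    yield no change-points. Deterministic.
    """
    x = np.asarray(series, dtype=float)
    if len(x) < 4:
        raise ValueError("change-point detection needs a series of length >= 4")
    found: list[tuple[int, float]] = []

    def best_split(lo: int, hi: int) -> tuple[int, float] | None:
        n = hi - lo
        if n < 2 * min_size:
            return None
        seg = x[lo:hi]
        csum = np.concatenate([[0.0], np.cumsum(seg)])
        csum2 = np.concatenate([[0.0], np.cumsum(seg**2)])
        ks = np.arange(min_size, n - min_size + 1)
        sse_l = csum2[ks] - csum[ks] ** 2 / ks
        nr = n - ks
        sse_r = (csum2[n] - csum2[ks]) - (csum[n] - csum[ks]) ** 2 / nr
        k = int(ks[np.argmin(sse_l + sse_r)])
        d = _cohens_d(seg[:k], seg[k:])
        if d >= min_effect:
            return lo + k, d
        return None

    segments = [(0, len(x))]
    while segments and len(found) < max_cps:
        lo, hi = segments.pop(0)
        hit = best_split(lo, hi)
        if hit is None:
            continue
        split, d = hit
        found.append((split, d))  # split = index of first day of right segment
        segments.append((lo, split))
        segments.append((split, hi))
    # day index of last pre-shift day, 1-based over series positions
    return sorted((split, d) for split, d in found)


@dataclass(frozen=True)
class CensorResult:
    bird_id: str
    changepoints: tuple[int, ...]
    effect_sizes: tuple[float, ...]
    censored_through: int
    included: bool
    n_days: int = 0


def censor_bird(
    bird_id: str,
    fixes: pd.DataFrame,
    min_survival_days: int = 14,
    bbox: tuple[float, float, float, float] | None = DEFAULT_BBOX,
    max_cps: int = 5,
    min_effect: float = 0.5,
    track_days: int = 20,
) -> CensorResult:
    """Censor decision for one bird from its GPS record.

    Change-points are sought in the first ``track_days`` days of daily
    displacement; the bird is excluded if it survived <= ``min_survival_days``
    (record span) or ever left ``bbox``.
    """
    disp = daily_displacement(fixes)
    n_days = int(disp["day"].max()) if len(disp) else 0
    included = n_days > min_survival_days
    if included and bbox is not None:
        lat_min, lat_max, lon_min, lon_max = bbox
        inside = fixes["lat"].between(lat_min, lat_max) & fixes["lon"].between(lon_min, lon_max)
        included = bool(inside.all())
    window = disp[(disp["day"] >= 1) & (disp["day"] <= track_days)]
    cps: list[tuple[int, float]] = []
    if len(window) >= 4:
        first_day = int(window["day"].iloc[0])
        raw = detect_changepoints(window["km"].to_numpy(), max_cps=max_cps, min_effect=min_effect)
        # split index -> last day of the left segment
        cps = [(first_day + split - 1, d) for split, d in raw]
    censored_through = max((day for day, _ in cps), default=0)
    return CensorResult(
        bird_id=bird_id,
        changepoints=tuple(day for day, _ in cps),
        effect_sizes=tuple(d for _, d in cps),
        censored_through=censored_through,
        included=included,
        n_days=n_days,
    )


def censor_all(gps: pd.DataFrame, **kwargs) -> dict[str, CensorResult]:
    return {
        str(bird): censor_bird(str(bird), g, **kwargs)
        for bird, g in gps.groupby("bird_id")
    }


def apply_censor(
    results: dict[str, CensorResult],
    acc: pd.DataFrame,
    release_dates: dict[str, pd.Timestamp] | None = None,
) -> pd.DataFrame:
    """Drop censored bursts and excluded birds from an ACC table.

    Removes bursts on days 1..censored_through (day index from the bird's
    release date, default the date of its first burst) and all bursts of
    birds with ``included`` False. Birds present in ``acc`` but absent from
    ``results`` are an error.
    """
    missing = set(acc["bird_id"].astype(str)) - set(results)
    if missing:
        raise ValueError(f"no censor result for bird(s): {sorted(missing)}")
    keep = np.ones(len(acc), dtype=bool)
    day0 = acc["timestamp_utc"].dt.normalize()
    for bird, g in acc.groupby("bird_id", sort=False):
        res = results[str(bird)]
        idx = g.index
        if not res.included:
            keep[acc.index.get_indexer(idx)] = False
            continue
        release = (
            pd.Timestamp(release_dates[str(bird)]).normalize()
            if release_dates and str(bird) in release_dates
            else day0.loc[idx].min()
        )
        day_index = (day0.loc[idx] - release).dt.days
        # a positive censor window removes the partial release day (day 0) too
        if res.censored_through >= 1:
            drop = day_index <= res.censored_through
        else:
            drop = day_index < 0  # nothing
        keep[acc.index.get_indexer(idx[drop])] = False
    return acc[keep]
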