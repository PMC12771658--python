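"""Per-burst feature extraction from tri-axial accelerometer bursts.

A burst is a short fixed-duration recording (here 5 s at 10 Hz = 50 samples
per axis, in g). Bursts are trimmed to their middle 3 s to isolate pure
behaviors, then summarised into a battery of per-burst features: per-axis
descriptive statistics, a static/dynamic decomposition (centered running
mean vs residual), posture Euler angles (pitch/roll/yaw), movement-intensity
proxies (ODBA, VeDBA), inverse coefficients of variation, and pairwise axis
correlations. The battery is a documented reconstruction: only three of the
original features are named in the source material (x_icv, yaw, static_y),
so the remainder follow standard accelerometry practice.

Conventions
-----------
* "icv" is the inverse coefficient of variation, mean/SD of an axis within
  a burst (SD with the n-1 denominator). Zero-variance axes give NaN, never
  +-inf.
* The static component is a centered running mean with a 10-sample (1 s)
  window and shrinking windows at the edges; 1 s separates posture from
  wingbeat/paddling frequencies at 10 Hz. dynamic = sample - static, so
  static + dynamic reconstructs the input exactly.
* Euler angles (degrees) from the mean static vector (s_x, s_y, s_z):
  pitch = atan2(s_x, sqrt(s_y^2 + s_z^2)), roll = atan2(s_y,
  sqrt(s_x^2 + s_z^2)), yaw = atan2(s_y, s_x).
* static_y = |mean of the running-mean series of y| (likewise x, z).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

AXES = ("x", "y", "z")
DEFAULT_SAMPLE_RATE = 10.0
DEFAULT_RUNNING_MEAN_WINDOW = 10  # samples = 1 s at 10 Hz


@dataclass
class AccBurst:
    """One tri-axial accelerometer burst for one bird at one timestamp."""

    bird_id: str
    timestamp: pd.Timestamp
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    sample_rate: float = DEFAULT_SAMPLE_RATE
    burst_id: str = ""

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if not (len(self.x) == len(self.y) == len(self.z)):
            raise ValueError(f"burst {self.burst_id or self.bird_id}: axis lengths differ")

    def __len__(self) -> int:
        return len(self.x)

    @property
    def samples(self) -> np.ndarray:
        """(n, 3) array of x/y/z samples."""
        return np.column_stack([self.x, self.y, self.z])


def middle_window(burst: AccBurst, window_s: float = 3.0) -> AccBurst:
    """Trim a burst to its centered ``window_s``-second window.

    A 50-sample burst at 10 Hz keeps 0-based indices 10..39. A burst already
    at the window length is returned unchanged; a shorter burst is an error.
    """
    n_keep = int(round(window_s * burst.sample_rate))
    n = len(burst)
    if n < n_keep:
        raise ValueError(
            f"burst {burst.burst_id or burst.bird_id} has {n} samples, "
            f"needs >= {n_keep} for a {window_s}-s window"
        )
    start = (n - n_keep) // 2
    sl = slice(start, start + n_keep)
    return AccBurst(
        bird_id=burst.bird_id,
        timestamp=burst.timestamp,
        x=burst.x[sl],
        y=burst.y[sl],
        z=burst.z[sl],
        sample_rate=burst.sample_rate,
        burst_id=burst.burst_id,
    )


def _running_mean(arr: np.ndarray, window: int) -> np.ndarray:
    """Centered running mean along the last axis, shrinking at the edges.

    For even windows the extra sample goes to the right:
    static[i] = mean(x[i - (w-1)//2 : i + w//2 + 1]) clipped to the series.
    """
    if window < 1:
        raise ValueError("running-mean window must be >= 1")
    n = arr.shape[-1]
    half_l = (window - 1) // 2
    half_r = window // 2
    idx = np.arange(n)
    lo = np.clip(idx - half_l, 0, n)
    hi = np.clip(idx + half_r + 1, 0, n)
    csum = np.concatenate(
        [np.zeros(arr.shape[:-1] + (1,)), np.cumsum(arr, axis=-1)], axis=-1
    )
    return (csum[..., hi] - csum[..., lo]) / (hi - lo)


def static_dynamic(
    samples: np.ndarray, running_mean_window: int = DEFAULT_RUNNING_MEAN_WINDOW
) -> tuple[np.ndarray, np.ndarray]:
    """Split axis samples into static (running mean) and dynamic (residual).

    static + dynamic reconstructs the input exactly.
    """
    samples = np.asarray(samples, dtype=float)
    if running_mean_window > samples.shape[-1]:
        raise ValueError("running-mean window exceeds series length")
    static = _running_mean(samples, running_mean_window)
    return static, samples - static


def _sd(a: np.ndarray, axis: int = -1) -> np.ndarray:
    return np.std(a, axis=axis, ddof=1)


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    """Elementwise num/den with 0-denominators giving NaN (never +-inf)."""
    den = np.asarray(den, dtype=float)
    out = np.full(np.broadcast(num, den).shape, np.nan)
    ok = den != 0
    np.divide(num, den, out=out, where=ok)
    return out


def _pairwise_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation along the last axis; constant series give NaN."""
    ac = a - a.mean(axis=-1, keepdims=True)
    bc = b - b.mean(axis=-1, keepdims=True)
    num = (ac * bc).sum(axis=-1)
    den = np.sqrt((ac**2).sum(axis=-1) * (bc**2).sum(axis=-1))
    return _safe_div(num, den)


def compute_features_array(
    samples: np.ndarray,
    running_mean_window: int = DEFAULT_RUNNING_MEAN_WINDOW,
) -> pd.DataFrame:
    """Feature battery for a stack of windowed bursts.

    ``samples`` has shape (n_bursts, n_samples, 3) with axes ordered x, y, z.
    Returns one row per burst; column order is the canonical feature order
    used by the correlation filter.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 3 or samples.shape[2] != 3:
        raise ValueError("expected samples of shape (n_bursts, n_samples, 3)")
    feats: dict[str, np.ndarray] = {}

    raw = {ax: samples[:, :, i] for i, ax in enumerate(AXES)}
    static_all, dyn_all = static_dynamic(
        np.moveaxis(samples, 2, 1), running_mean_window
    )  # (n, 3, t)
    static = {ax: static_all[:, i, :] for i, ax in enumerate(AXES)}
    dyn = {ax: dyn_all[:, i, :] for i, ax in enumerate(AXES)}

    for ax in AXES:
        a = raw[ax]
        q25, q50, q75 = np.percentile(a, [25, 50, 75], axis=1)
        sd = _sd(a)
        feats[f"{ax}_mean"] = a.mean(axis=1)
        feats[f"{ax}_sd"] = sd
        feats[f"{ax}_min"] = a.min(axis=1)
        feats[f"{ax}_max"] = a.max(axis=1)
        feats[f"{ax}_range"] = a.max(axis=1) - a.min(axis=1)
        feats[f"{ax}_median"] = q50
        feats[f"{ax}_q25"] = q25
        feats[f"{ax}_q75"] = q75
        feats[f"{ax}_iqr"] = q75 - q25
        feats[f"{ax}_skew"] = sps.skew(a, axis=1, bias=False)
        feats[f"{ax}_kurtosis"] = sps.kurtosis(a, axis=1, bias=False)
        feats[f"{ax}_rms"] = np.sqrt((a**2).mean(axis=1))
        feats[f"{ax}_icv"] = _safe_div(a.mean(axis=1), sd)
        feats[f"{ax}_mad"] = np.median(np.abs(a - q50[:, None]), axis=1)
        feats[f"{ax}_sum_abs_diff"] = np.abs(np.diff(a, axis=1)).sum(axis=1)
        # lag-1 autocorrelation
        feats[f"{ax}_autocorr1"] = _pairwise_corr(a[:, :-1], a[:, 1:])
        # linear trend (slope per sample)
        t = np.arange(a.shape[1]) - (a.shape[1] - 1) / 2.0
        feats[f"{ax}_trend"] = (a * t).sum(axis=1) / (t**2).sum()

    for ax in AXES:
        s, d = static[ax], dyn[ax]
        feats[f"static_{ax}"] = np.abs(s.mean(axis=1))
        feats[f"static_{ax}_sd"] = _sd(s)
        feats[f"dyn_{ax}_mean_abs"] = np.abs(d).mean(axis=1)
        feats[f"dyn_{ax}_sd"] = _sd(d)
        feats[f"dyn_{ax}_max_abs"] = np.abs(d).max(axis=1)
        feats[f"dyn_{ax}_rms"] = np.sqrt((d**2).mean(axis=1))
        # sign changes of the dynamic component, movement-cycle proxy
        sign = np.sign(d)
        feats[f"dyn_{ax}_zero_crossings"] = (
            (sign[:, :-1] * sign[:, 1:] < 0).sum(axis=1).astype(float)
        )

    for a1, a2 in (("x", "y"), ("x", "z"), ("y", "z")):
        feats[f"corr_{a1}{a2}"] = _pairwise_corr(raw[a1], raw[a2])
        feats[f"dyn_corr_{a1}{a2}"] = _pairwise_corr(dyn[a1], dyn[a2])
        n = samples.shape[1]
        feats[f"cov_{a1}{a2}"] = (
            (raw[a1] - raw[a1].mean(axis=1, keepdims=True))
            * (raw[a2] - raw[a2].mean(axis=1, keepdims=True))
        ).sum(axis=1) / (n - 1)

    dx, dy, dz = dyn["x"], dyn["y"], dyn["z"]
    odba_t = np.abs(dx) + np.abs(dy) + np.abs(dz)
    vedba_t = np.sqrt(dx**2 + dy**2 + dz**2)
    feats["odba"] = odba_t.mean(axis=1)
    feats["odba_sd"] = _sd(odba_t)
    feats["vedba"] = vedba_t.mean(axis=1)
    feats["vedba_sd"] = _sd(vedba_t)

    sx = static["x"].mean(axis=1)
    sy = static["y"].mean(axis=1)
    sz = static["z"].mean(axis=1)
    feats["pitch"] = np.degrees(np.arctan2(sx, np.sqrt(sy**2 + sz**2)))
    feats["roll"] = np.degrees(np.arctan2(sy, np.sqrt(sx**2 + sz**2)))
    feats["yaw"] = np.degrees(np.arctan2(sy, sx))

    norm = np.linalg.norm(samples, axis=2)
    feats["norm_mean"] = norm.mean(axis=1)
    feats["norm_sd"] = _sd(norm)
    feats["norm_min"] = norm.min(axis=1)
    feats["norm_max"] = norm.max(axis=1)

    return pd.DataFrame(feats)


FEATURE_NAMES: tuple[str, ...] = tuple(
    compute_features_array(np.zeros((1, 30, 3))).columns
)


def compute_features(burst: AccBurst) -> pd.Series:
    """Feature battery for a single (already windowed) burst."""
    row = compute_features_array(burst.samples[None, :, :]).iloc[0]
    row.name = burst.burst_id
    return row


def compute_features_table(
    acc: pd.DataFrame,
    window_s: float = 3.0,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
) -> pd.DataFrame:
    """Window every burst in a long-format ACC table and extract features.

    ``acc`` has columns burst_id, sample_idx, x_g, y_g, z_g (the on-disk
    dialect). Bursts must share a common length. Returns burst_id + features.
    """
    acc = acc.sort_values(["burst_id", "sample_idx"])
    ids = acc["burst_id"].unique()
    n_bursts = len(ids)
    arr = acc[["x_g", "y_g", "z_g"]].to_numpy(dtype=float)
    if arr.shape[0] % n_bursts:
        raise ValueError("bursts have unequal lengths")
    n_samples = arr.shape[0] // n_bursts
    stack = arr.reshape(n_bursts, n_samples, 3)
    n_keep = int(round(window_s * sample_rate))
    if n_samples < n_keep:
        raise ValueError(f"bursts have {n_samples} samples, need >= {n_keep}")
    start = (n_samples - n_keep) // 2
    stack = stack[:, start : start + n_keep, :]
    out = compute_features_array(stack)
    out.insert(0, "burst_id", ids)
    return out


def correlation_filter(
    features: pd.DataFrame, threshold: float = 0.9
) -> tuple[list[str], list[str]]:
    """Greedy de-correlation of the feature battery.

    Scans columns in canonical (given) order and drops any feature whose
    absolute Pearson correlation with an already-retained feature exceeds
    ``threshold``. Constant (or all-missing) columns are excluded before
    filtering. Returns (retained, excluded_constant). Deterministic and
    idempotent: first seen is kept.
    """
    meta = {"burst_id", "behavior", "sub_behavior", "purity_seconds", "bird_id"}
    cols = [
        c for c in features.columns
        if c not in meta and pd.api.types.is_numeric_dtype(features[c])
    ]
    if len(features) < 2:
        raise ValueError("correlation filter needs >= 2 rows")
    X = features[cols]
    sd = X.std(ddof=1)
    constant = [c for c in cols if not np.isfinite(sd[c]) or sd[c] == 0]
    cols = [c for c in cols if c not in constant]
    # pairwise-complete correlations; missing values are ignored per pair
    corr = X[cols].corr().abs()
    retained: list[str] = []
    for c in cols:
        if all(not (corr.loc[c, r] > threshold) for r in retained):
            retained.append(c)
    return retained, constant
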