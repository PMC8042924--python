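"""Two-channel enrichment and recruitment-correlation analysis.

Enrichment of a protein in a ruffle is quantified as the offset-corrected
mean intensity inside a ruffle region of interest divided by that of an
equal-pixel-count cytosol control region.  Temporal co-recruitment of two
channels is quantified by the mean, across ruffles, of the per-ruffle Pearson
correlation between the two intensity traces at integer frame lags; the lag
of the curve's maximum (ties broken toward zero) locates the recruitment
delay on the acquisition's time grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    InsufficientDataError,
    InvalidParameterError,
    InvalidROIError,
    UndefinedRatioError,
)

__all__ = [
    "EnrichmentRecord",
    "CorrelationCurve",
    "enrichment_ratio",
    "choose_cytosol_roi",
    "cross_correlate",
    "peak_lag",
]


@dataclass(frozen=True)
class EnrichmentRecord:
    """Offset-corrected ruffle/cytosol intensity ratio for one ruffle."""

    ruffle_id: int
    ratio: float
    ruffle_mean: float
    cytosol_mean: float
    n_pixels: int


@dataclass(frozen=True)
class CorrelationCurve:
    """Mean lagged correlation between two channels across ruffles."""

    lags: np.ndarray  # seconds, symmetric about 0
    values: np.ndarray  # mean Pearson r in [-1, 1]
    peak_lag: float  # seconds
    n_ruffles: int

    def __post_init__(self) -> None:
        lags = np.asarray(self.lags, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "values", values)
        if lags.shape != values.shape or lags.size == 0:
            raise InvalidParameterError("lags and values must be equal-length, non-empty")
        if np.any(np.abs(values) > 1 + 1e-9):
            raise InvalidParameterError("correlation values must lie in [-1, 1]")
        if not np.any(np.isclose(lags, self.peak_lag)):
            raise InvalidParameterError("peak_lag must be one of the lags")


def enrichment_ratio(
    image: np.ndarray,
    ruffle_roi: np.ndarray,
    cytosol_roi: np.ndarray,
    camera_offset: float = 0.0,
    ruffle_id: int = 0,
) -> EnrichmentRecord:
    """Offset-corrected mean-intensity ratio of ruffle over cytosol ROI.

    ``ratio = (mean(image[ruffle_roi]) - offset) / (mean(image[cytosol_roi]) - offset)``.
    The two boolean ROIs must be disjoint and contain the same number of
    pixels; the cytosol mean must exceed the camera offset.
    """
    image = np.asarray(image, dtype=float)
    ruffle_roi = np.asarray(ruffle_roi, dtype=bool)
    cytosol_roi = np.asarray(cytosol_roi, dtype=bool)
    n_ruffle = int(ruffle_roi.sum())
    n_cytosol = int(cytosol_roi.sum())
    if n_ruffle == 0 or n_ruffle != n_cytosol:
        raise InvalidROIError(
            f"ROIs must be non-empty and equal-sized (ruffle {n_ruffle}, "
            f"cytosol {n_cytosol} pixels)"
        )
    if np.any(ruffle_roi & cytosol_roi):
        raise InvalidROIError("ruffle and cytosol ROIs must be disjoint")
    ruffle_mean = float(image[ruffle_roi].mean())
    cytosol_mean = float(image[cytosol_roi].mean())
    if cytosol_mean <= camera_offset:
        raise UndefinedRatioError(
            f"cytosol mean ({cytosol_mean}) does not exceed the camera offset "
            f"({camera_offset})"
        )
    ratio = (ruffle_mean - camera_offset) / (cytosol_mean - camera_offset)
    return EnrichmentRecord(
        ruffle_id=ruffle_id,
        ratio=ratio,
        ruffle_mean=ruffle_mean,
        cytosol_mean=cytosol_mean,
        n_pixels=n_ruffle,
    )


def choose_cytosol_roi(
    ruffle_roi: np.ndarray,
    exclusion_mask: np.ndarray,
    seed: int = 0,
) -> np.ndarray:
    """Random cytosol control ROI with the same pixel count as ``ruffle_roi``.

    Pixels are drawn uniformly outside ``exclusion_mask`` (typically the
    dilated union of all ruffles).  Raises when too few free pixels exist.
    """
    ruffle_roi = np.asarray(ruffle_roi, dtype=bool)
    free = ~np.asarray(exclusion_mask, dtype=bool) & ~ruffle_roi
    n = int(ruffle_roi.sum())
    free_idx = np.flatnonzero(free.ravel())
    if free_idx.size < n:
        raise InvalidROIError("not enough cytosol pixels for an equal-sized control ROI")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(free_idx, size=n, replace=False)
    roi = np.zeros(ruffle_roi.size, dtype=bool)
    roi[chosen] = True
    return roi.reshape(ruffle_roi.shape)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        return np.nan
    return float(np.clip((a @ b) / denom, -1.0, 1.0))


def cross_correlate(traces: pd.DataFrame, max_lag_frames: int = 10) -> CorrelationCurve:
    """Mean lagged Pearson correlation between channels across ruffles.

    ``traces`` is a tidy table (ruffle_id, t_s, I1, I2) with a uniform time
    grid per ruffle.  For each ruffle and integer lag ``k`` in
    ``[-max_lag, +max_lag]``, the Pearson correlation of the overlapping
    segments of I1 and the k-frame-delayed I2 is computed on mean-subtracted
    values; the curve is the mean across ruffles and ``peak_lag`` the lag (in
    seconds) of its maximum, ties broken toward zero.  Constant (zero
    variance) traces are excluded with a warning.
    """
    if max_lag_frames < 0:
        raise InvalidParameterError("max_lag_frames must be >= 0")
    groups = list(traces.groupby("ruffle_id", sort=True))
    if len(groups) < 3:
        raise InsufficientDataError("need >= 3 ruffles for a correlation curve")
    intervals = []
    lags = np.arange(-max_lag_frames, max_lag_frames + 1)
    per_ruffle = []
    n_excluded = 0
    for _, grp in groups:
        grp = grp.sort_values("t_s")
        t = grp["t_s"].to_numpy(dtype=float)
        if len(t) < 8:
            raise InsufficientDataError("each ruffle needs >= 8 frames")
        dt = np.diff(t)
        if not np.allclose(dt, dt[0]):
            raise InvalidParameterError("time grid must be uniform per ruffle")
        intervals.append(dt[0])
        i1 = grp["I1"].to_numpy(dtype=float)
        i2 = grp["I2"].to_numpy(dtype=float)
        if np.ptp(i1) == 0 or np.ptp(i2) == 0:
            n_excluded += 1
            continue
        row = np.empty(lags.size)
        for j, k in enumerate(lags):
            if k >= 0:
                a, b = i1[: len(i1) - k], i2[k:]
            else:
                a, b = i1[-k:], i2[: len(i2) + k]
            row[j] = _pearson(a, b) if len(a) >= 3 else np.nan
        per_ruffle.append(row)
    if n_excluded:
        warnings.warn(
            f"excluded {n_excluded} constant-trace ruffles from the correlation",
            stacklevel=2,
        )
    if not per_ruffle:
        raise InsufficientDataError("all ruffles had constant traces")
    if not np.allclose(intervals, intervals[0]):
        raise InvalidParameterError("frame interval differs between ruffles")
    frame_interval = float(intervals[0])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        values = np.nanmean(np.vstack(per_ruffle), axis=0)
    lags_s = lags * frame_interval
    peak = _peak_lag(lags_s, values)
    return CorrelationCurve(
        lags=lags_s, values=values, peak_lag=peak, n_ruffles=len(per_ruffle)
    )


def _peak_lag(lags_s: np.ndarray, values: np.ndarray) -> float:
    finite = np.isfinite(values)
    if not np.any(finite):
        raise InsufficientDataError("correlation curve is empty")
    vmax = np.max(values[finite])
    candidates = np.flatnonzero(finite & np.isclose(values, vmax))
    best = min(candidates, key=lambda i: (abs(lags_s[i]), lags_s[i]))
    return float(lags_s[best])


def peak_lag(curve: CorrelationCurve) -> float:
    """Lag (s) maximizing the mean correlation; ties broken toward |lag| = 0."""
    return _peak_lag(curve.lags, curve.values)
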