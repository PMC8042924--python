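"""Persistence-length estimation from (L, R_ee) data.

Fits the 2D worm-like-chain mean squared end-to-end distance

    <R_ee^2>(L) = 8 l_p^2 [ L/(2 l_p) - 1 + exp(-L/(2 l_p)) ]

to pooled per-ruffle points by unweighted least squares on R_ee^2, with a
multi-start optimizer (the objective is flat in l_p for stiff data, so a
single start can stall far from the optimum).  Uncertainty comes from a
percentile bootstrap resampled over ruffles.  The observed persistence length
decomposes into bending and intrinsic-curvature contributions through
reciprocal additivity, ``1/l_p_obs = 1/l_p + 1/l_p_int``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import (
    DomainError,
    FitFailureError,
    InsufficientDataError,
    InvalidParameterError,
)
from .wlc_sim import theoretical_ree_sq

__all__ = [
    "WLCFitResult",
    "fit_persistence_length",
    "decompose_intrinsic",
    "bootstrap_ci",
    "DEFAULT_STARTS",
]

#: log-spaced grid of initial persistence lengths (um) for the multi-start fit
DEFAULT_STARTS: tuple[float, ...] = (0.1, 0.5, 1.0, 2.0, 5.0, 10.0, 50.0)


@dataclass(frozen=True)
class WLCFitResult:
    """Result of a worm-like-chain persistence-length fit.

    Attributes
    ----------
    l_p_obs : float
        Fitted (observed) persistence length, um.
    ci_low, ci_high : float
        Bootstrap percentile interval bounds (NaN when no bootstrap was run).
    n_ruffles : int
        Number of valid data points used.
    rss : float
        Residual sum of squares on R_ee^2, um^4.
    n_rejected : int
        Rows dropped because R_ee > L or L <= 0.
    converged : bool
        True when at least one optimizer start converged.
    """

    l_p_obs: float
    ci_low: float
    ci_high: float
    n_ruffles: int
    rss: float
    n_rejected: int = 0
    converged: bool = True

    def __post_init__(self) -> None:
        if not (self.l_p_obs > 0):
            raise InvalidParameterError("l_p_obs must be > 0")
        if self.n_ruffles < 3:
            raise InvalidParameterError("n_ruffles must be >= 3")
        if not (math.isnan(self.ci_low) or self.ci_low <= self.l_p_obs <= self.ci_high):
            raise InvalidParameterError("need ci_low <= l_p_obs <= ci_high")


def _extract_valid(records) -> tuple[np.ndarray, np.ndarray, int]:
    """Return (L, Ree) arrays of valid rows and the rejected-row count."""
    if isinstance(records, pd.DataFrame):
        L = records["L_um"].to_numpy(dtype=float)
        ree = records["Ree_um"].to_numpy(dtype=float)
    else:
        L, ree = (np.asarray(a, dtype=float) for a in records)
    valid = (L > 0) & (ree <= L * (1 + 1e-12)) & (ree >= 0)
    n_rejected = int((~valid).sum())
    if n_rejected:
        warnings.warn(
            f"rejected {n_rejected} rows with R_ee > L or non-positive L",
            stacklevel=3,
        )
    return L[valid], ree[valid], n_rejected


def fit_persistence_length(
    records,
    starts: tuple[float, ...] = DEFAULT_STARTS,
    n_boot: int = 0,
    level: float = 0.95,
    seed: int = 0,
) -> WLCFitResult:
    """Fit l_p by least squares of R_ee^2 against the 2D WLC curve.

    Parameters
    ----------
    records : DataFrame with columns (L_um, Ree_um) or tuple of arrays (L, Ree)
        Pooled per-ruffle measurements.  Rows with ``R_ee > L`` (possible with
        measurement noise) or ``L <= 0`` are rejected with a warning.
    starts : tuple of float
        Initial values for the multi-start optimizer; the best final RSS wins.
    n_boot, level, seed
        If ``n_boot > 0``, also compute a percentile bootstrap interval over
        ruffles (see :func:`bootstrap_ci`).
    """
    L, ree, n_rejected = _extract_valid(records)
    if L.size < 3:
        raise InsufficientDataError(
            f"need >= 3 valid (L, R_ee) records, have {L.size}"
        )
    l_p, rss, converged = _fit_arrays(L, ree**2, starts)
    ci_low = ci_high = math.nan
    if n_boot:
        ci_low, ci_high = bootstrap_ci(
            (L, ree), n_boot=n_boot, level=level, seed=seed
        )
        ci_low, ci_high = min(ci_low, l_p), max(ci_high, l_p)
    return WLCFitResult(
        l_p_obs=l_p,
        ci_low=ci_low,
        ci_high=ci_high,
        n_ruffles=int(L.size),
        rss=rss,
        n_rejected=n_rejected,
        converged=converged,
    )


def _fit_arrays(
    L: np.ndarray, ree_sq: np.ndarray, starts=DEFAULT_STARTS
) -> tuple[float, float, bool]:
    """Core multi-start solver on clean arrays; fit is in log(l_p) space."""

    def residuals(log_lp):
        return ree_sq - theoretical_ree_sq(L, math.exp(log_lp[0]))

    best = None
    diagnostics = {}
    for start in starts:
        try:
            sol = least_squares(residuals, x0=[math.log(start)], method="lm")
        except Exception as exc:  # pragma: no cover - scipy internal failure
            diagnostics[start] = repr(exc)
            continue
        rss = float(np.sum(sol.fun**2))
        diagnostics[start] = {"success": bool(sol.success), "rss": rss}
        if sol.success and (best is None or rss < best[1]):
            best = (math.exp(float(sol.x[0])), rss)
    if best is None:
        raise FitFailureError(
            "worm-like-chain fit failed from every start", diagnostics
        )
    return best[0], best[1], True


def decompose_intrinsic(l_p_obs: float, l_p_bend: float) -> float:
    """Intrinsic-curvature persistence length from reciprocal additivity.

    Solves ``1/l_p_obs = 1/l_p_bend + 1/l_p_int`` for ``l_p_int``:
    ``l_p_int = 1 / (1/l_p_obs - 1/l_p_bend)``.  Requires
    ``0 < l_p_obs < l_p_bend``; as ``l_p_obs -> l_p_bend`` from below the
    result diverges (no intrinsic curvature), returned as ``math.inf`` when
    the reciprocal difference underflows.
    """
    if not (l_p_obs > 0 and l_p_bend > 0):
        raise InvalidParameterError("persistence lengths must be > 0")
    if not (math.isfinite(l_p_obs) and math.isfinite(l_p_bend)):
        raise InvalidParameterError("persistence lengths must be finite")
    if l_p_obs >= l_p_bend:
        raise DomainError(
            "l_p_obs must be strictly smaller than the bending persistence "
            f"length (got l_p_obs={l_p_obs}, l_p_bend={l_p_bend}); equal values "
            "mean no intrinsic curvature (l_p_int -> inf)"
        )
    inv = 1.0 / l_p_obs - 1.0 / l_p_bend
    if inv <= 0.0:
        return math.inf
    return 1.0 / inv


def bootstrap_ci(
    records,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
    starts: tuple[float, ...] | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap interval for l_p, resampled over ruffles.

    Each resample draws ruffles (rows) with replacement; resamples with fewer
    than 3 distinct ruffles are redrawn (error if more than 50% of draws are
    redraws).  Refits start from the full-data point estimate, which is a
    reliable neighbourhood for resampled data.  Deterministic under ``seed``.
    """
    if n_boot < 100:
        raise InvalidParameterError("n_boot must be >= 100")
    if not (0.0 < level < 1.0):
        raise InvalidParameterError("level must be in (0, 1)")
    L, ree, _ = _extract_valid(records)
    if L.size < 3:
        raise InsufficientDataError("need >= 3 valid records for the bootstrap")
    ree_sq = ree**2
    point, _, _ = _fit_arrays(L, ree_sq, starts or DEFAULT_STARTS)
    rng = np.random.default_rng(seed)
    estimates = np.empty(n_boot)
    n = L.size
    redraws = 0
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            if np.unique(idx).size >= 3:
                break
            redraws += 1
            if redraws > n_boot / 2:
                raise InsufficientDataError(
                    "more than 50% of bootstrap resamples were degenerate"
                )
        estimates[b], _, _ = _fit_arrays(L[idx], ree_sq[idx], starts=(point,))
    alpha = 1.0 - level
    lo, hi = np.quantile(estimates, [alpha / 2, 1.0 - alpha / 2])
    return float(lo), float(hi)
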