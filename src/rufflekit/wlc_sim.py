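"""Discrete 2D worm-like-chain (Kratky–Porod) sampling and theory.

Membrane ruffles seen from the top behave like semiflexible filaments in the
membrane plane.  This module samples discrete chains of fixed segment length
``step`` whose per-step turning angles are Gaussian, which reproduces the 2D
worm-like-chain tangent correlation ``<t(0)·t(s)> = exp(-s / (2 l_p))`` and
hence the mean squared end-to-end distance

    <R_ee^2> = 8 l_p^2 [ L / (2 l_p) - 1 + exp(-L / (2 l_p)) ].

Apparent flexibility can also come from a preferred, disordered shape rather
than thermal bending.  That is modelled as quenched per-step preferred angles
(drawn once per chain) with their own persistence length ``l_p_int``; the
observed stiffness then satisfies ``1/l_p_obs = 1/l_p + 1/l_p_int``.

All lengths are in micrometres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, InvalidParameterError

__all__ = [
    "WLCParams",
    "ChainConformation",
    "sample_chain",
    "theoretical_ree_sq",
    "chain_measurements",
    "sample_ensemble",
    "sample_uniform_length_ensemble",
]


@dataclass(frozen=True)
class WLCParams:
    """Parameters of a discrete 2D worm-like chain.

    Parameters
    ----------
    l_p : float
        Bending persistence length (um), strictly positive.
    contour_length : float
        Total chain length L (um), strictly positive.
    step : float
        Segment length ``delta_s`` (um).  Must satisfy ``step <= l_p / 5`` so the
        Gaussian-turning-angle discretization is a faithful WLC, and
        ``step <= contour_length``.
    l_p_int : float
        Persistence length of the quenched intrinsic-curvature disorder (um).
        ``math.inf`` (default) means no intrinsic curvature.
    """

    l_p: float
    contour_length: float
    step: float = 0.05
    l_p_int: float = math.inf

    def __post_init__(self) -> None:
        for name in ("l_p", "contour_length", "step", "l_p_int"):
            value = getattr(self, name)
            if not (value > 0):
                raise InvalidParameterError(f"{name} must be > 0, got {value!r}")
        if self.step > self.contour_length:
            raise InvalidParameterError(
                f"step ({self.step}) must not exceed contour_length ({self.contour_length})"
            )
        if self.step > self.l_p / 5:
            raise InvalidParameterError(
                f"step ({self.step}) must be <= l_p/5 ({self.l_p / 5}) for a valid "
                "worm-like-chain discretization"
            )

    @property
    def n_segments(self) -> int:
        return int(round(self.contour_length / self.step))

    @property
    def l_p_obs(self) -> float:
        """Observed persistence length combining bending and intrinsic curvature."""
        if math.isinf(self.l_p_int):
            return self.l_p
        return 1.0 / (1.0 / self.l_p + 1.0 / self.l_p_int)


@dataclass(frozen=True)
class ChainConformation:
    """Ordered 2D backbone coordinates with fixed segment length.

    ``points`` is an (n, 2) array of (x, y) in um; consecutive points are
    exactly ``step`` apart (checked to 1e-9 relative tolerance).
    """

    points: np.ndarray
    step: float
    _validate: bool = field(default=True, repr=False, compare=False)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "points", pts)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
            raise InvalidParameterError(
                f"points must be an (n>=2, 2) array, got shape {pts.shape}"
            )
        if self._validate:
            seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
            if not np.allclose(seg, self.step, rtol=1e-9, atol=0.0):
                raise InvalidParameterError(
                    "consecutive point spacing deviates from the declared step"
                )

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def contour_length(self) -> float:
        return (self.n_points - 1) * self.step


def theoretical_ree_sq(L, l_p: float):
    """Mean squared end-to-end distance of a 2D worm-like chain.

    Evaluates ``8 l_p^2 [L/(2 l_p) - 1 + exp(-L/(2 l_p))]`` (um^2), the 2D
    Kratky–Porod form whose tangent correlation decays as ``exp(-s/(2 l_p))``.
    Vectorized over ``L``.
    """
    if not (l_p > 0):
        raise InvalidParameterError(f"l_p must be > 0, got {l_p!r}")
    L_arr = np.asarray(L, dtype=float)
    if np.any(L_arr < 0):
        raise InvalidParameterError("contour length L must be >= 0")
    x = L_arr / (2.0 * l_p)
    out = 8.0 * l_p**2 * (x - 1.0 + np.exp(-x))
    # guard against tiny negative round-off at x ~ 0
    out = np.maximum(out, 0.0)
    return float(out) if np.isscalar(L) or L_arr.ndim == 0 else out


def sample_chain(params: WLCParams, seed: int) -> ChainConformation:
    """Sample one chain conformation.

    The chain has ``n = round(L/step)`` segments.  Per-step turning angles are
    ``N(0, step/l_p)`` (thermal bending); if ``l_p_int`` is finite an additional
    preferred angle ``N(0, step/l_p_int)`` is drawn per step, once per chain
    (quenched disorder).  The initial heading is uniform on [0, 2*pi).
    Identical ``params`` and ``seed`` give a bit-identical chain.
    """
    rng = np.random.default_rng(seed)
    n = params.n_segments
    theta0 = rng.uniform(0.0, 2.0 * math.pi)
    turns = rng.normal(0.0, math.sqrt(params.step / params.l_p), size=n - 1)
    if math.isfinite(params.l_p_int):
        turns = turns + rng.normal(
            0.0, math.sqrt(params.step / params.l_p_int), size=n - 1
        )
    headings = theta0 + np.concatenate(([0.0], np.cumsum(turns)))
    displacements = params.step * np.column_stack(
        (np.cos(headings), np.sin(headings))
    )
    points = np.concatenate(
        (np.zeros((1, 2)), np.cumsum(displacements, axis=0)), axis=0
    )
    return ChainConformation(points=points, step=params.step, _validate=False)


def chain_measurements(chain: ChainConformation) -> tuple[float, float]:
    """Contour length and end-to-end distance ``(L, R_ee)`` of a chain (um).

    ``L = (n_points - 1) * step``; ``R_ee`` is the Euclidean distance between
    the first and last points.  ``R_ee <= L`` always (triangle inequality).
    """
    if chain.n_points < 2:
        raise InsufficientDataError("chain must have at least 2 points")
    L = chain.contour_length
    r_ee = float(np.linalg.norm(chain.points[-1] - chain.points[0]))
    return L, min(r_ee, L)  # numerical guard; r_ee <= L analytically


def sample_ensemble(
    params_list: list[WLCParams],
    n_per_length: int,
    seed: int,
    return_chains: bool = False,
):
    """Sample ``n_per_length`` chains for each parameter set.

    Per-chain seeds are ``seed + chain_index`` (chain_index running over the
    whole table) so the table is reproducible chain by chain.  Returns a
    DataFrame with columns ``(chain_id, L_um, Ree_um)``; with
    ``return_chains=True`` also the list of :class:`ChainConformation`.
    """
    if len(params_list) == 0:
        raise InvalidParameterError("params_list must be non-empty")
    if n_per_length < 1:
        raise InvalidParameterError("n_per_length must be >= 1")
    rows = []
    chains: list[ChainConformation] = []
    chain_id = 0
    for params in params_list:
        for _ in range(n_per_length):
            chain = sample_chain(params, seed=seed + chain_id)
            L, r_ee = chain_measurements(chain)
            rows.append((chain_id, L, r_ee))
            if return_chains:
                chains.append(chain)
            chain_id += 1
    table = pd.DataFrame(rows, columns=["chain_id", "L_um", "Ree_um"])
    return (table, chains) if return_chains else table


def sample_uniform_length_ensemble(
    n_chains: int,
    l_min: float,
    l_max: float,
    l_p: float,
    seed: int,
    step: float = 0.05,
    l_p_int: float = math.inf,
) -> pd.DataFrame:
    """Ensemble with contour lengths uniform on ``[l_min, l_max]``.

    Lengths are drawn from ``default_rng(seed)``; chain seeds are
    ``seed + 1 + index``.  Note that master seeds closer together than
    ``n_chains`` therefore share chain streams — use well-separated seeds for
    independent replicate ensembles.  Returns ``(chain_id, L_um, Ree_um)``.
    """
    if n_chains < 1:
        raise InvalidParameterError("n_chains must be >= 1")
    if not (0 < l_min <= l_max):
        raise InvalidParameterError("need 0 < l_min <= l_max")
    rng = np.random.default_rng(seed)
    lengths = rng.uniform(l_min, l_max, size=n_chains)
    rows = []
    for i, L in enumerate(lengths):
        params = WLCParams(
            l_p=l_p, contour_length=float(L), step=step, l_p_int=l_p_int
        )
        chain = sample_chain(params, seed=seed + 1 + i)
        L_meas, r_ee = chain_measurements(chain)
        rows.append((i, L_meas, r_ee))
    return pd.DataFrame(rows, columns=["chain_id", "L_um", "Ree_um"])
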