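"""Synthetic light-sheet-like volumes of dorsal membrane ruffles.

Ruffles are modelled as thin vertical sheets: a 2D worm-like-chain backbone in
the membrane plane, extruded upward from a flat dorsal surface at ``base_z``
to a per-ruffle height, with constant lateral thickness.  A uniform cytosol
slab fills the volume below the dorsal surface.  Rendered unit-density
occupancy is degraded with an anisotropic Gaussian blur (the residual PSF of
deconvolved light-sheet data) and Poisson photon noise plus a constant camera
offset.  A second channel multiplies the ruffle density by an enrichment
factor while the cytosol stays at unit density, emulating a protein that
partitions into ruffles.

Every synthetic scene is returned together with its ground truth so the
measurement stages can be tested for parameter recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from .errors import (
    InvalidParameterError,
    OutOfBoundsError,
    SceneTooCrowdedError,
)
from .wlc_sim import ChainConformation, WLCParams, sample_chain

__all__ = [
    "SceneParams",
    "RuffleTruth",
    "GroundTruth",
    "VolumeTimeSeries",
    "render_sheet",
    "apply_psf_noise",
    "synthesize_ruffle_scene",
    "synthesize_recruitment_traces",
]


@dataclass(frozen=True)
class SceneParams:
    """Geometry, optics and acquisition parameters of a synthetic scene.

    Defaults follow the measured ruffle phenotype: ~0.83 um thick sheets,
    1-4 um tall, near-isotropic 0.1 um voxels, residual blur of
    0.1 um lateral / 0.25 um axial, and 8 s frames.
    """

    voxel_size: tuple[float, float, float] = (0.1, 0.1, 0.1)  # (x, y, z) um
    volume_shape: tuple[int, int, int] = (160, 160, 50)  # (nx, ny, nz) voxels
    n_ruffles: int = 5
    backbone_params: WLCParams = field(
        default_factory=lambda: WLCParams(l_p=5.0, contour_length=5.0, step=0.05)
    )
    height_mean: float = 2.0  # um
    height_sd: float = 0.5  # um
    thickness: float = 0.83  # um
    base_z: float = 1.0  # um, dorsal surface position
    cytosol_density: float = 1.0
    channel2_enrichment: float = 3.0
    psf_sigma: tuple[float, float] = (0.1, 0.25)  # (lateral, axial) um
    photon_scale: float = 500.0  # expected counts at unit density
    camera_offset: float = 100.0  # counts
    frame_interval: float = 8.0  # s
    n_frames: int = 1
    n_channels: int = 2

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.voxel_size):
            raise InvalidParameterError("voxel sizes must be > 0")
        if any(n < 1 for n in self.volume_shape):
            raise InvalidParameterError("volume_shape entries must be >= 1")
        if self.n_ruffles < 0:
            raise InvalidParameterError("n_ruffles must be >= 0")
        if self.thickness < min(self.voxel_size[:2]):
            raise InvalidParameterError("thickness must be >= one lateral voxel")
        if self.photon_scale <= 0:
            raise InvalidParameterError("photon_scale must be > 0")
        if self.n_frames < 1:
            raise InvalidParameterError("n_frames must be >= 1")
        if self.n_channels not in (1, 2):
            raise InvalidParameterError("n_channels must be 1 or 2")
        if any(s < 0 for s in self.psf_sigma):
            raise InvalidParameterError("psf_sigma must be >= 0")

    @property
    def extent(self) -> tuple[float, float, float]:
        """Physical (x, y, z) size of the volume in um."""
        return tuple(n * v for n, v in zip(self.volume_shape, self.voxel_size))


@dataclass(frozen=True)
class RuffleTruth:
    """Ground truth for one rendered ruffle."""

    backbone: ChainConformation
    arclength: np.ndarray  # um, dense stations along the backbone
    height_profile: np.ndarray  # um, height above base_z at each station
    thickness: float  # um
    channel2_enrichment: float

    @property
    def contour_length(self) -> float:
        return self.backbone.contour_length

    @property
    def mean_height(self) -> float:
        return float(np.mean(self.height_profile))


@dataclass(frozen=True)
class GroundTruth:
    """Scene-level truth stored alongside every synthetic volume."""

    ruffles: list[RuffleTruth]
    base_z: float
    params: SceneParams


@dataclass(frozen=True)
class VolumeTimeSeries:
    """Synthetic acquisition: counts indexed as (time, channel, z, y, x)."""

    intensities: np.ndarray
    voxel_size: tuple[float, float, float]  # (x, y, z) um
    frame_interval: float  # s

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities)
        if arr.ndim != 5:
            raise InvalidParameterError("intensities must be 5-D (t, c, z, y, x)")
        if np.any(arr < 0):
            raise InvalidParameterError("intensities must be non-negative")
        object.__setattr__(self, "intensities", arr)


def _densify(
    backbone: ChainConformation, spacing: float
) -> tuple[np.ndarray, np.ndarray]:
    """Resample the backbone polyline at ~``spacing`` um; return (points, arclength)."""
    pts = backbone.points
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate(([0.0], np.cumsum(seg)))
    n = max(int(math.ceil(s[-1] / spacing)) + 1, 2)
    s_new = np.linspace(0.0, s[-1], n)
    dense = np.column_stack(
        (np.interp(s_new, s, pts[:, 0]), np.interp(s_new, s, pts[:, 1]))
    )
    return dense, s_new


def render_sheet(
    backbone: ChainConformation,
    height_profile,
    thickness: float,
    base_z: float,
    params: SceneParams,
) -> np.ndarray:
    """Render one ruffle sheet as a (z, y, x) occupancy volume in [0, 1].

    The sheet is a slab of the given lateral ``thickness`` centred on the
    backbone, extruded vertically from ``base_z`` to ``base_z + height(s)``
    where ``s`` is arclength.  ``height_profile`` is either a scalar (constant
    height) or an ``(m, 2)`` array of (arclength um, height um) interpolated
    linearly.  Voxel values are the approximate occupied fraction (linear
    partial-volume weighting on each face), with flat end caps.
    """
    dx, dy, dz = params.voxel_size
    nx, ny, nz = params.volume_shape
    if thickness < min(dx, dy):
        raise InvalidParameterError("thickness must be at least one lateral voxel")
    dense, s_dense = _densify(backbone, spacing=min(dx, dy) / 4.0)
    margin = thickness / 2.0
    bad = (
        (dense[:, 0] < margin)
        | (dense[:, 0] > nx * dx - margin)
        | (dense[:, 1] < margin)
        | (dense[:, 1] > ny * dy - margin)
    )
    if np.any(bad):
        x, y = dense[np.argmax(bad)]
        raise OutOfBoundsError(
            f"backbone point (x={x:.3f}, y={y:.3f}) um does not fit inside the "
            f"{nx * dx:.1f} x {ny * dy:.1f} um lateral field of view"
        )

    if np.isscalar(height_profile):
        heights_dense = np.full(len(dense), float(height_profile))
    else:
        hp = np.asarray(height_profile, dtype=float)
        heights_dense = np.interp(s_dense, hp[:, 0], hp[:, 1])
    if np.any(heights_dense < 0):
        raise InvalidParameterError("heights must be >= 0")

    # lateral occupancy: nearest dense station per voxel centre
    xs = (np.arange(nx) + 0.5) * dx
    ys = (np.arange(ny) + 0.5) * dy
    gx, gy = np.meshgrid(xs, ys, indexing="xy")  # (ny, nx)
    centres = np.column_stack((gx.ravel(), gy.ravel()))
    tree = cKDTree(dense)
    dist, idx = tree.query(centres, workers=-1)
    w_lat = math.sqrt(dx * dy)
    f_lat = np.clip(0.5 + (thickness / 2.0 - dist) / w_lat, 0.0, 1.0)

    # flat end caps: linear fall-off along the terminal tangents
    f_cap = np.ones_like(f_lat)
    for end_idx, sign in ((0, -1.0), (len(dense) - 1, 1.0)):
        tangent = dense[min(end_idx + 1, len(dense) - 1)] - dense[
            max(end_idx - 1, 0)
        ]
        norm = np.linalg.norm(tangent)
        if norm == 0:
            continue
        tangent = sign * tangent / norm
        at_end = idx == end_idx
        overshoot = (centres[at_end] - dense[end_idx]) @ tangent
        f_cap[at_end] = np.clip(0.5 - overshoot / w_lat, 0.0, 1.0)

    heights = heights_dense[idx]  # per lateral voxel
    top = base_z + heights
    z_lo = np.arange(nz) * dz
    z_hi = z_lo + dz
    # overlap of each voxel's z-extent with [base_z, top], per lateral pixel
    f_z = (
        np.minimum(top[None, :], z_hi[:, None]) - np.maximum(base_z, z_lo[:, None])
    ) / dz
    f_z = np.clip(f_z, 0.0, 1.0)
    volume = (f_z * (f_lat * f_cap)[None, :]).reshape(nz, ny, nx)
    return volume


def apply_psf_noise(
    volume: np.ndarray,
    psf_sigma: tuple[float, float],
    photon_scale: float,
    camera_offset: float,
    seed: int,
    voxel_size: tuple[float, float, float] = (0.1, 0.1, 0.1),
) -> np.ndarray:
    """Degrade a (z, y, x) density volume into camera counts.

    Applies an anisotropic Gaussian blur (``psf_sigma = (lateral, axial)`` in
    um, converted to voxels), then draws Poisson counts at
    ``photon_scale * density`` and adds ``camera_offset``.  Deterministic
    under a fixed ``seed``.
    """
    lateral, axial = psf_sigma
    if lateral < 0 or axial < 0:
        raise InvalidParameterError("psf_sigma components must be >= 0")
    if np.any(np.asarray(volume) < 0):
        raise InvalidParameterError("volume must be non-negative")
    dx, dy, dz = voxel_size
    blurred = np.asarray(volume, dtype=float)
    if lateral > 0 or axial > 0:
        blurred = gaussian_filter(blurred, sigma=(axial / dz, lateral / dy, lateral / dx))
    rng = np.random.default_rng(seed)
    counts = rng.poisson(photon_scale * np.clip(blurred, 0.0, None)).astype(float)
    return counts + camera_offset


def _chain_footprint_ok(
    dense: np.ndarray, placed: list[np.ndarray], clearance: float
) -> bool:
    for other in placed:
        if cKDTree(other).query(dense, k=1)[0].min() < clearance:
            return False
    return True


def _place_chain(
    chain: ChainConformation, rng: np.random.Generator, params: SceneParams
) -> ChainConformation | None:
    """Random rotation + translation keeping the chain inside the field."""
    nx, ny, _ = params.volume_shape
    dx, dy, _ = params.voxel_size
    margin = params.thickness / 2.0 + 0.3
    theta = rng.uniform(0.0, 2.0 * math.pi)
    rot = np.array(
        [[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]]
    )
    pts = chain.points @ rot.T
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    span = hi - lo
    avail = np.array([nx * dx, ny * dy]) - 2 * margin - span
    if np.any(avail <= 0):
        return None
    shift = margin - lo + rng.uniform(0.0, 1.0, size=2) * avail
    return ChainConformation(points=pts + shift, step=chain.step, _validate=False)


def synthesize_ruffle_scene(
    params: SceneParams, seed: int
) -> tuple[VolumeTimeSeries, GroundTruth]:
    """Render a full synthetic scene with its ground truth.

    Backbones are worm-like chains placed by rejection sampling so that their
    lateral footprints stay at least 0.4 um apart (at most 1000 attempts per
    ruffle).  Channel 1 holds the ruffle density plus a cytosol slab below the
    dorsal surface; channel 2 multiplies ruffle density by
    ``channel2_enrichment`` with the same unit-density cytosol.  Each frame and
    channel is degraded independently; the geometry is static over time.
    """
    rng = np.random.default_rng(seed)
    nx, ny, nz = params.volume_shape
    placed: list[RuffleTruth] = []
    footprints: list[np.ndarray] = []
    clearance = params.thickness + 0.4
    occupancy = np.zeros((nz, ny, nx))
    for i in range(params.n_ruffles):
        for attempt in range(1000):
            chain_seed = int(rng.integers(0, 2**31 - 1))
            chain = sample_chain(params.backbone_params, seed=chain_seed)
            placed_chain = _place_chain(chain, rng, params)
            if placed_chain is None:
                continue
            dense, s_dense = _densify(placed_chain, spacing=0.05)
            if not _chain_footprint_ok(dense, footprints, clearance):
                continue
            height = float(
                np.clip(
                    rng.normal(params.height_mean, params.height_sd), 0.3, None
                )
            )
            occupancy += render_sheet(
                placed_chain, height, params.thickness, params.base_z, params
            )
            footprints.append(dense)
            placed.append(
                RuffleTruth(
                    backbone=placed_chain,
                    arclength=s_dense,
                    height_profile=np.full(len(s_dense), height),
                    thickness=params.thickness,
                    channel2_enrichment=params.channel2_enrichment,
                )
            )
            break
        else:
            raise SceneTooCrowdedError(
                f"could not place ruffle {i + 1}/{params.n_ruffles} after 1000 attempts"
            )
    occupancy = np.clip(occupancy, 0.0, 1.0)

    z_centres = (np.arange(nz) + 0.5) * params.voxel_size[2]
    cytosol = np.zeros_like(occupancy)
    cytosol[z_centres < params.base_z] = params.cytosol_density
    cytosol *= 1.0 - occupancy  # ruffle displaces cytosol where they touch

    densities = [occupancy + cytosol]
    if params.n_channels == 2:
        densities.append(occupancy * params.channel2_enrichment + cytosol)

    frames = np.empty(
        (params.n_frames, params.n_channels, nz, ny, nx), dtype=float
    )
    for t in range(params.n_frames):
        for c, density in enumerate(densities):
            noise_seed = int(rng.integers(0, 2**31 - 1))
            frames[t, c] = apply_psf_noise(
                density,
                params.psf_sigma,
                params.photon_scale,
                params.camera_offset,
                seed=noise_seed,
                voxel_size=params.voxel_size,
            )
    series = VolumeTimeSeries(
        intensities=frames,
        voxel_size=params.voxel_size,
        frame_interval=params.frame_interval,
    )
    return series, GroundTruth(ruffles=placed, base_z=params.base_z, params=params)


def synthesize_recruitment_traces(
    n_ruffles: int,
    n_frames: int,
    frame_interval: float,
    lag_frames: int,
    noise_sd: float,
    seed: int,
) -> pd.DataFrame:
    """Paired two-channel recruitment traces with a known lag.

    Channel 1 is a smooth logistic rise-to-plateau with a randomized onset;
    channel 2 is the same curve delayed by ``lag_frames`` frames plus Gaussian
    noise.  Returns a tidy table ``(ruffle_id, t_s, I1, I2)``.
    """
    if n_frames < 8:
        raise InvalidParameterError("n_frames must be >= 8")
    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be >= 0")
    if abs(lag_frames) >= n_frames / 2:
        raise InvalidParameterError("|lag_frames| must be < n_frames / 2")
    rng = np.random.default_rng(seed)
    k = np.arange(n_frames, dtype=float)
    rows = []
    for r in range(n_ruffles):
        onset = rng.uniform(0.3 * n_frames, 0.55 * n_frames)
        tau = rng.uniform(1.5, 3.0)
        i1 = 1.0 / (1.0 + np.exp(-(k - onset) / tau))
        i2 = 1.0 / (1.0 + np.exp(-(k - lag_frames - onset) / tau))
        if noise_sd > 0:
            i2 = i2 + rng.normal(0.0, noise_sd, size=n_frames)
        for t_idx in range(n_frames):
            rows.append((r, t_idx * frame_interval, i1[t_idx], i2[t_idx]))
    return pd.DataFrame(rows, columns=["ruffle_id", "t_s", "I1", "I2"])
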