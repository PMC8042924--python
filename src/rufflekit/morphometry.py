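"""Ruffle morphometry: segmentation, skeleton analysis, thickness and height.

The measurement chain mirrors common fluorescence-microscopy practice:

* a maximum-intensity projection collapses the volume to a top view;
* Gaussian smoothing + Otsu thresholding + connected components segment
  individual ruffles;
* each ruffle mask is skeletonized and its skeleton treated as a graph
  (junctions and endpoints are nodes, arcs are edges); the contour is the
  longest endpoint-to-endpoint path found with step weights 1 (axial) and
  sqrt(2) (diagonal), as in branch-length analysis of skeletons.  Its
  reported length applies two standard digitization corrections — an
  endpoint-preserving smoothing of the pixel path (the raw 1/sqrt(2) metric
  overestimates oblique and curved contours by up to ~8%) and a tangent
  extension of both ends to the mask boundary (thinning erodes ends by about
  half the local width).  The end-to-end distance is the Euclidean distance
  between the corrected endpoints;
* thickness is the full width at half maximum of an interpolated cross-
  section profile, corrected in quadrature for the residual point-spread
  blur: ``t = sqrt(max(FWHM^2 - (2.355 sigma)^2, 0))``;
* height is located per vertical column by sub-pixel linear interpolation of
  the threshold crossing at the top edge of the sheet.

Coordinates follow the voxel-centre convention: physical position of index
``i`` is ``(i + 0.5) * pixel_size``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, map_coordinates
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.morphology import skeletonize

from .errors import (
    InsufficientDataError,
    InvalidParameterError,
    UnmeasurableProfileError,
)

__all__ = [
    "RuffleRecord",
    "HeightProfile",
    "max_intensity_projection",
    "segment_ruffles",
    "skeletonize_and_measure",
    "longest_skeleton_path",
    "measure_thickness",
    "thickness_along_path",
    "measure_height_profile",
]

GAUSSIAN_FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))  # 2.3548


@dataclass(frozen=True)
class RuffleRecord:
    """Per-ruffle morphometric measurements (lengths in um)."""

    ruffle_id: int
    contour_length: float
    end_to_end: float
    n_branches: int
    mean_thickness: float = math.nan
    mean_height: float = math.nan
    height_sd: float = math.nan
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.contour_length < 0 or self.end_to_end < 0:
            raise InvalidParameterError("lengths must be >= 0")
        if self.end_to_end > self.contour_length * (1 + 1e-9) + 1e-12:
            raise InvalidParameterError("end-to-end distance cannot exceed contour length")


@dataclass(frozen=True)
class HeightProfile:
    """Height along a ruffle's skeleton (arclength and height in um)."""

    arclength: np.ndarray
    height: np.ndarray
    flags: np.ndarray  # True where the column never crossed the threshold

    @property
    def mean(self) -> float:
        return float(np.mean(self.height))

    @property
    def sd(self) -> float:
        return float(np.std(self.height, ddof=1)) if len(self.height) > 1 else 0.0


def max_intensity_projection(volume: np.ndarray, axis: int = 0) -> np.ndarray:
    """Per-pixel maximum of a 3-D volume along ``axis``."""
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise InvalidParameterError("volume must be 3-D")
    if not -3 <= axis < 3:
        raise InvalidParameterError(f"axis {axis} out of range for a 3-D volume")
    return volume.max(axis=axis)


def segment_ruffles(
    image: np.ndarray,
    smoothing_sigma: float = 1.0,
    min_area_um2: float = 0.25,
    pixel_size: float = 0.1,
) -> np.ndarray:
    """Label individual ruffles in a 2-D projection image.

    Gaussian smoothing (``smoothing_sigma`` in pixels), Otsu threshold,
    8-connected component labelling, then removal of components smaller than
    ``min_area_um2``.  A blank image (single intensity value) yields an empty
    mask with a warning rather than an exception.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise InvalidParameterError("image must be 2-D")
    if np.ptp(image) == 0:
        warnings.warn("blank image: no ruffles segmented", stacklevel=2)
        return np.zeros(image.shape, dtype=np.int32)
    smoothed = gaussian_filter(image, smoothing_sigma) if smoothing_sigma > 0 else image
    mask = smoothed > threshold_otsu(smoothed)
    min_px = max(int(round(min_area_um2 / pixel_size**2)), 1)
    labels = sk_label(mask, connectivity=2)
    areas = np.bincount(labels.ravel())
    keep = np.flatnonzero(areas >= min_px)
    keep = keep[keep != 0]
    relabel = np.zeros(areas.size, dtype=np.int32)
    relabel[keep] = np.arange(1, keep.size + 1, dtype=np.int32)
    return relabel[labels]


_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _skeleton_graph(skel: np.ndarray) -> nx.Graph:
    """8-connected pixel graph of a skeleton; edge weights 1 or sqrt(2) px."""
    graph = nx.Graph()
    coords = set(map(tuple, np.argwhere(skel)))
    for rc in coords:
        graph.add_node(rc)
    for r, c in coords:
        for dr, dc in _OFFSETS:
            nb = (r + dr, c + dc)
            if nb in coords:
                graph.add_edge((r, c), nb, weight=math.hypot(dr, dc))
    return graph


def _prune_spurs(graph: nx.Graph, min_length_px: float) -> nx.Graph:
    """Iteratively remove terminal arcs shorter than ``min_length_px``."""
    graph = graph.copy()
    changed = True
    while changed:
        changed = False
        endpoints = [n for n in graph.nodes if graph.degree(n) == 1]
        for ep in endpoints:
            if ep not in graph:
                continue
            # walk from the endpoint until a junction or another endpoint
            arc = [ep]
            length = 0.0
            prev, cur = None, ep
            while True:
                nbrs = [n for n in graph.neighbors(cur) if n != prev]
                if graph.degree(cur) >= 3 or (not nbrs and cur != ep):
                    break
                if not nbrs:
                    break
                nxt = nbrs[0]
                length += graph[cur][nxt]["weight"]
                prev, cur = cur, nxt
                if graph.degree(cur) >= 3:
                    break
                arc.append(cur)
            terminates_at_junction = graph.degree(cur) >= 3
            if terminates_at_junction and length < min_length_px:
                graph.remove_nodes_from(arc)
                changed = True
    return graph


def _count_branches(graph: nx.Graph) -> int:
    """Number of arcs between junction clusters and endpoints.

    Adjacent junction pixels (8-connected skeletons produce small junction
    clusters) are merged into one node before counting, so a Y-shape counts 3
    branches regardless of how its centre rasterizes.
    """
    if graph.number_of_nodes() <= 1:
        return 0
    special = {n for n in graph.nodes if graph.degree(n) != 2}
    if not special:  # pure cycle
        return 1
    cluster_of: dict = {}
    for comp in nx.connected_components(graph.subgraph(special)):
        rep = min(comp)
        for node in comp:
            cluster_of[node] = rep
    visited_edges = set()
    arcs = set()
    for node in special:
        for nbr in graph.neighbors(node):
            edge = frozenset((node, nbr))
            if edge in visited_edges:
                continue
            visited_edges.add(edge)
            if nbr in special:
                if cluster_of[node] != cluster_of[nbr]:
                    arcs.add(frozenset((cluster_of[node], cluster_of[nbr], "direct")))
                continue
            prev, cur = node, nbr
            interior = [cur]
            while cur not in special:
                nxt = [n for n in graph.neighbors(cur) if n != prev]
                if not nxt:
                    break
                visited_edges.add(frozenset((cur, nxt[0])))
                prev, cur = cur, nxt[0]
                interior.append(cur)
            arcs.add(frozenset((cluster_of[node], min(interior))))
    return len(arcs)


def longest_skeleton_path(mask: np.ndarray, prune_px: float = 3.0):
    """Skeletonize a binary mask and return its longest path.

    Returns ``(path, length_px, n_branches)`` where ``path`` is an ordered
    (n, 2) array of (row, col) skeleton pixels along the longest
    endpoint-to-endpoint route (weights 1 / sqrt(2)), ``length_px`` its length
    in pixel units, and ``n_branches`` the arc count of the pruned skeleton.
    Spurs shorter than ``prune_px`` are removed first.
    """
    skel = skeletonize(mask.astype(bool))
    graph = _skeleton_graph(skel)
    if graph.number_of_nodes() == 0:
        return np.empty((0, 2), dtype=int), 0.0, 0
    graph = _prune_spurs(graph, prune_px)
    if graph.number_of_nodes() == 0:
        return np.empty((0, 2), dtype=int), 0.0, 0
    n_branches = max(_count_branches(graph), 1)
    if graph.number_of_nodes() == 1:
        return np.asarray(list(graph.nodes), dtype=int), 0.0, n_branches
    endpoints = [n for n in graph.nodes if graph.degree(n) == 1]
    if len(endpoints) >= 2:
        best = (-1.0, None, None)
        for i, src in enumerate(endpoints):
            dist = nx.single_source_dijkstra_path_length(graph, src, weight="weight")
            for dst in endpoints[i + 1 :]:
                d = dist.get(dst, -1.0)
                if d > best[0]:
                    best = (d, src, dst)
        length_px, src, dst = best
    else:
        # cyclic skeleton (thinning can close small loops): double-sweep
        # heuristic for the most distant pixel pair
        start = next(iter(graph.nodes))
        for _ in range(2):
            dist = nx.single_source_dijkstra_path_length(graph, start, weight="weight")
            start, length_px = max(dist.items(), key=lambda kv: kv[1])
        src, dst = start, max(
            nx.single_source_dijkstra_path_length(graph, start, weight="weight").items(),
            key=lambda kv: kv[1],
        )[0]
        length_px = nx.dijkstra_path_length(graph, src, dst, weight="weight")
    path = nx.dijkstra_path(graph, src, dst, weight="weight")
    return np.asarray(path, dtype=int), float(length_px), n_branches


def _chaikin(points: np.ndarray, iterations: int = 3) -> np.ndarray:
    """Chaikin corner-cutting; endpoint-preserving low-pass for pixel paths."""
    pts = points
    for _ in range(iterations):
        if len(pts) < 3:
            return pts
        q = 0.75 * pts[:-1] + 0.25 * pts[1:]
        r = 0.25 * pts[:-1] + 0.75 * pts[1:]
        mid = np.empty((2 * len(pts) - 2, 2))
        mid[0::2] = q
        mid[1::2] = r
        pts = np.concatenate(([pts[0]], mid, [pts[-1]]))
    return pts


def _corrected_path_metrics(
    path: np.ndarray, mask: np.ndarray, pixel_size: float
) -> tuple[float, float]:
    """Contour length and end-to-end distance (um) of a skeleton path.

    Two digitization corrections are applied: (i) the path coordinates are
    smoothed (Gaussian, sigma 2 px) before summing segment lengths, removing
    the systematic overestimate of the 1/sqrt(2) pixel metric on oblique or
    curved paths; (ii) each end is extended along its local tangent to the
    mask boundary (minus half a pixel, the centre-to-edge offset), undoing the
    end erosion of topological thinning.
    """
    pts = path.astype(float)
    smooth = _chaikin(pts, iterations=3)
    length_px = float(np.sum(np.linalg.norm(np.diff(smooth, axis=0), axis=1)))
    ends = []
    for end, inner in ((0, min(6, len(pts) - 1)), (-1, max(-7, -len(pts)))):
        direction = pts[end] - pts[inner]
        norm = np.linalg.norm(direction)
        end_pos = pts[end].copy()
        if norm > 0:
            direction = direction / norm
            travelled = 0.0
            pos = pts[end].copy()
            while travelled < 10.0:
                nxt = pos + 0.25 * direction
                idx = np.floor(nxt + 0.5).astype(int)  # pixel i covers [i-.5, i+.5)
                if (
                    np.any(idx < 0)
                    or np.any(idx >= np.asarray(mask.shape))
                    or not mask[idx[0], idx[1]]
                ):
                    break
                pos, travelled = nxt, travelled + 0.25
            extension = max(travelled - 0.5, 0.0)
            length_px += extension
            end_pos = pts[end] + extension * direction
        ends.append(end_pos)
    r_ee_px = float(np.linalg.norm(ends[1] - ends[0]))
    L = length_px * pixel_size
    return L, min(r_ee_px * pixel_size, L)


def skeletonize_and_measure(
    mask: np.ndarray,
    pixel_size: float,
    prune_um: float = 0.3,
) -> pd.DataFrame:
    """Skeleton-based contour metrics for every label in a mask.

    Per label: the longest skeleton path is found with 1 / sqrt(2) step
    weights after pruning spurs shorter than ``prune_um``; its contour length
    and end-to-end distance are reported after digitization corrections (see
    :func:`_corrected_path_metrics`), and the branch count is the arc count of
    the pruned skeleton graph.  Labels whose skeleton collapses to a single
    pixel yield ``L = 0`` flagged degenerate.  Returns a DataFrame with
    columns (ruffle_id, L_um, Ree_um, n_branches, degenerate).
    """
    if pixel_size <= 0:
        raise InvalidParameterError("pixel_size must be > 0")
    mask = np.asarray(mask)
    rows = []
    for lab in np.unique(mask):
        if lab == 0:
            continue
        path, length_px, n_branches = longest_skeleton_path(
            mask == lab, prune_px=prune_um / pixel_size
        )
        if len(path) < 2:
            rows.append((int(lab), 0.0, 0.0, max(n_branches, 1), True))
            continue
        L, r_ee = _corrected_path_metrics(path, mask == lab, pixel_size)
        rows.append((int(lab), L, r_ee, n_branches, False))
    return pd.DataFrame(
        rows, columns=["ruffle_id", "L_um", "Ree_um", "n_branches", "degenerate"]
    )


def measure_thickness(
    plane_image: np.ndarray,
    cross_section,
    pixel_size: float,
    psf_sigma: float = 0.0,
) -> float:
    """PSF-corrected FWHM thickness (um) along one cross-section line.

    ``cross_section = ((r0, c0), (r1, c1))`` in (fractional) pixel
    coordinates.  The profile is sampled at quarter-pixel spacing with
    bilinear interpolation; the baseline is the median of the outer 15% of
    samples at each end; the FWHM is found by linear interpolation of the
    half-maximum crossings bracketing the peak, then corrected in quadrature
    for a Gaussian PSF of standard deviation ``psf_sigma`` (um).
    """
    (r0, c0), (r1, c1) = cross_section
    length_px = math.hypot(r1 - r0, c1 - c0)
    if length_px <= 0:
        raise InvalidParameterError("cross-section endpoints coincide")
    n = int(math.ceil(length_px * 4)) + 1
    rows = np.linspace(r0, r1, n)
    cols = np.linspace(c0, c1, n)
    profile = map_coordinates(
        np.asarray(plane_image, dtype=float), [rows, cols], order=1, mode="nearest"
    )
    spacing_um = length_px / (n - 1) * pixel_size
    n_tail = max(int(round(0.15 * n)), 2)
    baseline = float(np.median(np.concatenate((profile[:n_tail], profile[-n_tail:]))))
    peak_idx = int(np.argmax(profile))
    half = baseline + 0.5 * (profile[peak_idx] - baseline)
    if profile[peak_idx] <= baseline:
        raise UnmeasurableProfileError("profile has no peak above baseline")

    above = profile >= half
    if not (np.any(~above[:peak_idx]) and np.any(~above[peak_idx + 1 :])):
        raise UnmeasurableProfileError(
            "profile does not fall below half maximum on both sides of the peak"
        )
    left = peak_idx
    while above[left - 1]:
        left -= 1
    right = peak_idx
    while above[right + 1]:
        right += 1
    # sub-sample linear interpolation of the two half-maximum crossings
    crossing_left = (left - 1) + (half - profile[left - 1]) / (
        profile[left] - profile[left - 1]
    )
    crossing_right = right + (half - profile[right]) / (
        profile[right + 1] - profile[right]
    )
    fwhm_um = (crossing_right - crossing_left) * spacing_um
    corrected_sq = fwhm_um**2 - (GAUSSIAN_FWHM_FACTOR * psf_sigma) ** 2
    return math.sqrt(max(corrected_sq, 0.0))


def thickness_along_path(
    plane_image: np.ndarray,
    path_px: np.ndarray,
    pixel_size: float,
    psf_sigma: float = 0.0,
    spacing_um: float = 0.2,
    line_length_um: float = 4.0,
    smooth_px: float = 3.0,
) -> np.ndarray:
    """Thickness at stations spaced ``spacing_um`` along a pixel path.

    Cross-section lines run along the local normal (tangent from a smoothed
    path).  Stations whose profile has no measurable FWHM are skipped.
    """
    path = np.asarray(path_px, dtype=float)
    if len(path) < 3:
        raise InsufficientDataError("path too short for cross-sections")
    if smooth_px > 0:
        path = np.column_stack(
            [gaussian_filter(path[:, i], smooth_px, mode="nearest") for i in (0, 1)]
        )
    seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
    s = np.concatenate(([0.0], np.cumsum(seg))) * pixel_size
    stations = np.arange(spacing_um, s[-1] - spacing_um, spacing_um)
    half_len_px = line_length_um / 2.0 / pixel_size
    values = []
    for st in stations:
        i = int(np.searchsorted(s, st))
        i = min(max(i, 1), len(path) - 2)
        tangent = path[i + 1] - path[i - 1]
        norm = np.linalg.norm(tangent)
        if norm == 0:
            continue
        normal = np.array([-tangent[1], tangent[0]]) / norm
        centre = path[i]
        p0 = centre - normal * half_len_px
        p1 = centre + normal * half_len_px
        try:
            values.append(
                measure_thickness(plane_image, (p0, p1), pixel_size, psf_sigma)
            )
        except UnmeasurableProfileError:
            continue
    return np.asarray(values)


def measure_height_profile(
    volume: np.ndarray,
    ruffle_mask: np.ndarray,
    base_z: float,
    sampling_step: float = 0.2,
    voxel_size: tuple[float, float, float] = (0.1, 0.1, 0.1),
    threshold: float | None = None,
    prune_um: float = 0.3,
) -> HeightProfile:
    """Sub-pixel height profile along a ruffle's skeleton.

    At stations spaced ``sampling_step`` (um) along the skeleton of
    ``ruffle_mask`` (a 2-D boolean footprint in the (y, x) plane of the
    (z, y, x) ``volume``), the vertical intensity column is extracted and the
    top edge located as the sub-pixel z where the intensity falls through
    ``threshold`` (Otsu of the volume when None), by linear interpolation
    between bracketing voxels.  Height = top edge - ``base_z``; columns that
    never reach the threshold record height 0 with a flag.
    """
    volume = np.asarray(volume, dtype=float)
    if volume.ndim != 3:
        raise InvalidParameterError("volume must be 3-D (z, y, x)")
    dx, dy, dz = voxel_size
    nz = volume.shape[0]
    if not 0 <= base_z <= nz * dz:
        raise InvalidParameterError("base_z must lie inside the volume")
    if not np.any(ruffle_mask):
        raise InsufficientDataError("ruffle mask is empty")
    if threshold is None:
        threshold = float(threshold_otsu(volume))
    path, _, _ = longest_skeleton_path(
        np.asarray(ruffle_mask, dtype=bool), prune_px=prune_um / dx
    )
    if len(path) < 2:
        raise InsufficientDataError("skeleton too short for a height profile")
    seg = np.linalg.norm(np.diff(path.astype(float), axis=0), axis=1)
    s = np.concatenate(([0.0], np.cumsum(seg))) * dx
    stations = np.arange(0.0, s[-1] + 1e-9, sampling_step)
    heights = np.zeros(len(stations))
    flags = np.zeros(len(stations), dtype=bool)
    for k, st in enumerate(stations):
        i = min(int(np.searchsorted(s, st)), len(path) - 1)
        r, c = path[i]
        column = volume[:, r, c]
        above = np.nonzero(column >= threshold)[0]
        if above.size == 0:
            flags[k] = True
            continue
        top = int(above[-1])
        z_top = (top + 0.5) * dz
        if top + 1 < nz and column[top] > column[top + 1]:
            frac = (column[top] - threshold) / (column[top] - column[top + 1])
            z_top += frac * dz
        heights[k] = max(z_top - base_z, 0.0)
    return HeightProfile(arclength=stations, height=heights, flags=flags)
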