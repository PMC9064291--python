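"""3D detection of centrioles (puncta) and cilia (filaments).

Centrioles appear as diffraction-limited puncta in the centriole-marker
channel; they are detected as local maxima of a scale-normalised multi-scale
Laplacian-of-Gaussian (LoG) response, with per-axis sigmas scaled for the
axial elongation of a confocal point-spread function.  Cilia are filaments in
the cilium-marker channel; they are extracted by matched smoothing,
thresholding, 3D skeletonisation and path tracing.  Association pairs each
cilium base with at most one centriole by optimal assignment on base-to-spot
distance inside a capture radius.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import linear_sum_assignment
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import shortest_path
from skimage.feature import peak_local_max
from skimage.filters import apply_hysteresis_threshold, threshold_otsu
from skimage.morphology import skeletonize

from .io import VoxelGrid, polyline_length

logger = logging.getLogger("centriomig")

#: Axial-to-lateral PSF elongation assumed when building anisotropic LoG
#: kernels (typical spinning-disk confocal ratio).
DEFAULT_AXIAL_FACTOR = 2.33


@dataclass(frozen=True)
class Spot:
    """A detected punctum with physical coordinates."""

    id: int
    position_um: tuple[float, float, float]  # (z, y, x)
    scale_um: float
    intensity: float
    roi_id: int | None = None


@dataclass(frozen=True)
class Cilium:
    """A detected filament: ordered 3D polyline with a designated base."""

    id: int
    polyline_um: np.ndarray  # (n, 3) points, base first
    length_um: float

    @property
    def base_um(self) -> np.ndarray:
        return self.polyline_um[0]


@dataclass(frozen=True)
class AssociationResult:
    """One-to-one centriole-cilium matching and the association fraction."""

    pairs: tuple[tuple[int, int], ...]  # (spot id, cilium id)
    n_spots: int
    n_cilia: int

    @property
    def fraction_associated(self) -> float:
        return len(self.pairs) / self.n_spots if self.n_spots else 0.0


def _log_noise_gain(sigma_vox: np.ndarray) -> float:
    """L2 norm of the (unnormalised) Laplacian-of-Gaussian kernel.

    White noise of unit variance filtered by the LoG has this standard
    deviation.  Computed from separable 1D integrals of the Gaussian and
    its second derivative on the voxel lattice.
    """
    A, C, D = [], [], []
    for s in sigma_vox:
        half = int(np.ceil(6 * s)) + 1
        x = np.arange(-half, half + 1, dtype=float)
        g = np.exp(-(x**2) / (2 * s**2)) / (np.sqrt(2 * np.pi) * s)
        g2 = (x**2 / s**4 - 1.0 / s**2) * g  # second derivative
        A.append(float(np.sum(g * g)))
        C.append(float(np.sum(g2 * g2)))
        D.append(float(np.sum(g * g2)))
    total = (
        C[0] * A[1] * A[2] + A[0] * C[1] * A[2] + A[0] * A[1] * C[2]
        + 2 * (D[0] * D[1] * A[2] + D[0] * A[1] * D[2] + A[0] * D[1] * D[2])
    )
    return float(np.sqrt(max(total, 0.0)))


def _raw_noise_sigma(vol: np.ndarray) -> float:
    """Robust per-voxel noise s.d. of the raw image (wavelet estimator)."""
    from skimage.restoration import estimate_sigma

    return float(estimate_sigma(vol))


def detect_spots(
    image: VoxelGrid,
    channel: int | str = 0,
    scale_range_um: tuple[float, float] = (0.4, 1.0),
    threshold_policy: str = "otsu",
    threshold_abs: float | None = None,
    n_scales: int = 4,
    axial_factor: float = DEFAULT_AXIAL_FACTOR,
    t: int = 0,
    refine: bool = True,
    review: pd.DataFrame | None = None,
) -> list[Spot]:
    """Detect diffraction-limited puncta in one channel at one timepoint.

    Parameters
    ----------
    scale_range_um
        Lateral blob-scale interval bracketing the expected centriole radius
        (≈0.5–1 µm at expanded scale).
    threshold_policy
        ``"otsu"`` (default): Otsu on the pooled LoG response, floored by a
        robust noise estimate so a pure-noise image yields no spots;
        ``"absolute"``: use ``threshold_abs`` directly.
    review
        Optional manual-review table with columns ``id`` and ``keep``
        (boolean); detections flagged ``keep == False`` are dropped, making a
        semi-automated count reproducible.

    Returns
    -------
    list of Spot, sorted by descending intensity, de-duplicated so that no
    two spots lie within ``0.7 × (scale_i + scale_j)`` of each other.
    """
    vol = image.volume(channel, t).astype(np.float32)
    spacing = np.asarray(image.spacing_um, dtype=float)
    lo, hi = scale_range_um
    if not 0 < lo <= hi:
        raise ValueError(f"invalid scale range {scale_range_um}")
    scales = np.geomspace(lo, hi, n_scales)

    responses = np.empty((len(scales),) + vol.shape, dtype=np.float32)
    aniso = np.array([axial_factor, 1.0, 1.0])
    for i, s in enumerate(scales):
        sigma_vox = s * aniso / spacing
        responses[i] = -(s**2) * ndimage.gaussian_laplace(vol, sigma_vox)
    pooled = responses.max(axis=0)
    best_scale = responses.argmax(axis=0)

    if threshold_policy == "absolute":
        if threshold_abs is None:
            raise ValueError("threshold_abs required with policy 'absolute'")
        thr = float(threshold_abs)
    elif threshold_policy == "otsu":
        # floor: k sigma of the pure-noise response of the most permissive
        # scale, so an empty image cannot yield Otsu-driven false spots
        sigma_raw = _raw_noise_sigma(vol)
        gain = max(
            s**2 * _log_noise_gain(s * aniso / spacing) for s in scales
        )
        floor = 8.5 * sigma_raw * gain
        thr = max(float(threshold_otsu(pooled)), floor)
        if threshold_abs is not None:
            thr = max(thr, float(threshold_abs))
    else:
        raise ValueError(f"unknown threshold policy {threshold_policy!r}")
    logger.debug("spot detection threshold %.4g (policy %s)", thr, threshold_policy)

    min_dist_vox = np.maximum(1, np.round(0.7 * lo * aniso / spacing)).astype(int)
    peaks = peak_local_max(
        pooled,
        threshold_abs=thr,
        min_distance=int(min_dist_vox.min()),
        exclude_border=False,
    )
    if peaks.size == 0:
        return []

    candidates = []
    for pz, py, px in peaks:
        s = float(scales[best_scale[pz, py, px]])
        resp = float(pooled[pz, py, px])
        pos = np.array([pz, py, px], dtype=float)
        if refine:
            pos = _refine_centroid(vol, (pz, py, px), s * aniso / spacing)
        candidates.append((resp, s, pos * spacing))
    candidates.sort(key=lambda c: -c[0])

    kept: list[tuple[float, float, np.ndarray]] = []
    for resp, s, pos in candidates:
        if all(
            np.linalg.norm(pos - kpos) >= 0.7 * (s + ks) for _, ks, kpos in kept
        ):
            kept.append((resp, s, pos))

    spots = [
        Spot(id=i, position_um=tuple(pos), scale_um=s, intensity=resp)
        for i, (resp, s, pos) in enumerate(kept)
    ]
    if review is not None:
        drop = set(review.loc[~review["keep"].astype(bool), "id"].astype(int))
        spots = [sp for sp in spots if sp.id not in drop]
    return spots


def _refine_centroid(
    vol: np.ndarray, peak: tuple[int, int, int], sigma_vox: np.ndarray
) -> np.ndarray:
    """Background-subtracted intensity-weighted centroid near a peak."""
    # window tight enough to exclude a resolvable neighbour's core
    half = np.maximum(2, np.ceil(1.2 * sigma_vox)).astype(int)
    lo = np.maximum(0, np.array(peak) - half)
    hi = np.minimum(vol.shape, np.array(peak) + half + 1)
    win = vol[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]].astype(float)
    w = win - np.median(win)
    w[w < 0] = 0
    if w.sum() <= 0:
        return np.array(peak, dtype=float)
    idx = np.indices(w.shape, dtype=float)
    com = (w * idx).sum(axis=(1, 2, 3)) / w.sum()
    return lo + com


def count_centrioles(
    spots: Sequence[Spot],
    roi: np.ndarray | None = None,
    spacing_um: Sequence[float] | None = None,
) -> tuple[dict[int, int], int]:
    """Count spots per labelled region.

    Parameters
    ----------
    roi
        Integer label volume on the same grid as the detections (0 =
        background), or None to count all spots into region 1.
    spacing_um
        Required with a roi, to map physical positions back to voxels.

    Returns
    -------
    (per-region counts, number of spots outside all regions)
    """
    if roi is None:
        return ({1: len(spots)}, 0)
    if spacing_um is None:
        raise ValueError("spacing_um required when counting within a roi")
    spacing = np.asarray(spacing_um, dtype=float)
    counts: dict[int, int] = {int(lbl): 0 for lbl in np.unique(roi) if lbl != 0}
    outside = 0
    for sp in spots:
        vox = np.round(np.asarray(sp.position_um) / spacing).astype(int)
        vox = np.clip(vox, 0, np.array(roi.shape) - 1)
        lbl = int(roi[tuple(vox)])
        if lbl == 0:
            outside += 1
        else:
            counts[lbl] = counts.get(lbl, 0) + 1
    return counts, outside


# -- cilium detection ---------------------------------------------------------

_NEIGHBORS = np.array(
    [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
)


def detect_cilia(
    image: VoxelGrid,
    channel: int | str = 0,
    min_length_um: float = 2.0,
    tube_sigma_um: float = 0.2,
    threshold_factor: float = 0.75,
    t: int = 0,
    base_reference_um: Sequence[float] | np.ndarray | None = None,
    base_capture_um: float = 1.2,
    iso_spacing_um: float = 0.2,
) -> list[Cilium]:
    """Detect filamentous cilia and measure their arc lengths.

    The channel is ridge-enhanced by matched Gaussian smoothing at the tube
    scale, thresholded (foreground Otsu over a robust noise floor),
    skeletonised in 3D, and traced: each skeleton component contributes one
    path per distal endpoint, running to its nearest proximal (base)
    endpoint.  Paths shorter than ``min_length_um`` are discarded.

    Parameters
    ----------
    base_reference_um
        Reference for deciding which skeleton endpoints are cilium bases:
        either one point (z, y, x) or, better, the (n, 3) positions of the
        detected centrioles — an endpoint within ``base_capture_um`` of any
        of them is a base candidate.  Defaults to the basal centre of the
        volume.
    """
    vol = image.volume(channel, t).astype(np.float32)
    spacing = np.asarray(image.spacing_um, dtype=float)
    smoothed = ndimage.gaussian_filter(vol, tube_sigma_um / spacing)
    finite = smoothed[np.isfinite(smoothed)]
    if finite.max() <= finite.min():
        return []
    # resample to an isotropic grid: 3D thinning assumes isotropic
    # connectivity, and steep filaments are squat on an anisotropic lattice
    if not np.allclose(spacing, iso_spacing_um):
        smoothed = ndimage.zoom(smoothed, spacing / iso_spacing_um, order=1)
        spacing = np.full(3, iso_spacing_um)
    bg = float(np.median(smoothed))
    sigma_sm = 1.4826 * float(np.median(np.abs(smoothed - bg)))
    floor = bg + 8.0 * max(sigma_sm, 1e-12) + 1e-9
    fg = smoothed[smoothed > floor]
    if fg.size < 10:
        return []
    # estimate the filament core intensity (top of the above-noise Otsu
    # class) and threshold at a fraction of its height over background, so
    # the mask stays narrow enough to keep neighbouring filaments apart
    core_vox = smoothed[smoothed > float(threshold_otsu(fg))]
    core = float(np.quantile(core_vox, 0.9)) if core_vox.size else floor
    thr = max(floor, bg + threshold_factor * (core - bg))
    mask = smoothed > thr
    if not mask.any():
        return []
    skel = skeletonize(mask)
    if base_reference_um is None:
        ext = (np.array(vol.shape) - 1) * spacing
        base_reference_um = np.array([ext[0], ext[1] / 2, ext[2] / 2])
    base_ref = np.atleast_2d(np.asarray(base_reference_um, dtype=float))

    labels, n_comp = ndimage.label(skel, structure=np.ones((3, 3, 3), dtype=int))
    candidates: list[np.ndarray] = []
    for comp in range(1, n_comp + 1):
        coords = np.argwhere(labels == comp)
        if len(coords) < 3:
            continue
        for poly in _trace_component(coords, spacing, base_ref, base_capture_um):
            if len(poly) < 3:
                continue
            poly = _smooth_polyline(poly)
            # a filament's blurred intensity at its true endpoint equals
            # half its core height; the core is read off this path's own
            # interior so ends refine to the per-filament half-max level
            interior = poly[max(1, len(poly) // 4) : max(2, 3 * len(poly) // 4)]
            vals = ndimage.map_coordinates(
                smoothed, (interior / spacing).T, order=1, mode="nearest"
            )
            path_core = float(np.median(vals))
            half_max = max(floor, bg + 0.5 * (path_core - bg))
            poly = _extend_path(poly, smoothed, half_max, spacing)
            poly = _deblur_length(poly, smoothed, spacing, bg, path_core)
            if len(base_ref) > 1:
                poly = _snap_base(poly, base_ref, base_capture_um)
            if polyline_length(poly) >= min_length_um:
                candidates.append(poly)
    candidates = _dedup_paths(candidates)
    return [
        Cilium(id=i, polyline_um=poly, length_um=polyline_length(poly))
        for i, poly in enumerate(candidates)
    ]


def _profile_along(poly, smoothed, spacing, step, overshoot_um):
    """Intensity sampled at uniform arc steps along a path, extrapolated
    straight past both ends by ``overshoot_um``."""
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    arc = np.arange(-overshoot_um, cum[-1] + overshoot_um + step, step)
    pts = np.empty((len(arc), 3))
    inside = (arc >= 0) & (arc <= cum[-1])
    for d in range(3):
        pts[inside, d] = np.interp(arc[inside], cum, poly[:, d])
    head_dir = poly[0] - poly[min(4, len(poly) - 1)]
    head_dir /= max(np.linalg.norm(head_dir), 1e-9)
    tail_dir = poly[-1] - poly[-1 - min(4, len(poly) - 1)]
    tail_dir /= max(np.linalg.norm(tail_dir), 1e-9)
    pts[arc < 0] = poly[0] + np.outer(-arc[arc < 0], head_dir)
    over = arc > cum[-1]
    pts[over] = poly[-1] + np.outer(arc[over] - cum[-1], tail_dir)
    vals = ndimage.map_coordinates(
        smoothed, (pts / spacing).T, order=1, mode="nearest"
    )
    return arc, vals, float(cum[-1])


def _deblur_length(
    poly: np.ndarray,
    smoothed: np.ndarray,
    spacing: np.ndarray,
    bg: float,
    core: float,
) -> np.ndarray:
    """Correct a half-max path for blur along the shaft.

    A filament of true length L blurred along its axis with sigma has a
    measured half-max extent Lm that solves
    ``Phi((Lm+L)/2s) - Phi((Lm-L)/2s) = Phi(L/2s) - 1/2``; sigma is read
    from the 75%→25% end-ramp width (1.349 sigma for an erf ramp).  For a
    resolved filament the correction vanishes; for a sub-resolution stub it
    shrinks the measured extent toward the true length.  The polyline is
    trimmed symmetrically so that length and vertices stay consistent.
    """
    from math import erf, sqrt

    if core <= bg:
        return poly
    step = float(spacing.min()) / 2.0
    arc, vals, l_meas = _profile_along(poly, smoothed, spacing, step, 3.0)
    rel = (vals - bg) / (core - bg)
    widths = []
    for end_arc, sign in ((0.0, -1.0), (l_meas, 1.0)):
        outward = (arc - end_arc) * sign
        order = np.argsort(outward)
        x, y = outward[order], rel[order]
        hi = np.where(y >= 0.75)[0]
        lo = np.where((y <= 0.25) & (x > 0))[0]
        if len(hi) and len(lo):
            width = x[lo[0]] - x[hi[-1]]
            if 0 < width < 6.0:
                widths.append(width / 1.349)
    if not widths:
        return poly
    sigma = float(np.mean(widths))
    if sigma < 1e-6:
        return poly

    def phi(z):
        return 0.5 * (1.0 + erf(z / sqrt(2.0)))

    def measured(l_true):
        return_val = None
        # solve f(t)=0.5 f(0) for t numerically via bisection on t
        lo_t, hi_t = 0.0, l_true / 2 + 6 * sigma

        def f(t):
            return phi((t + l_true / 2) / sigma) - phi((t - l_true / 2) / sigma)

        target = 0.5 * f(0.0)
        for _ in range(60):
            mid = 0.5 * (lo_t + hi_t)
            if f(mid) > target:
                lo_t = mid
            else:
                hi_t = mid
        return lo_t + hi_t  # 2 * t_half

    lo_l, hi_l = 0.0, l_meas
    for _ in range(60):
        mid = 0.5 * (lo_l + hi_l)
        if measured(mid) < l_meas:
            lo_l = mid
        else:
            hi_l = mid
    l_est = 0.5 * (lo_l + hi_l)
    trim = max(0.0, (l_meas - l_est) / 2.0)
    if trim < step:
        return poly
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    keep = (cum >= trim) & (cum <= l_meas - trim)
    if keep.sum() < 2:
        keep = np.zeros(len(poly), dtype=bool)
        keep[[len(poly) // 2 - 1, len(poly) // 2]] = True
    return poly[keep]


def _dedup_paths(
    paths: list[np.ndarray], overlap_radius_um: float = 0.5, max_shared: float = 0.6
) -> list[np.ndarray]:
    """Drop paths that mostly retrace an already-kept (longer) path.

    Skeleton spurs near a filament tip can split one filament into two
    near-identical traces; two real filaments sharing a proximal trunk stay
    distinct because they diverge over most of their length.
    """
    order = np.argsort([-polyline_length(p) for p in paths])
    kept: list[np.ndarray] = []
    for i in order:
        p = paths[i]
        dup = False
        for q in kept:
            d = np.linalg.norm(p[:, None, :] - q[None, :, :], axis=2).min(axis=1)
            if (d <= overlap_radius_um).mean() >= max_shared:
                dup = True
                break
        if not dup:
            kept.append(p)
    return kept


def _snap_base(
    poly: np.ndarray,
    base_ref: np.ndarray,
    base_capture_um: float,
    proximal_um: float = 3.0,
) -> np.ndarray:
    """Trim the proximal end to the path point nearest a reference centriole.

    The traced path runs through the true base but its extended end can
    overshoot where neighbouring filament halos keep the intensity high;
    when the path passes within the capture distance of a detected
    centriole, the closest pass becomes the base.
    """
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    prox = poly[arc <= proximal_um]
    if len(prox) < 2:
        return poly
    d = np.linalg.norm(prox[:, None, :] - base_ref[None, :, :], axis=2).min(axis=1)
    k = int(np.argmin(d))
    if d[k] <= base_capture_um and k > 0 and len(poly) - k >= 2:
        return poly[k:]
    return poly


def _extend_path(
    poly: np.ndarray,
    smoothed: np.ndarray,
    thr: float,
    spacing: np.ndarray,
    max_extension_um: float = 2.5,
    gap_um: float = 1.2,
) -> np.ndarray:
    """Extend a skeleton path at both ends while intensity stays above
    threshold, compensating the endpoint erosion of 3D thinning.

    Short sub-threshold dips (up to ``gap_um``) are crossed if the signal
    recovers beyond them, so a filament fragmented by a local intensity dip
    is re-joined to its continuation; a dip with no recovery is trimmed.
    """
    step = float(spacing.min()) / 2.0
    n_dir = min(4, len(poly) - 1)

    def grow(end: np.ndarray, inward: np.ndarray) -> list[np.ndarray]:
        direction = end - inward
        nrm = np.linalg.norm(direction)
        if nrm < 1e-9:
            return []
        direction /= nrm
        added: list[np.ndarray] = []
        below = 0
        max_below = int(gap_um / step)
        p = end.copy()
        for _ in range(int(max_extension_um / step)):
            q = p + step * direction
            vox = q / spacing
            if np.any(vox < 0) or np.any(vox > np.array(smoothed.shape) - 1):
                break
            val = ndimage.map_coordinates(
                smoothed, vox[:, None], order=1, mode="nearest"
            )[0]
            if val <= thr:
                below += 1
                if below > max_below:
                    break
            else:
                below = 0
            added.append(q)
            p = q
        if below:
            added = added[: len(added) - below]
        return added

    head = grow(poly[0], poly[n_dir])
    tail = grow(poly[-1], poly[-1 - n_dir])
    parts = [np.array(head[::-1])] if head else []
    parts.append(poly)
    if tail:
        parts.append(np.array(tail))
    return np.vstack(parts)


def _trace_component(
    coords: np.ndarray,
    spacing: np.ndarray,
    base_ref: np.ndarray,
    base_capture_um: float = 1.2,
) -> list[np.ndarray]:
    """Trace base→tip polylines through one skeleton component.

    Any skeleton voxel within ``base_capture_um`` of a reference point is a
    base node; endpoints (degree-1 voxels) farther than that are distal
    tips.  Each tip contributes one path to its nearest base node (shortest
    path in physical distance, via a zero-cost virtual source attached to
    all base nodes), so filaments that merge near their bases — or run
    tip-to-tip through a shared base region — are still split one path per
    tip.  Components with no endpoints (pure loops) are skipped.
    """
    index = {tuple(c): i for i, c in enumerate(coords)}
    rows, cols, dists = [], [], []
    for i, c in enumerate(coords):
        for off in _NEIGHBORS:
            j = index.get(tuple(c + off))
            if j is not None and j > i:
                d = float(np.linalg.norm(off * spacing))
                rows.append(i)
                cols.append(j)
                dists.append(d)
    n = len(coords)
    degree = np.bincount(rows + cols, minlength=n)
    endpoints = np.flatnonzero(degree == 1)
    if len(endpoints) == 0:
        return []
    pos_um = coords * spacing
    ref_dist = np.linalg.norm(
        pos_um[:, None, :] - base_ref[None, :, :], axis=2
    ).min(axis=1)
    base_nodes = np.flatnonzero(ref_dist <= base_capture_um)
    tips = endpoints[ref_dist[endpoints] > base_capture_um]
    if len(base_nodes) == 0:
        base_nodes = np.array([int(np.argmin(ref_dist))])
    if len(tips) == 0:
        # short filament eroded to within the capture zone: trace from the
        # endpoint farthest from the centrioles to the one nearest them
        if len(endpoints) < 2:
            return []
        order = np.argsort(ref_dist[endpoints])
        tips = endpoints[order[-1:]]
        base_nodes = endpoints[order[:1]]
        if tips[0] == base_nodes[0]:
            return []
    # virtual source (index n) wired to every base node at ~zero cost
    rows += [n] * len(base_nodes)
    cols += list(base_nodes)
    dists += [1e-9] * len(base_nodes)
    graph = coo_matrix((dists, (rows, cols)), shape=(n + 1, n + 1))
    dist, pred = shortest_path(
        graph, directed=False, indices=n, return_predecessors=True
    )
    paths = []
    for tip in tips:
        if not np.isfinite(dist[tip]):
            continue
        chain = [int(tip)]
        while pred[chain[-1]] != n and pred[chain[-1]] >= 0:
            chain.append(int(pred[chain[-1]]))
        paths.append(pos_um[chain[::-1]])  # base first
    return paths


def _smooth_polyline(poly: np.ndarray, window: int = 5) -> np.ndarray:
    """Moving-average smoothing that tames staircase length inflation.

    Endpoints are kept fixed so tip positions (and base positions, used for
    association) are not pulled inward.
    """
    if len(poly) <= window:
        return poly
    kernel = np.ones(window) / window
    sm = np.empty_like(poly)
    for d in range(poly.shape[1]):
        sm[:, d] = np.convolve(np.pad(poly[:, d], window // 2, mode="edge"), kernel, "valid")
    sm[0], sm[-1] = poly[0], poly[-1]
    return sm


def associate(
    spots: Sequence[Spot],
    cilia: Sequence[Cilium],
    capture_radius_um: float = 0.5,
    base_segment_um: float = 0.0,
) -> AssociationResult:
    """Match cilium bases to centrioles one-to-one within a capture radius.

    Minimises total base-to-spot distance over all one-to-one matchings whose
    pairs all lie within ``capture_radius_um`` (optimal assignment).  Ties
    are resolved toward lower spot id, then lower cilium id.

    With ``base_segment_um > 0`` the base-to-spot distance is measured from
    the spot to the nearest point on the cilium's proximal segment (the
    first ``base_segment_um`` of arc length) rather than to the base vertex
    alone; a traced path runs through its true base even when its endpoint
    over- or undershoots it.
    """
    n_s, n_c = len(spots), len(cilia)
    if n_s == 0 or n_c == 0:
        return AssociationResult(pairs=(), n_spots=n_s, n_cilia=n_c)
    spot_pos = np.array([s.position_um for s in spots])
    dist = np.empty((n_s, n_c))
    for j, c in enumerate(cilia):
        if base_segment_um > 0:
            seg = np.linalg.norm(np.diff(c.polyline_um, axis=0), axis=1)
            arc = np.concatenate([[0.0], np.cumsum(seg)])
            prox = c.polyline_um[arc <= base_segment_um]
        else:
            prox = c.polyline_um[:1]
        dist[:, j] = np.linalg.norm(
            spot_pos[:, None, :] - prox[None, :, :], axis=2
        ).min(axis=1)
    big = 1e6
    cost = np.where(dist <= capture_radius_um, dist, big)
    rows, cols = linear_sum_assignment(cost)
    pairs = tuple(
        (spots[i].id, cilia[j].id)
        for i, j in sorted(zip(rows, cols))
        if dist[i, j] <= capture_radius_um
    )
    return AssociationResult(pairs=pairs, n_spots=n_s, n_cilia=n_c)


# -- tabular round-trips -------------------------------------------------------

SPOT_COLUMNS = ["id", "z_um", "y_um", "x_um", "scale_um", "intensity", "roi_id"]


def spots_to_frame(spots: Sequence[Spot]) -> pd.DataFrame:
    rows = [
        {
            "id": s.id,
            "z_um": s.position_um[0],
            "y_um": s.position_um[1],
            "x_um": s.position_um[2],
            "scale_um": s.scale_um,
            "intensity": s.intensity,
            "roi_id": s.roi_id,
        }
        for s in spots
    ]
    return pd.DataFrame(rows, columns=SPOT_COLUMNS)


def frame_to_spots(df: pd.DataFrame) -> list[Spot]:
    return [
        Spot(
            id=int(r.id),
            position_um=(float(r.z_um), float(r.y_um), float(r.x_um)),
            scale_um=float(r.scale_um),
            intensity=float(r.intensity),
            roi_id=None if pd.isna(r.roi_id) else int(r.roi_id),
        )
        for r in df.itertuples()
    ]


def cilia_to_frame(cilia: Sequence[Cilium]) -> pd.DataFrame:
    rows = []
    for c in cilia:
        for k, (z, y, x) in enumerate(c.polyline_um):
            rows.append(
                {"id": c.id, "vertex": k, "z_um": z, "y_um": y, "x_um": x, "length_um": c.length_um}
            )
    return pd.DataFrame(rows, columns=["id", "vertex", "z_um", "y_um", "x_um", "length_um"])


def frame_to_cilia(df: pd.DataFrame) -> list[Cilium]:
    cilia = []
    for cid, sub in df.groupby("id", sort=True):
        sub = sub.sort_values("vertex")
        poly = sub[["z_um", "y_um", "x_um"]].to_numpy(dtype=float)
        cilia.append(Cilium(id=int(cid), polyline_um=poly, length_um=polyline_length(poly)))
    return cilia
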