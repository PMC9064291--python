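"""Synthetic microscopy scenes with known ground truth.

Three generators emulate the data regimes the pipeline analyses:

* :func:`generate_knob_scene` — a dendritic knob bearing tens of
  diffraction-limited centriole puncta, a subset of which anchor filamentous
  cilia, imaged as a two-channel 3D confocal stack (expanded-gel scale).
* :func:`generate_timelapse` — a 4D movie of tight centriole clusters whose
  centroids drift apically or basally at ≤0.2 µm/min beside a static
  fiducial cluster.
* :func:`generate_count_table` — paired drug/control centriole-group count
  tables across animals, timepoints and epithelial compartments, with a
  configurable per-compartment drug enrichment.

All randomness flows from the seed in the scene configuration; identical
configurations produce byte-identical images and truth.  Puncta are rendered
as anisotropic 3D Gaussians (the PSF approximation), cilia as tubes of
Gaussian cross-section along quadratic Bézier curves, and noise as Poisson
shot noise on signal-plus-background with additive Gaussian read noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .compartments import COMPARTMENTS, GroupCountRecord
from .grouping import CentrioleGroup
from .io import VoxelGrid, polyline_length


@dataclass
class SceneConfig:
    """Physical and optical parameters of a simulated scene.

    All geometry is expressed in the expanded-gel frame (the frame images
    are acquired in after ~4-fold physical expansion of the specimen).

    Parameters
    ----------
    image_shape
        Voxels per axis (z, y, x); each at least 8.
    voxel_spacing_um
        µm per voxel (z, y, x); default z = 0.27 µm, xy = 0.11 µm.
    expansion_factor
        Scale applied to the pre-expansion PSF widths (default 4.0).
    psf_sigma_um
        Pre-expansion Gaussian PSF sigma per axis (z, y, x); the rendered
        sigma is ``psf_sigma_um * expansion_factor``.
    snr
        Peak signal over background noise s.d.; ``None`` or ``inf`` disables
        noise entirely (the image equals the noiseless render plus the
        constant background).
    background_level
        Mean background intensity (photons).
    read_noise_sigma
        Additive Gaussian read-noise s.d.
    seed
        Mandatory RNG seed; no global state is touched.
    """

    seed: int
    image_shape: tuple[int, int, int] = (68, 224, 224)
    voxel_spacing_um: tuple[float, float, float] = (0.27, 0.11, 0.11)
    expansion_factor: float = 4.0
    psf_sigma_um: tuple[float, float, float] = (0.35, 0.15, 0.15)
    snr: float | None = 10.0
    background_level: float = 100.0
    read_noise_sigma: float = 2.0
    apical_axis: str = "-z"

    def __post_init__(self) -> None:
        self.image_shape = tuple(int(n) for n in self.image_shape)
        if len(self.image_shape) != 3 or any(n < 8 for n in self.image_shape):
            raise ValueError("image_shape must be 3 axes of >= 8 voxels")
        self.voxel_spacing_um = tuple(float(s) for s in self.voxel_spacing_um)
        self.psf_sigma_um = tuple(float(s) for s in self.psf_sigma_um)
        if any(s <= 0 for s in self.voxel_spacing_um + self.psf_sigma_um):
            raise ValueError("spacings and PSF sigmas must be strictly positive")
        if self.expansion_factor <= 0:
            raise ValueError("expansion_factor must be strictly positive")
        if self.snr is not None and not math.isinf(self.snr) and self.snr <= 0:
            raise ValueError("snr must be strictly positive (or None/inf for noiseless)")
        if self.background_level < 0 or self.read_noise_sigma < 0:
            raise ValueError("background and read noise must be non-negative")

    @property
    def noiseless(self) -> bool:
        return self.snr is None or math.isinf(self.snr)

    @property
    def rendered_sigma_um(self) -> np.ndarray:
        """Effective PSF sigma in the acquisition frame, (z, y, x) µm."""
        return np.asarray(self.psf_sigma_um) * self.expansion_factor

    @property
    def extent_um(self) -> np.ndarray:
        return (np.asarray(self.image_shape) - 1) * np.asarray(self.voxel_spacing_um)

    @property
    def peak_signal(self) -> float:
        """Peak punctum intensity implied by the configured SNR."""
        noise_sd = math.sqrt(self.background_level + self.read_noise_sigma**2)
        if self.noiseless:
            return 100.0
        return self.snr * max(noise_sd, 1.0)


@dataclass
class GroundTruth:
    """True values of every estimand in a generated scene."""

    spot_positions_um: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    group_membership: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))
    cilium_curves: list[np.ndarray] = field(default_factory=list)
    cilium_to_spot: dict[int, int] = field(default_factory=dict)
    track_positions_um: np.ndarray | None = None  # (n_groups+1, n_frames, 3)
    track_velocities_um_per_min: np.ndarray | None = None
    fiducial_index: int | None = None
    frame_interval_min: float | None = None
    compartment_labels: list[str] = field(default_factory=list)
    count_table: list[GroupCountRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        gm = np.asarray(self.group_membership, dtype=int)
        labels = np.unique(gm[gm >= 0])
        if labels.size and not np.array_equal(labels, np.arange(labels.size)):
            raise ValueError("group membership indices must be contiguous from 0 (or -1)")

    @property
    def n_spots(self) -> int:
        return len(self.spot_positions_um)

    @property
    def n_cilia(self) -> int:
        return len(self.cilium_curves)

    @property
    def association_fraction(self) -> float:
        return len(self.cilium_to_spot) / self.n_spots if self.n_spots else 0.0


# -- rendering primitives ------------------------------------------------------


def _splat(clean: np.ndarray, positions_um: np.ndarray, masses: np.ndarray,
           spacing: np.ndarray) -> None:
    """Deposit point masses with trilinear weights (centroid-exact)."""
    if len(positions_um) == 0:
        return
    vox = positions_um / spacing
    base = np.floor(vox).astype(int)
    frac = vox - base
    for corner in range(8):
        off = np.array([(corner >> 2) & 1, (corner >> 1) & 1, corner & 1])
        w = np.prod(np.where(off, frac, 1.0 - frac), axis=1)
        idx = base + off
        ok = np.all((idx >= 0) & (idx < clean.shape), axis=1)
        np.add.at(clean, tuple(idx[ok].T), masses[ok] * w[ok])


def render_scene(
    config: SceneConfig,
    spot_positions_um: np.ndarray,
    cilium_polylines: Sequence[np.ndarray] = (),
    rng: np.random.Generator | None = None,
    cilium_peak_fraction: float = 0.8,
) -> VoxelGrid:
    """Render puncta and cilia into a noisy two-channel stack.

    Channel ``centrin`` holds the puncta, channel ``cilia`` the filaments.
    Each punctum is a unit-mass delta blurred by the effective PSF and scaled
    so its peak equals the configured peak signal; each cilium is a dense
    chain of deltas along its polyline, blurred identically.
    """
    spacing = np.asarray(config.voxel_spacing_um)
    sigma_um = config.rendered_sigma_um
    sigma_vox = sigma_um / spacing
    # peak of a unit impulse after discrete Gaussian blur
    impulse_peak = float(np.prod(1.0 / (math.sqrt(2 * math.pi) * sigma_vox)))
    peak = config.peak_signal

    spots_clean = np.zeros(config.image_shape, dtype=np.float64)
    pos = np.asarray(spot_positions_um, dtype=float).reshape(-1, 3)
    _splat(spots_clean, pos, np.full(len(pos), peak / impulse_peak), spacing)
    spots_clean = ndimage.gaussian_filter(spots_clean, sigma_vox, mode="constant")

    cilia_clean = np.zeros(config.image_shape, dtype=np.float64)
    step = float(spacing.min()) / 2.0
    # a blurred line of linear density rho has peak rho / (2 pi s_perp) with
    # s_perp^2 = det(Sigma) u' Sigma^-1 u for shaft direction u; choosing rho
    # per cilium gives every tube the same peak regardless of orientation
    det_sigma = float(np.prod(sigma_um**2))
    inv_var = 1.0 / sigma_um**2
    for poly in cilium_polylines:
        poly = np.asarray(poly, dtype=float)
        u = poly[-1] - poly[0]
        u /= max(np.linalg.norm(u), 1e-9)
        s_perp = math.sqrt(math.sqrt(det_sigma * float(u**2 @ inv_var)))
        rho = cilium_peak_fraction * peak * 2 * math.pi * s_perp**2
        dense = _resample_polyline(poly, step)
        # convert volume density to voxel mass: blur kernel is normalised per
        # voxel, so divide by voxel volume
        mass = np.full(len(dense), rho * step / float(np.prod(spacing)))
        _splat(cilia_clean, dense, mass, spacing)
    cilia_clean = ndimage.gaussian_filter(cilia_clean, sigma_vox, mode="constant")

    channels = np.stack([spots_clean, cilia_clean])[np.newaxis]  # (1, 2, z, y, x)
    data = _apply_noise(channels, config, rng)
    return VoxelGrid(
        data,
        spacing_um=config.voxel_spacing_um,
        channel_names=("centrin", "cilia"),
        apical_axis=config.apical_axis,
    )


def _apply_noise(
    clean: np.ndarray, config: SceneConfig, rng: np.random.Generator | None
) -> np.ndarray:
    signal = clean + config.background_level
    if config.noiseless:
        return signal.astype(np.float32)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    noisy = rng.poisson(signal).astype(np.float32)
    if config.read_noise_sigma > 0:
        noisy += rng.normal(0.0, config.read_noise_sigma, size=noisy.shape).astype(
            np.float32
        )
    return noisy


def _resample_polyline(poly: np.ndarray, step: float) -> np.ndarray:
    seg = np.diff(poly, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    n = max(2, int(np.ceil(cum[-1] / step)) + 1)
    arc = np.linspace(0.0, cum[-1], n)
    return np.column_stack([np.interp(arc, cum, poly[:, d]) for d in range(poly.shape[1])])


# -- knob scene ----------------------------------------------------------------


def _normalized_min_dist(p: np.ndarray, others: list[np.ndarray], sigma: np.ndarray) -> float:
    """Min pairwise distance in PSF-sigma-normalised coordinates."""
    if not others:
        return np.inf
    diff = (np.array(others) - p) / sigma
    return float(np.linalg.norm(diff, axis=1).min())


def _sample_points_min_dist(
    rng: np.random.Generator,
    n: int,
    proposal,
    sigma_um: np.ndarray,
    crowding: float,
    max_tries: int = 200_000,
) -> np.ndarray:
    """Random sequential placement with an anisotropic exclusion zone.

    Candidates from ``proposal(rng)`` are accepted when their distance to all
    placed points, measured in units of the per-axis PSF sigma, is at least
    ``crowding``.  This keeps nearest neighbours resolvable regardless of
    their orientation relative to the elongated axial PSF.
    """
    pts: list[np.ndarray] = []
    for _ in range(max_tries):
        if len(pts) == n:
            break
        p = proposal(rng)
        if _normalized_min_dist(p, pts, sigma_um) >= crowding:
            pts.append(p)
    if len(pts) < n:
        raise RuntimeError(
            f"could not place {n} points at crowding {crowding} sigma"
        )
    return np.array(pts).reshape(n, 3)


def _farthest_point_subset(points: np.ndarray, k: int) -> np.ndarray:
    """Indices of k points chosen by farthest-point sampling (max spread)."""
    n = len(points)
    if k >= n:
        return np.arange(n)
    chosen = [int(np.argmin(points[:, 0]))]  # start from the most apical point
    d = np.linalg.norm(points - points[chosen[0]], axis=1)
    for _ in range(k - 1):
        nxt = int(np.argmax(d))
        chosen.append(nxt)
        d = np.minimum(d, np.linalg.norm(points - points[nxt], axis=1))
    return np.array(sorted(chosen))


def _bezier(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, n: int = 50) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n)[:, None]
    return (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t**2 * p2


def generate_knob_scene(
    config: SceneConfig,
    n_centrioles: int = 36,
    n_cilia: int = 31,
    knob_radius_um: float = 7.0,
    dome_height_um: float = 2.4,
    crowding_sigma: float = 2.6,
    cilium_length_range_um: tuple[float, float] = (4.0, 7.0),
    cilium_curvature_um: float = 0.5,
    fan_spread: float = 0.75,
    cilium_separation_sigma: float = 3.4,
) -> tuple[VoxelGrid, GroundTruth]:
    """Simulate a dendritic knob with docked centrioles and attached cilia.

    Centrioles are placed on the apical docking surface of the knob — a
    gently curved paraboloid dome of lateral radius ``knob_radius_um`` and
    height ``dome_height_um`` — emulating basal bodies docked at the knob
    membrane.  Their pairwise spacing, measured in units of the per-axis
    effective PSF sigma, is at least ``crowding_sigma`` (configurable
    crowding; the default keeps nearest neighbours optically resolvable
    despite the elongated axial PSF).  Cilia anchor at a maximally spread
    subset of the centrioles and extend along the local surface normal,
    biased apically, as gently curved Bézier tubes.

    Raises
    ------
    ValueError
        If ``n_cilia > n_centrioles`` or counts are negative.
    """
    if n_cilia > n_centrioles:
        raise ValueError(f"n_cilia ({n_cilia}) cannot exceed n_centrioles ({n_centrioles})")
    if n_centrioles < 0 or n_cilia < 0:
        raise ValueError("counts must be non-negative")
    rng = np.random.default_rng(config.seed)
    extent = config.extent_um
    apex = np.array([0.52 * extent[0], 0.5 * extent[1], 0.5 * extent[2]])
    slope = 2.0 * dome_height_um / knob_radius_um**2  # d(depth)/d(r) prefactor

    def propose_dome(r: np.random.Generator) -> np.ndarray:
        rad = knob_radius_um * math.sqrt(r.random())  # area-uniform on the dome
        phi = r.uniform(0.0, 2 * math.pi)
        dy, dx = rad * math.sin(phi), rad * math.cos(phi)
        dz = dome_height_um * (rad / knob_radius_um) ** 2
        return apex + np.array([dz, dy, dx])

    if n_centrioles:
        spots = _sample_points_min_dist(
            rng, n_centrioles, propose_dome, config.rendered_sigma_um, crowding_sigma
        )
    else:
        spots = np.zeros((0, 3))

    curves: list[np.ndarray] = []
    cilium_to_spot: dict[int, int] = {}
    if n_cilia:
        apical = np.array([-1.0, 0.0, 0.0])  # decreasing z
        sigma = config.rendered_sigma_um

        def try_anchor(si: int, n_attempts: int):
            """Best separable curve anchored at spot si, or the best found."""
            base = spots[si]
            # cone fan: lateral tilt grows with radial position (up to
            # ``fan_spread`` per unit climb), so every cilium climbs apically
            # while neighbours diverge both radially and azimuthally
            lat = base[1:] - apex[1:]
            r = np.linalg.norm(lat)
            u_lat = lat / r if r > 1e-9 else np.zeros(2)
            tilt = fan_spread * r / knob_radius_um
            nominal = np.array([-1.0, tilt * u_lat[0], tilt * u_lat[1]])
            nominal /= np.linalg.norm(nominal)
            best_curve, best_sep = None, -np.inf
            for attempt in range(n_attempts):
                direction = nominal
                if attempt:  # jitter the shaft direction to avoid neighbours
                    direction = nominal + rng.normal(0.0, 0.05 * attempt, 3)
                    direction /= np.linalg.norm(direction)
                length = rng.uniform(*cilium_length_range_um)
                # all cilia bow the same way (apical component orthogonal to
                # the shaft) so neighbours curve in parallel, not across
                perp = apical - (apical @ direction) * direction
                perp /= max(np.linalg.norm(perp), 1e-9)
                ctrl = base + 0.5 * length * direction + rng.uniform(
                    0.0, cilium_curvature_um
                ) * perp
                curve = _bezier(base, ctrl, base + length * direction)
                curve = _truncate_to_bounds(curve, extent)
                if len(curve) < 2:
                    continue
                sep = _min_curve_separation(curve, curves, sigma)
                if sep > best_sep:
                    best_curve, best_sep = curve, sep
                if sep >= cilium_separation_sigma:
                    break
            return best_curve, best_sep

        anchors = list(_farthest_point_subset(spots, n_cilia))
        free = [i for i in range(len(spots)) if i not in set(anchors)]
        deferred: list[tuple[int, np.ndarray, float]] = []
        placed: list[tuple[int, np.ndarray]] = []
        for si in anchors:
            curve, sep = try_anchor(int(si), 40)
            if curve is not None and sep >= cilium_separation_sigma:
                placed.append((int(si), curve))
                curves.append(curve)
            else:
                deferred.append((int(si), curve, sep))
        # anchors that could not separate try the spots left unciliated
        for si, curve, sep in deferred:
            best_si, best_curve, best_sep = si, curve, sep
            for alt in free:
                c2, s2 = try_anchor(int(alt), 25)
                if c2 is not None and s2 > best_sep:
                    best_si, best_curve, best_sep = int(alt), c2, s2
                if best_sep >= cilium_separation_sigma:
                    break
            if best_curve is not None:
                placed.append((best_si, best_curve))
                curves.append(best_curve)
                if best_si in free:
                    free.remove(best_si)
                    free.append(si)
        curves = []
        for ci, (si, curve) in enumerate(placed):
            curves.append(curve)
            cilium_to_spot[ci] = si

    grid = render_scene(config, spots, curves, rng=rng)
    truth = GroundTruth(
        spot_positions_um=spots,
        group_membership=np.zeros(len(spots), dtype=int) if len(spots) else np.zeros(0, int),
        cilium_curves=curves,
        cilium_to_spot=cilium_to_spot,
    )
    return grid, truth


def _distal(curve: np.ndarray, skip_um: float) -> np.ndarray:
    seg = np.linalg.norm(np.diff(curve, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    out = curve[arc > skip_um]
    return out if len(out) else curve[-1:]


def _min_curve_separation(
    curve: np.ndarray,
    others: Sequence[np.ndarray],
    sigma_um: np.ndarray,
    skip_um: float = 1.5,
) -> float:
    """Min distance (in PSF-sigma units) from a curve to other curves.

    The proximal ``skip_um`` of each curve is ignored: filaments may share
    a crowded base region (the path tracer splits those), but their shafts
    must stay resolvable.
    """
    if not others:
        return np.inf
    a = _distal(curve, skip_um) / sigma_um
    best = np.inf
    for other in others:
        b = _distal(other, skip_um) / sigma_um
        d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2).min()
        best = min(best, float(d))
    return best


def _truncate_to_bounds(curve: np.ndarray, extent: np.ndarray) -> np.ndarray:
    inside = np.all((curve >= 0) & (curve <= extent), axis=1)
    if inside.all():
        return curve
    first_out = int(np.argmin(inside))
    return curve[:max(first_out, 2)] if first_out else curve[:0]


# -- time-lapse ----------------------------------------------------------------


def generate_timelapse(
    config: SceneConfig,
    n_groups: int,
    velocities_um_per_min: Sequence[float],
    n_frames: int,
    frame_interval_min: float,
    positional_noise_um: float = 0.0,
    puncta_per_group: tuple[int, int] = (3, 12),
    cluster_sigma_um: float = 0.4,
    max_velocity_um_per_min: float = 1.0,
    min_cluster_separation_um: float = 4.0,
    render: bool = True,
) -> tuple[VoxelGrid | None, GroundTruth]:
    """Simulate a 4D movie of migrating centriole-group clusters.

    Each group is a tight cluster of puncta whose centroid moves along the
    apical axis at its assigned signed velocity (µm/min, apical positive)
    with i.i.d. Gaussian positional jitter per frame.  A static fiducial
    cluster (index ``n_groups`` in the truth) is always included.  Ground
    truth records the per-frame rendered centroid of every cluster.

    Set ``render=False`` to skip image synthesis and obtain truth only.
    """
    velocities = np.asarray(list(velocities_um_per_min), dtype=float)
    if len(velocities) != n_groups:
        raise ValueError(
            f"{len(velocities)} velocities supplied for {n_groups} groups"
        )
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    if np.any(np.abs(velocities) > max_velocity_um_per_min):
        raise ValueError(
            f"velocities exceed the sanity bound {max_velocity_um_per_min} µm/min"
        )
    rng = np.random.default_rng(config.seed)
    extent = config.extent_um
    spacing = np.asarray(config.voxel_spacing_um)
    total_min = (n_frames - 1) * frame_interval_min
    apical_sign = -1 if config.apical_axis == "-z" else 1

    n_clusters = n_groups + 1  # fiducial last
    all_vel = np.concatenate([velocities, [0.0]])
    margin = float(min(3.0, extent.min() / 4.0))
    starts = np.empty((n_clusters, 3))
    minutes = np.arange(n_frames) * frame_interval_min
    for i, v in enumerate(all_vel):
        # keep the whole trajectory inside the volume
        travel = apical_sign * v * total_min  # z displacement
        z_lo = margin + max(0.0, -min(travel, 0.0))
        z_hi = extent[0] - margin - max(travel, 0.0)
        if z_hi <= z_lo:
            raise ValueError("volume too small for the requested trajectory")
        # distinct groups migrate in distinct dendrites: reject starts whose
        # trajectory ever comes close to an already-placed cluster's
        for attempt in range(2000):
            cand = np.array(
                [
                    rng.uniform(z_lo, z_hi),
                    rng.uniform(margin, extent[1] - margin),
                    rng.uniform(margin, extent[2] - margin),
                ]
            )
            ok = True
            for j in range(i):
                dz = (cand[0] - starts[j, 0]) + apical_sign * (v - all_vel[j]) * minutes
                dist = np.sqrt(dz**2 + np.sum((cand[1:] - starts[j, 1:]) ** 2))
                if dist.min() < min_cluster_separation_um:
                    ok = False
                    break
            if ok:
                starts[i] = cand
                break
        else:
            raise RuntimeError(
                "could not place separated cluster trajectories; enlarge the "
                "volume or lower min_cluster_separation_um"
            )
    sizes = rng.integers(puncta_per_group[0], puncta_per_group[1] + 1, size=n_clusters)
    offsets = [rng.normal(0.0, cluster_sigma_um, size=(s, 3)) for s in sizes]
    offsets = [o - o.mean(axis=0) for o in offsets]  # centroid exactly at cluster centre

    track_positions = np.empty((n_clusters, n_frames, 3))
    frames_data = []
    for t in range(n_frames):
        minutes = t * frame_interval_min
        frame_spots = []
        for i in range(n_clusters):
            centre = starts[i].copy()
            centre[0] += apical_sign * all_vel[i] * minutes
            if positional_noise_um > 0:
                centre = centre + rng.normal(0.0, positional_noise_um, size=3)
            track_positions[i, t] = centre
            frame_spots.append(centre + offsets[i])
        if render:
            clean = np.zeros(config.image_shape, dtype=np.float64)
            sigma_vox = config.rendered_sigma_um / spacing
            impulse_peak = float(np.prod(1.0 / (math.sqrt(2 * math.pi) * sigma_vox)))
            pos = np.vstack(frame_spots)
            _splat(clean, pos, np.full(len(pos), config.peak_signal / impulse_peak), spacing)
            clean = ndimage.gaussian_filter(clean, sigma_vox, mode="constant")
            frames_data.append(clean[np.newaxis])  # one channel

    truth = GroundTruth(
        spot_positions_um=np.zeros((0, 3)),
        track_positions_um=track_positions,
        track_velocities_um_per_min=all_vel,
        fiducial_index=n_groups,
        frame_interval_min=frame_interval_min,
    )
    if not render:
        return None, truth
    movie = _apply_noise(np.stack(frames_data), config, rng)
    grid = VoxelGrid(
        movie,
        spacing_um=config.voxel_spacing_um,
        channel_names=("centrin",),
        apical_axis=config.apical_axis,
    )
    return grid, truth


def groups_from_truth(truth: GroundTruth) -> list[list[CentrioleGroup]]:
    """Per-frame CentrioleGroup lists from time-lapse ground truth.

    Cluster ids are stable across frames (the fiducial keeps
    ``truth.fiducial_index``), matching what a per-frame detection +
    clustering stage would hand to the tracker.
    """
    if truth.track_positions_um is None:
        raise ValueError("truth carries no time-lapse positions")
    n_clusters, n_frames, _ = truth.track_positions_um.shape
    per_frame = []
    for t in range(n_frames):
        frame = [
            CentrioleGroup(
                id=i,
                member_ids=(),
                centroid_um=tuple(truth.track_positions_um[i, t]),
                extent_um=0.0,
                size=1,
            )
            for i in range(n_clusters)
        ]
        per_frame.append(frame)
    return per_frame


# -- count tables --------------------------------------------------------------


def generate_count_table(
    n_animals: int = 2,
    timepoints: Sequence[str] = ("1hr", "6hr"),
    compartments: Sequence[str] = COMPARTMENTS,
    base_density_per_100um: float = 2.9,
    drug_multiplier_by_compartment: Mapping | None = None,
    length_um_range: tuple[float, float] = (900.0, 1150.0),
    seed: int = 0,
) -> list[GroupCountRecord]:
    """Simulate a paired drug/control centriole-group count table.

    For every animal × timepoint × compartment a control and a drug record
    are emitted.  Counts are Poisson with mean
    ``density × length/100 × multiplier`` where the multiplier is 1 for the
    control arm and the configured per-compartment (or per
    compartment-and-timepoint) enrichment for the drug arm.  The default
    density (2.9 groups per 100 µm) matches densities observed in explanted
    olfactory epithelium; section lengths are drawn uniformly from
    ``length_um_range``.
    """
    if n_animals < 1:
        raise ValueError("need at least one animal")
    timepoints = list(timepoints)
    compartments = list(compartments)
    if not timepoints or not compartments:
        raise ValueError("timepoints and compartments must be non-empty")
    if base_density_per_100um <= 0:
        raise ValueError("base density must be positive")
    lo, hi = length_um_range
    if not 0 < lo <= hi:
        raise ValueError("invalid length range")
    multipliers = dict(drug_multiplier_by_compartment or {})
    if any(m <= 0 for m in multipliers.values()):
        raise ValueError("drug multipliers must be positive")

    rng = np.random.default_rng(seed)
    records: list[GroupCountRecord] = []
    for a in range(n_animals):
        for tp in timepoints:
            for comp in compartments:
                mult = multipliers.get((comp, tp), multipliers.get(comp, 1.0))
                for condition, m in (("control", 1.0), ("drug", mult)):
                    length = float(rng.uniform(lo, hi))
                    mean = base_density_per_100um * length / 100.0 * m
                    count = int(rng.poisson(mean))
                    records.append(
                        GroupCountRecord(
                            animal_id=f"A{a + 1}",
                            condition=condition,
                            timepoint=tp,
                            compartment=comp,
                            count=count,
                            basal_length_um=length,
                        )
                    )
    return records


def synthetic_annotation(
    lateral_span_um: float = 100.0,
    apical_depth_um: float = 0.0,
    sustentacular_depth_um: float = 20.0,
    basal_depth_um: float = 60.0,
):
    """A flat three-boundary epithelium annotation (testing convenience)."""
    from .io import EpitheliumAnnotation

    xs = [0.0, lateral_span_um]
    return EpitheliumAnnotation(
        apical_surface=np.array([[apical_depth_um, x] for x in xs]),
        sustentacular_lower_boundary=np.array([[sustentacular_depth_um, x] for x in xs]),
        basal_lamina=np.array([[basal_depth_um, x] for x in xs]),
    )
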