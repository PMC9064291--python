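"""Time-lapse tracking of centriole groups and kymograph construction.

Groups detected per frame are linked across time by greedy nearest-neighbour
matching (closest pair first) inside a gating radius, with short gaps
bridged.  A static fiducial — a nearby mature neuron's docked centrioles —
can be named; its per-frame position is subtracted from every position so
common drift cancels before rates are computed.

The primary migration rate follows the field's scoring convention: the
difference between the first and last observed positions divided by elapsed
time.  A least-squares regression rate over all observations is reported
alongside as a robustness check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .grouping import CentrioleGroup
from .io import VoxelGrid


class FiducialError(ValueError):
    """Raised when the named fiducial is missing from too many frames."""


class GeometryError(ValueError):
    """Raised when a sampling line leaves the image bounds."""


@dataclass
class GroupTrack:
    """A time-indexed sequence of fiducial-corrected group positions.

    Positions are coordinates along the apical axis with apical positive,
    so a positive net displacement means apical-ward migration.
    """

    track_id: int
    frames: tuple[int, ...]
    positions_um: tuple[float, ...]
    elapsed_min: float
    direction: str = field(default="none")

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.frames, self.frames[1:])):
            raise ValueError("frames must be strictly increasing")
        if len(self.frames) != len(self.positions_um):
            raise ValueError("frames and positions length mismatch")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def net_displacement_um(self) -> float:
        return self.positions_um[-1] - self.positions_um[0]

    @property
    def rate_um_per_min(self) -> float:
        if self.elapsed_min <= 0:
            raise ValueError("elapsed time must be positive for a rate")
        return self.net_displacement_um / self.elapsed_min

    def regression_rate_um_per_min(self, frame_interval_min: float) -> float:
        """Least-squares slope over all observations (secondary estimate)."""
        t = np.asarray(self.frames, dtype=float) * frame_interval_min
        return float(np.polyfit(t, np.asarray(self.positions_um), 1)[0])


@dataclass
class Kymograph:
    """Intensity along a sampling line (columns) versus time (rows)."""

    data: np.ndarray  # (n_frames, n_arc_samples)
    line_um: np.ndarray
    width_um: float
    pixel_size_um: float


def project_side_view(movie: VoxelGrid, axis: str = "x") -> VoxelGrid:
    """Maximum-intensity projection along a lateral axis, per frame/channel.

    Projecting along the apical (z) axis is refused: it would destroy the
    coordinate that migration is measured on.  The projected axis is kept as
    a singleton so the result remains a (t, c, z, y, x) grid.
    """
    if axis == "z":
        raise ValueError("cannot project along the apical axis (z)")
    if axis not in ("y", "x"):
        raise ValueError(f"axis must be 'y' or 'x', got {axis!r}")
    ax = {"y": 3, "x": 4}[axis]
    proj = movie.data.max(axis=ax, keepdims=True)
    return VoxelGrid(
        proj,
        spacing_um=movie.spacing_um,
        channel_names=movie.channel_names,
        apical_axis=movie.apical_axis,
    )


def _apical_position(centroid: Sequence[float], apical_sign: int) -> float:
    """Signed apical-axis coordinate (apical positive) of a 3D centroid."""
    return apical_sign * float(centroid[0])


def link_tracks(
    per_frame_groups: Sequence[Sequence[CentrioleGroup]],
    gating_radius_um: float = 3.0,
    fiducial_id: int | None = None,
    frame_interval_min: float = 1.0,
    max_gap: int = 2,
    apical_sign: int = -1,
    displacement_threshold_um: float = 0.5,
) -> list[GroupTrack]:
    """Link per-frame centriole groups into tracks and estimate rates.

    Parameters
    ----------
    per_frame_groups
        One list of :class:`CentrioleGroup` per frame (ids are per-frame).
    gating_radius_um
        Maximum 3D frame-to-frame jump accepted by the linker.
    fiducial_id
        Group id of the static fiducial cluster; if given, the fiducial's
        per-frame position is subtracted from all positions (drift
        correction) and the fiducial's own track is dropped from the output.
        Missing from more than half the frames → :class:`FiducialError`.
    apical_sign
        -1 (default) when apical is toward decreasing z.
    """
    if len(per_frame_groups) < 2:
        raise ValueError("need at least 2 frames to link tracks")
    if gating_radius_um <= 0:
        raise ValueError("gating radius must be positive")

    n_frames = len(per_frame_groups)
    fid_pos: np.ndarray | None = None
    if fiducial_id is not None:
        raw = []
        for frame in per_frame_groups:
            match = [g for g in frame if g.id == fiducial_id]
            raw.append(np.asarray(match[0].centroid_um, float) if match else None)
        missing = sum(p is None for p in raw)
        if missing > n_frames / 2:
            raise FiducialError(
                f"fiducial {fiducial_id} missing in {missing}/{n_frames} frames"
            )
        # interpolate missing fiducial frames from neighbours
        known = [i for i, p in enumerate(raw) if p is not None]
        stack = np.array([raw[i] for i in known], dtype=float)
        fid_pos = np.empty((n_frames, stack.shape[1]))
        for d in range(stack.shape[1]):
            fid_pos[:, d] = np.interp(np.arange(n_frames), known, stack[:, d])

    # active track state: list of dicts with frames, raw 3D positions
    active: list[dict] = []
    done: list[dict] = []
    for t, frame_groups in enumerate(per_frame_groups):
        groups = [
            g for g in frame_groups if fiducial_id is None or g.id != fiducial_id
        ]
        centroids = [np.asarray(g.centroid_um, dtype=float) for g in groups]
        # candidate links: (distance, track index, group index), greedy closest first
        cands = []
        for ti, tr in enumerate(active):
            for gi, c in enumerate(centroids):
                d = float(np.linalg.norm(c - tr["last_pos"]))
                if d <= gating_radius_um:
                    cands.append((d, ti, gi))
        cands.sort(key=lambda x: x[0])
        used_t: set[int] = set()
        used_g: set[int] = set()
        for d, ti, gi in cands:
            if ti in used_t or gi in used_g:
                continue
            used_t.add(ti)
            used_g.add(gi)
            tr = active[ti]
            tr["frames"].append(t)
            tr["pos"].append(centroids[gi])
            tr["last_pos"] = centroids[gi]
        for gi, c in enumerate(centroids):
            if gi not in used_g:
                active.append({"frames": [t], "pos": [c], "last_pos": c})
        still = []
        for tr in active:
            if t - tr["frames"][-1] > max_gap:
                done.append(tr)
            else:
                still.append(tr)
        active = still
    done.extend(active)
    done = [tr for tr in done if len(tr["frames"]) >= 2]
    done.sort(key=lambda tr: (tr["frames"][0], _apical_position(tr["pos"][0], apical_sign)))

    tracks = []
    for tid, tr in enumerate(done):
        frames = tuple(tr["frames"])
        positions = []
        for f, p in zip(frames, tr["pos"]):
            corrected = p - (fid_pos[f] if fid_pos is not None else 0.0)
            positions.append(_apical_position(corrected, apical_sign))
        elapsed = (frames[-1] - frames[0]) * frame_interval_min
        track = GroupTrack(
            track_id=tid,
            frames=frames,
            positions_um=tuple(positions),
            elapsed_min=elapsed,
        )
        track.direction = classify_direction(track, displacement_threshold_um)
        tracks.append(track)
    return tracks


def classify_direction(
    track: GroupTrack, displacement_threshold_um: float = 0.5
) -> str:
    """'apical', 'basal' or 'none' from the track's net displacement.

    Apical if net displacement exceeds +threshold, basal below -threshold,
    otherwise no net movement.
    """
    if track.n_frames < 2:
        raise ValueError("direction needs at least 2 observations")
    d = track.net_displacement_um
    if d > displacement_threshold_um:
        return "apical"
    if d < -displacement_threshold_um:
        return "basal"
    return "none"


def build_kymograph(
    movie: VoxelGrid,
    line_um: np.ndarray,
    width_um: float = 1.0,
    channel: int | str = 0,
    pixel_size_um: float | None = None,
) -> Kymograph:
    """Sample intensity along a line over time (bilinear interpolation).

    ``movie`` must be a side-view projection (singleton lateral axis); the
    line is given in the 2D (z, y) frame in µm.  Intensity is averaged over
    ``width_um`` perpendicular to the line at every arc position.
    """
    data = movie.data
    ci = movie.channel_index(channel)
    if data.shape[4] == 1:
        frames = data[:, ci, :, :, 0]
        sp = (movie.spacing_um[0], movie.spacing_um[1])
    elif data.shape[3] == 1:
        frames = data[:, ci, :, 0, :]
        sp = (movie.spacing_um[0], movie.spacing_um[2])
    else:
        raise ValueError("kymograph needs a side-view projection (one lateral axis singleton)")
    line = np.asarray(line_um, dtype=float)
    if line.ndim != 2 or line.shape[0] < 2 or line.shape[1] != 2:
        raise ValueError("line must be an (n>=2, 2) polyline in (z, y) µm")
    extent = ((frames.shape[1] - 1) * sp[0], (frames.shape[2] - 1) * sp[1])
    if (line < -1e-9).any() or (line[:, 0] > extent[0] + 1e-9).any() or (
        line[:, 1] > extent[1] + 1e-9
    ).any():
        raise GeometryError("sampling line exits the image bounds")

    if pixel_size_um is None:
        pixel_size_um = float(min(sp))
    # resample line at uniform arc steps
    seg = np.diff(line, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    n_arc = max(2, int(np.floor(cum[-1] / pixel_size_um)) + 1)
    arc = np.linspace(0.0, cum[-1], n_arc)
    pts = np.column_stack(
        [np.interp(arc, cum, line[:, d]) for d in range(2)]
    )
    # unit tangents and normals along the resampled line
    tang = np.gradient(pts, axis=0)
    tang /= np.maximum(np.linalg.norm(tang, axis=1, keepdims=True), 1e-12)
    normal = np.column_stack([-tang[:, 1], tang[:, 0]])
    n_off = max(1, int(np.round(width_um / pixel_size_um)) + 1)
    offsets = np.linspace(-width_um / 2, width_um / 2, n_off)

    rows = np.empty((frames.shape[0], n_arc), dtype=float)
    spacing = np.asarray(sp)
    for t in range(frames.shape[0]):
        acc = np.zeros(n_arc)
        for off in offsets:
            sample_um = pts + off * normal
            coords = (sample_um / spacing).T  # (2, n_arc) in voxel units
            acc += ndimage.map_coordinates(
                frames[t].astype(float), coords, order=1, mode="nearest"
            )
        rows[t] = acc / len(offsets)
    return Kymograph(
        data=rows, line_um=line, width_um=width_um, pixel_size_um=float(arc[1] - arc[0])
    )


def kymograph_ridge_slope(kymo: Kymograph, frame_interval_min: float) -> float:
    """Velocity (µm/min) of the brightest ridge, from per-row maxima.

    Fits a line to the arc position of each row's intensity maximum; the
    slope is the ridge velocity along the sampling line.
    """
    pos = kymo.data.argmax(axis=1) * kymo.pixel_size_um
    t = np.arange(kymo.data.shape[0]) * frame_interval_min
    return float(np.polyfit(t, pos, 1)[0])


TRACK_COLUMNS = [
    "track_id",
    "n_frames",
    "first_frame",
    "last_frame",
    "net_displacement_um",
    "elapsed_min",
    "rate_um_per_min",
    "regression_rate_um_per_min",
    "direction",
]


def tracks_to_frame(
    tracks: Sequence[GroupTrack], frame_interval_min: float = 1.0
) -> pd.DataFrame:
    rows = [
        {
            "track_id": tr.track_id,
            "n_frames": tr.n_frames,
            "first_frame": tr.frames[0],
            "last_frame": tr.frames[-1],
            "net_displacement_um": tr.net_displacement_um,
            "elapsed_min": tr.elapsed_min,
            "rate_um_per_min": tr.rate_um_per_min,
            "regression_rate_um_per_min": tr.regression_rate_um_per_min(frame_interval_min),
            "direction": tr.direction,
        }
        for tr in tracks
    ]
    return pd.DataFrame(rows, columns=TRACK_COLUMNS)
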