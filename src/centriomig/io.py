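"""Image and annotation I/O with physical calibration.

All image data travel through :class:`VoxelGrid`, a 5D intensity array with
axes ordered ``(t, c, z, y, x)`` and per-axis physical spacing in micrometres.
Physical coordinates follow the voxel-centre convention: the centre of voxel
``i`` along an axis with spacing ``s`` sits at ``i * s`` µm.  "Apical" is the
direction of decreasing ``z`` unless overridden.

Side-view tissue landmarks (apical surface, lower boundary of the
sustentacular nuclei, basal lamina) are carried by
:class:`EpitheliumAnnotation` in a 2D frame whose first coordinate is
apico-basal depth (increasing basally) and second is lateral position, both
in µm.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger("centriomig")

#: Default spacing used when a file carries no calibration, (z, y, x) µm.
DEFAULT_SPACING_UM = (0.27, 0.11, 0.11)


class FormatError(ValueError):
    """Raised when a file's axes or metadata cannot be interpreted."""


class AnnotationError(ValueError):
    """Raised when tissue landmark polylines violate their ordering contract."""


@dataclass
class VoxelGrid:
    """Multi-channel, optionally time-indexed intensity volume.

    Parameters
    ----------
    data
        Array with axes ``(t, c, z, y, x)``; singleton axes are allowed.
        Lower-dimensional arrays are promoted on construction: 3D input is
        treated as a single-channel, single-timepoint ``(z, y, x)`` volume
        and 4D input as ``(c, z, y, x)``.
    spacing_um
        Physical voxel spacing ``(z, y, x)`` in µm; strictly positive.
    channel_names
        One label per channel.
    apical_axis
        ``"-z"`` (default) means apical lies toward decreasing z; ``"+z"``
        toward increasing z.
    """

    data: np.ndarray
    spacing_um: tuple[float, float, float] = DEFAULT_SPACING_UM
    channel_names: tuple[str, ...] = ()
    apical_axis: str = "-z"

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim == 3:
            arr = arr[np.newaxis, np.newaxis]
        elif arr.ndim == 4:
            arr = arr[np.newaxis]
        if arr.ndim != 5:
            raise ValueError(
                f"expected 3D, 4D or 5D data, got {np.asarray(self.data).ndim}D"
            )
        self.data = arr
        self.spacing_um = tuple(float(s) for s in self.spacing_um)
        if len(self.spacing_um) != 3 or any(s <= 0 for s in self.spacing_um):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing_um}")
        if not self.channel_names:
            self.channel_names = tuple(f"ch{i}" for i in range(arr.shape[1]))
        else:
            self.channel_names = tuple(self.channel_names)
        if len(self.channel_names) != arr.shape[1]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {arr.shape[1]} channels"
            )
        if self.apical_axis not in ("-z", "+z"):
            raise ValueError(f"apical_axis must be '-z' or '+z', got {self.apical_axis!r}")

    # -- convenience accessors -------------------------------------------------

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.data.shape[2:]

    @property
    def extent_um(self) -> tuple[float, float, float]:
        """Physical extent (z, y, x) in µm spanned by voxel centres."""
        return tuple((n - 1) * s for n, s in zip(self.shape_zyx, self.spacing_um))

    @property
    def apical_sign(self) -> int:
        """+1 if apical is toward increasing z, -1 otherwise."""
        return 1 if self.apical_axis == "+z" else -1

    def channel_index(self, channel: int | str) -> int:
        if isinstance(channel, (int, np.integer)):
            if not 0 <= channel < self.n_channels:
                raise ValueError(f"channel index {channel} out of range")
            return int(channel)
        try:
            return self.channel_names.index(channel)
        except ValueError:
            raise ValueError(
                f"channel {channel!r} not in {list(self.channel_names)}"
            ) from None

    def volume(self, channel: int | str = 0, t: int = 0) -> np.ndarray:
        """Return the (z, y, x) volume for one channel at one timepoint."""
        return self.data[t, self.channel_index(channel)]


def write_stack(path: str | Path, grid: VoxelGrid) -> None:
    """Write a VoxelGrid as an ImageJ-hyperstack TIFF (TZCYX plane order).

    Calibration and channel names are embedded in the ImageJ metadata so
    :func:`read_stack` round-trips them exactly.
    """
    path = Path(path)
    dz, dy, dx = grid.spacing_um
    data = np.ascontiguousarray(np.moveaxis(grid.data, 1, 2))  # TCZYX -> TZCYX
    if data.dtype not in (np.uint8, np.uint16, np.float32):
        data = data.astype(np.float32)
    info = json.dumps(
        {
            "channel_names": list(grid.channel_names),
            "spacing_um": list(grid.spacing_um),
            "apical_axis": grid.apical_axis,
        }
    )
    tifffile.imwrite(
        path,
        data,
        imagej=True,
        resolution=(1.0 / dx, 1.0 / dy),
        metadata={"axes": "TZCYX", "spacing": dz, "unit": "um", "Info": info},
    )


def read_stack(path: str | Path, default_spacing_um: Sequence[float] = DEFAULT_SPACING_UM) -> VoxelGrid:
    """Read a TIFF stack into a VoxelGrid.

    Axis metadata (ImageJ or OME) is honoured when present; plain 2D/3D TIFFs
    are promoted to singleton time/channel axes.  Missing spacing metadata
    falls back to ``default_spacing_um`` with a logged warning.

    Raises
    ------
    OSError
        If the file is missing or truncated.
    FormatError
        If the axis string contains axes this pipeline cannot place.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tf:
            series = tf.series[0]
            data = series.asarray()
            axes = series.axes.upper()
            ij = tf.imagej_metadata or {}
            tags = tf.pages[0].tags
            xres = tags.get("XResolution")
            yres = tags.get("YResolution")
    except (tifffile.TiffFileError, ValueError) as exc:
        raise OSError(f"cannot read TIFF {path}: {exc}") from exc

    if axes.endswith("S"):  # trailing samples-per-pixel = channels
        axes = axes[:-1] + "C"
    known = "TCZYX"
    # plain stacks come back with generic axis labels; map them to the first
    # missing structural axis (depth first, then channel, then time)
    for generic in ("Q", "I", "S"):
        while generic in axes:
            for target in "ZCT":
                if target not in axes:
                    axes = axes.replace(generic, target, 1)
                    break
            else:
                break
    if any(a not in known for a in axes):
        bad = [a for a in axes if a not in known]
        raise FormatError(f"unsupported axis {bad} in TIFF axes {axes!r} of {path}")
    if len(axes) != data.ndim:
        raise FormatError(f"axis string {axes!r} does not match {data.ndim}D data")
    # insert singleton axes and reorder to TCZYX
    for i, a in enumerate(known):
        if a not in axes:
            axes = axes[:i] + a + axes[i:]
            data = np.expand_dims(data, i)
    data = np.moveaxis(data, [axes.index(a) for a in known], range(5))

    if ij.get("images") and int(np.prod(data.shape[:3])) != int(ij["images"]):
        raise OSError(
            f"truncated TIFF {path}: expected {ij['images']} planes, "
            f"read {int(np.prod(data.shape[:3]))}"
        )

    spacing = None
    channel_names: tuple[str, ...] = ()
    apical_axis = "-z"
    info = ij.get("Info")
    if info:
        try:
            meta = json.loads(info)
            spacing = tuple(meta["spacing_um"])
            channel_names = tuple(meta.get("channel_names", ()))
            apical_axis = meta.get("apical_axis", "-z")
        except (json.JSONDecodeError, KeyError, TypeError):
            pass
    if spacing is None and "spacing" in ij:
        dz = float(ij["spacing"])
        dx = xres.value[1] / xres.value[0] if xres and xres.value[0] else None
        dy = yres.value[1] / yres.value[0] if yres and yres.value[0] else None
        if dx and dy:
            spacing = (dz, dy, dx)
    if spacing is None:
        logger.warning(
            "no spacing metadata in %s; falling back to %s µm", path, default_spacing_um
        )
        spacing = tuple(default_spacing_um)
    return VoxelGrid(data, spacing_um=spacing, channel_names=channel_names, apical_axis=apical_axis)


# -- polyline helpers ----------------------------------------------------------


def polyline_length(vertices: np.ndarray) -> float:
    """Arc length of a polyline given as an (n, d) vertex array."""
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[0] < 2:
        raise ValueError("polyline needs at least 2 vertices")
    return float(np.linalg.norm(np.diff(v, axis=0), axis=1).sum())


def _depth_at(polyline: np.ndarray, lateral: np.ndarray) -> np.ndarray:
    """Interpolated apico-basal depth of a (depth, lateral) polyline.

    The polyline is treated as a function of the lateral coordinate; vertices
    are sorted by lateral position before interpolation.
    """
    v = np.asarray(polyline, dtype=float)
    order = np.argsort(v[:, 1])
    return np.interp(lateral, v[order, 1], v[order, 0])


@dataclass
class EpitheliumAnnotation:
    """Landmark polylines defining epithelial compartments in a side view.

    Each polyline is an (n, 2) array of (depth_um, lateral_um) vertices with
    depth increasing basally (apical surface at small depth).  At every
    lateral position covered by all three, the apical surface must lie apical
    of the sustentacular lower boundary, which must lie apical of the basal
    lamina.  ``basal_length_um`` is the arc length of the basal lamina — the
    normalisation denominator for group counts.
    """

    apical_surface: np.ndarray
    sustentacular_lower_boundary: np.ndarray
    basal_lamina: np.ndarray
    basal_length_um: float = field(init=False)

    def __post_init__(self) -> None:
        self.apical_surface = np.asarray(self.apical_surface, dtype=float)
        self.sustentacular_lower_boundary = np.asarray(
            self.sustentacular_lower_boundary, dtype=float
        )
        self.basal_lamina = np.asarray(self.basal_lamina, dtype=float)
        for name in ("apical_surface", "sustentacular_lower_boundary", "basal_lamina"):
            poly = getattr(self, name)
            if poly.ndim != 2 or poly.shape[0] < 2 or poly.shape[1] != 2:
                raise AnnotationError(f"{name} must be an (n>=2, 2) polyline")
        self.basal_length_um = polyline_length(self.basal_lamina)
        self._validate_ordering()

    @property
    def lateral_span(self) -> tuple[float, float]:
        """Lateral interval covered by all three polylines."""
        lo = max(p[:, 1].min() for p in self._polylines())
        hi = min(p[:, 1].max() for p in self._polylines())
        return float(lo), float(hi)

    def _polylines(self):
        return (self.apical_surface, self.sustentacular_lower_boundary, self.basal_lamina)

    def _validate_ordering(self, n_samples: int = 512) -> None:
        lo, hi = self.lateral_span
        if hi <= lo:
            raise AnnotationError("polylines share no lateral interval")
        xs = np.linspace(lo, hi, n_samples)
        a = _depth_at(self.apical_surface, xs)
        s = _depth_at(self.sustentacular_lower_boundary, xs)
        b = _depth_at(self.basal_lamina, xs)
        bad = (a > s) | (s > b)
        if bad.any():
            xb = xs[bad]
            raise AnnotationError(
                "landmark ordering violated (apical above sustentacular above basal) "
                f"over lateral interval [{xb.min():.3f}, {xb.max():.3f}] µm"
            )

    def depths_at(self, lateral: float) -> tuple[float, float, float]:
        """(apical, sustentacular, basal) depths at one lateral coordinate."""
        lo, hi = self.lateral_span
        if not lo <= lateral <= hi:
            raise AnnotationError(
                f"lateral coordinate {lateral:.3f} outside annotated span [{lo:.3f}, {hi:.3f}]"
            )
        x = np.asarray([lateral], dtype=float)
        return (
            float(_depth_at(self.apical_surface, x)[0]),
            float(_depth_at(self.sustentacular_lower_boundary, x)[0]),
            float(_depth_at(self.basal_lamina, x)[0]),
        )


_ANNOTATION_KEYS = {
    "apical_surface",
    "sustentacular_lower_boundary",
    "basal_lamina",
}


def load_annotation(path: str | Path) -> EpitheliumAnnotation:
    """Load landmark polylines from JSON or CSV.

    JSON: ``{"apical_surface": [[depth, lateral], ...], ...}``.
    CSV: columns ``landmark, depth_um, lateral_um``.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            raw = json.load(fh)
        missing = _ANNOTATION_KEYS - raw.keys()
        if missing:
            raise AnnotationError(f"annotation {path} missing polylines: {sorted(missing)}")
        return EpitheliumAnnotation(
            apical_surface=np.asarray(raw["apical_surface"], dtype=float),
            sustentacular_lower_boundary=np.asarray(
                raw["sustentacular_lower_boundary"], dtype=float
            ),
            basal_lamina=np.asarray(raw["basal_lamina"], dtype=float),
        )
    df = pd.read_csv(path)
    required = {"landmark", "depth_um", "lateral_um"}
    if not required <= set(df.columns):
        raise AnnotationError(f"annotation CSV needs columns {sorted(required)}")
    polys = {}
    for name, sub in df.groupby("landmark", sort=False):
        polys[name] = sub[["depth_um", "lateral_um"]].to_numpy(dtype=float)
    missing = _ANNOTATION_KEYS - polys.keys()
    if missing:
        raise AnnotationError(f"annotation {path} missing polylines: {sorted(missing)}")
    return EpitheliumAnnotation(
        apical_surface=polys["apical_surface"],
        sustentacular_lower_boundary=polys["sustentacular_lower_boundary"],
        basal_lamina=polys["basal_lamina"],
    )


def save_annotation(path: str | Path, annotation: EpitheliumAnnotation) -> None:
    """Write an annotation as JSON (inverse of :func:`load_annotation`)."""
    payload = {
        "apical_surface": annotation.apical_surface.tolist(),
        "sustentacular_lower_boundary": annotation.sustentacular_lower_boundary.tolist(),
        "basal_lamina": annotation.basal_lamina.tolist(),
        "basal_length_um": annotation.basal_length_um,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def configure_logging(verbose: bool = False, quiet: bool = False) -> None:
    """Structured logging to stderr shared by all CLI stages."""
    level = logging.DEBUG if verbose else logging.ERROR if quiet else logging.INFO
    logging.basicConfig(
        level=level, format="%(asctime)s %(name)s %(levelname)s %(message)s"
    )
    logger.setLevel(level)
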