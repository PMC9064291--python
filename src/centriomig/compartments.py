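"""Epithelial compartment scoring and length-normalised densities.

The olfactory epithelium is divided, in a side view, into a subapical
compartment (between the apical surface and the bottom of the sustentacular
cell nuclei) and a middle/basal compartment (between that boundary and the
basal lamina).  Centriole-group counts per compartment are normalised to the
lateral arc length of the basal lamina and reported per 100 µm, which makes
counts comparable across sections of different sizes — the same convention
used for EdU-positive nuclei densities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .grouping import CentrioleGroup
from .io import AnnotationError, EpitheliumAnnotation

SUBAPICAL = "subapical"
MIDDLE_BASAL = "middle_basal"
OUTSIDE = "outside"
COMPARTMENTS = (SUBAPICAL, MIDDLE_BASAL)


@dataclass(frozen=True)
class GroupCountRecord:
    """One row of the animal × condition × timepoint × compartment table."""

    animal_id: str
    condition: str  # "drug" or "control"
    timepoint: str
    compartment: str
    count: int
    basal_length_um: float
    normalized_per_100um: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("count must be non-negative")
        if self.basal_length_um <= 0:
            raise ValueError("basal length must be positive")
        expected = 100.0 * self.count / self.basal_length_um
        if self.normalized_per_100um is None:
            object.__setattr__(self, "normalized_per_100um", expected)
        elif abs(self.normalized_per_100um - expected) > 1e-9:
            raise ValueError(
                f"normalized_per_100um {self.normalized_per_100um} inconsistent "
                f"with count {self.count} over {self.basal_length_um} µm"
            )


def classify_compartment(
    position_um: Sequence[float], annotation: EpitheliumAnnotation
) -> str:
    """Compartment of a side-view point ``(depth_um, lateral_um)``.

    Depth boundaries are linearly interpolated between polyline vertices at
    the point's lateral coordinate.  Intervals are closed on their apical
    boundary: a point exactly on the sustentacular boundary is subapical, a
    point on the basal lamina is middle/basal.  Points apical of the apical
    surface or basal of the basal lamina are ``outside``.

    Raises
    ------
    AnnotationError
        If the lateral coordinate lies outside the annotated span.
    """
    depth, lateral = float(position_um[0]), float(position_um[1])
    apical, sustentacular, basal = annotation.depths_at(lateral)
    if apical <= depth <= sustentacular:
        return SUBAPICAL
    if sustentacular < depth <= basal:
        return MIDDLE_BASAL
    return OUTSIDE


def tabulate_counts(
    groups: Iterable[CentrioleGroup | Sequence[float]],
    annotation: EpitheliumAnnotation,
    animal_id: str,
    condition: str,
    timepoint: str,
) -> tuple[list[GroupCountRecord], int]:
    """Count groups per compartment, normalised per 100 µm of basal lamina.

    ``groups`` may be :class:`CentrioleGroup` objects whose centroids are
    side-view ``(depth, lateral)`` coordinates, or bare 2D points.  Returns
    one record per compartment plus the number of groups falling outside
    both compartments.
    """
    tallies = {c: 0 for c in COMPARTMENTS}
    outside = 0
    for g in groups:
        pos = g.centroid_um if isinstance(g, CentrioleGroup) else g
        label = classify_compartment(pos, annotation)
        if label == OUTSIDE:
            outside += 1
        else:
            tallies[label] += 1
    records = [
        GroupCountRecord(
            animal_id=animal_id,
            condition=condition,
            timepoint=timepoint,
            compartment=c,
            count=tallies[c],
            basal_length_um=annotation.basal_length_um,
        )
        for c in COMPARTMENTS
    ]
    return records, outside


def linear_density(n_objects: int, basal_length_um: float) -> float:
    """Objects per 100 µm of basal-lamina length, rounded to 2 decimals.

    Used for EdU-positive nuclei and any other per-length tally.
    """
    if basal_length_um <= 0:
        raise ValueError("basal length must be positive")
    if n_objects < 0:
        raise ValueError("count must be non-negative")
    return round(100.0 * n_objects / basal_length_um, 2)


COUNT_COLUMNS = [
    "animal_id",
    "condition",
    "timepoint",
    "compartment",
    "count",
    "basal_length_um",
    "normalized_per_100um",
]


def records_to_frame(records: Sequence[GroupCountRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "animal_id": r.animal_id,
                "condition": r.condition,
                "timepoint": r.timepoint,
                "compartment": r.compartment,
                "count": r.count,
                "basal_length_um": r.basal_length_um,
                "normalized_per_100um": r.normalized_per_100um,
            }
            for r in records
        ],
        columns=COUNT_COLUMNS,
    )


def frame_to_records(df: pd.DataFrame) -> list[GroupCountRecord]:
    """Parse a count table (e.g. a published per-animal source-data CSV).

    Requires columns ``animal_id, condition, timepoint, compartment, count,
    basal_length_um``; ``normalized_per_100um`` is recomputed if absent.
    """
    required = set(COUNT_COLUMNS) - {"normalized_per_100um"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"count table missing columns {sorted(missing)}")
    records = []
    for r in df.itertuples():
        records.append(
            GroupCountRecord(
                animal_id=str(r.animal_id),
                condition=str(r.condition),
                timepoint=str(r.timepoint),
                compartment=str(r.compartment),
                count=int(r.count),
                basal_length_um=float(r.basal_length_um),
            )
        )
    return records


def detect_edu_nuclei(
    image,
    dapi_channel,
    edu_channel,
    nucleus_sigma_um: float = 2.0,
    t: int = 0,
):
    """EdU-positive nuclei: DAPI blobs gated by mean EdU intensity.

    Nuclei are detected as coarse-scale blobs in the DAPI channel; a nucleus
    is EdU-positive when the mean EdU intensity in a nucleus-sized ball
    around its centre exceeds an Otsu threshold of the EdU channel.  Returns
    the list of positive nucleus positions (µm).  The gate is configurable
    only through the Otsu statistic here; manual curation can be layered on
    via the detection module's review table.
    """
    from skimage.filters import threshold_otsu

    from .detection import detect_spots

    nuclei = detect_spots(
        image,
        channel=dapi_channel,
        scale_range_um=(nucleus_sigma_um * 0.7, nucleus_sigma_um * 1.4),
        n_scales=3,
        axial_factor=1.0,  # nuclei are roughly isotropic
        t=t,
    )
    edu = image.volume(edu_channel, t).astype(float)
    spacing = np.asarray(image.spacing_um)
    thr = float(threshold_otsu(edu))
    positive = []
    half = np.maximum(1, np.round(nucleus_sigma_um / spacing)).astype(int)
    for nuc in nuclei:
        vox = np.round(np.asarray(nuc.position_um) / spacing).astype(int)
        lo = np.maximum(0, vox - half)
        hi = np.minimum(edu.shape, vox + half + 1)
        patch = edu[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
        if patch.size and patch.mean() > thr:
            positive.append(nuc.position_um)
    return positive
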