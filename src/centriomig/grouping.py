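"""Clustering of centrioles into migrating groups; lag behind the dendrite tip.

Migrating centrioles travel in tight clusters ("groups") separated by several
µm along the dendrite, with occasional centrioles travelling singly between
groups.  Groups are recovered by single-linkage clustering at a physical
cutoff: two centrioles belong to the same cluster whenever a chain of
pairwise distances ≤ cutoff connects them.  Clusters below a minimum size are
reported as singletons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .detection import Spot


@dataclass(frozen=True)
class CentrioleGroup:
    """A cluster of ≥2 centrioles with centroid and spatial extent."""

    id: int
    member_ids: tuple[int, ...]
    centroid_um: tuple[float, ...]
    extent_um: float  # max pairwise member distance
    size: int


@dataclass(frozen=True)
class LagMeasurement:
    """Arc distance from a group centroid to the dendrite's apical tip."""

    group_id: int
    tip_um: tuple[float, ...]
    lag_um: float


class GeometryError(ValueError):
    """Raised when a point cannot be projected onto a reference polyline."""


def cluster_groups(
    spots: Sequence[Spot],
    linkage_cutoff_um: float = 2.0,
    min_group_size: int = 2,
) -> tuple[list[CentrioleGroup], list[int]]:
    """Partition spots into centriole groups and singletons.

    Single-linkage clustering at ``linkage_cutoff_um``; clusters with at
    least ``min_group_size`` members become groups (ordered apically, i.e.
    by ascending z centroid, with ids 0..k-1), smaller clusters' spots are
    returned as singleton spot ids.
    """
    if linkage_cutoff_um <= 0:
        raise ValueError("linkage cutoff must be positive")
    if not spots:
        return [], []
    pos = np.array([s.position_um for s in spots], dtype=float)
    if len(spots) == 1:
        labels = np.array([1])
    else:
        z = linkage(pdist(pos), method="single")
        labels = fcluster(z, t=linkage_cutoff_um, criterion="distance")

    groups: list[CentrioleGroup] = []
    singletons: list[int] = []
    for lbl in np.unique(labels):
        idx = np.flatnonzero(labels == lbl)
        if len(idx) < min_group_size:
            singletons.extend(spots[i].id for i in idx)
            continue
        members = pos[idx]
        extent = float(pdist(members).max()) if len(idx) > 1 else 0.0
        groups.append(
            CentrioleGroup(
                id=-1,
                member_ids=tuple(sorted(spots[i].id for i in idx)),
                centroid_um=tuple(members.mean(axis=0)),
                extent_um=extent,
                size=len(idx),
            )
        )
    groups.sort(key=lambda g: g.centroid_um[0])  # apical (low z) first
    groups = [
        CentrioleGroup(i, g.member_ids, g.centroid_um, g.extent_um, g.size)
        for i, g in enumerate(groups)
    ]
    singletons.sort()
    return groups, singletons


def _project_to_polyline(
    point: np.ndarray, path: np.ndarray
) -> tuple[float, float]:
    """(distance to polyline, arc position of the closest point).

    Arc position is measured from the first vertex of ``path``.
    """
    seg_start = path[:-1]
    seg_vec = path[1:] - seg_start
    seg_len = np.linalg.norm(seg_vec, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.einsum("ij,ij->i", point - seg_start, seg_vec) / seg_len**2
    t = np.clip(np.nan_to_num(t), 0.0, 1.0)
    closest = seg_start + t[:, None] * seg_vec
    d = np.linalg.norm(point - closest, axis=1)
    k = int(np.argmin(d))
    return float(d[k]), float(cum[k] + t[k] * seg_len[k])


def measure_lag(
    group: CentrioleGroup,
    dendrite_path_um: np.ndarray,
    projection_tolerance_um: float = 2.0,
) -> LagMeasurement:
    """Lag of a group behind the dendrite tip, along the dendrite path.

    ``dendrite_path_um`` is an (n, 3) polyline ordered base → apical tip.
    The group centroid is orthogonally projected onto the path; the lag is
    the arc distance from that projection to the apical endpoint.

    Raises
    ------
    GeometryError
        If the centroid lies farther than ``projection_tolerance_um`` from
        the path.
    """
    path = np.asarray(dendrite_path_um, dtype=float)
    if path.ndim != 2 or path.shape[0] < 2:
        raise ValueError("dendrite path needs at least 2 vertices")
    centroid = np.asarray(group.centroid_um, dtype=float)
    dist, arc = _project_to_polyline(centroid, path)
    if dist > projection_tolerance_um:
        raise GeometryError(
            f"group centroid {dist:.2f} µm from dendrite path "
            f"(tolerance {projection_tolerance_um} µm)"
        )
    total = float(np.linalg.norm(np.diff(path, axis=0), axis=1).sum())
    return LagMeasurement(
        group_id=group.id, tip_um=tuple(path[-1]), lag_um=total - arc
    )


def groups_to_frame(
    groups: Sequence[CentrioleGroup], singletons: Sequence[int] = ()
) -> pd.DataFrame:
    """groups.csv layout; singleton spots are listed with group_id -1."""
    rows = [
        {
            "group_id": g.id,
            "size": g.size,
            "centroid_z_um": g.centroid_um[0],
            "centroid_y_um": g.centroid_um[1] if len(g.centroid_um) > 1 else np.nan,
            "centroid_x_um": g.centroid_um[2] if len(g.centroid_um) > 2 else np.nan,
            "extent_um": g.extent_um,
            "member_ids": ";".join(map(str, g.member_ids)),
        }
        for g in groups
    ]
    for sid in singletons:
        rows.append(
            {
                "group_id": -1,
                "size": 1,
                "centroid_z_um": np.nan,
                "centroid_y_um": np.nan,
                "centroid_x_um": np.nan,
                "extent_um": 0.0,
                "member_ids": str(sid),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "group_id",
            "size",
            "centroid_z_um",
            "centroid_y_um",
            "centroid_x_um",
            "extent_um",
            "member_ids",
        ],
    )
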