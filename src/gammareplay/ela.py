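"""Probabilistic electrode-to-atlas labeling (ELA).

Each electrode is represented by a voxel "cloud" on the 1-mm label
lattice: depth contacts (bipolar midpoints) get a cigar-shaped capsule —
a cylinder of length L with hemispherical caps, diameter D — oriented
along the lead; grid contacts get a sphere of diameter D intersected
with the cortical-surface voxel mask. The probability that the
electrode sees a given region is the fraction of cloud voxels falling
inside that region's voxels. If the cloud intersects no label, its
geometry is grown by a fixed expansion step and the intersection is
retried (bounded); the region with the highest probability wins, ties
broken by smaller distance between the electrode and the centroid of
the intersecting voxels, then lexicographically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthdata import LabelVolume

logger = logging.getLogger("gammareplay")

MAX_EXPANSIONS = 50


@dataclass
class CloudGeometry:
    """Cloud shape parameters in mm; defaults per electrode kind."""

    kind: str  # "depth_cigar" | "grid_disk"
    length: float = 4.0  # cylinder length (depth only)
    diameter: float = 3.0
    step_length: float = 1.0
    step_diameter: float = 0.5

    def __post_init__(self) -> None:
        if self.kind not in ("depth_cigar", "grid_disk"):
            raise ValueError(f"unknown cloud kind {self.kind!r}")
        if self.diameter <= 0 or (self.kind == "depth_cigar" and self.length <= 0):
            raise ValueError("cloud dimensions must be positive")

    @classmethod
    def depth(cls) -> "CloudGeometry":
        return cls("depth_cigar", length=4.0, diameter=3.0,
                   step_length=1.0, step_diameter=0.5)

    @classmethod
    def grid(cls) -> "CloudGeometry":
        return cls("grid_disk", length=0.0, diameter=3.0,
                   step_length=0.0, step_diameter=0.5)

    def expanded(self, n: int) -> "CloudGeometry":
        return CloudGeometry(
            self.kind,
            self.length + n * self.step_length,
            self.diameter + n * self.step_diameter,
            self.step_length,
            self.step_diameter,
        )


@dataclass
class LabelProbability:
    label: str
    probability: float
    expansions_used: int


def electrode_cloud(
    center: np.ndarray,
    axis: np.ndarray | None,
    geom: CloudGeometry,
    volume: LabelVolume,
) -> np.ndarray:
    """Voxel indices (k x 3 int array) of the electrode cloud.

    Membership is by voxel-center inclusion. For the capsule, a voxel
    belongs iff its center lies within ``diameter/2`` of the axial
    segment of length ``length`` centered on ``center``. For the grid
    disk, iff it lies within the sphere AND is a surface voxel.
    """
    center = np.asarray(center, dtype=float)
    r = geom.diameter / 2.0
    if geom.kind == "depth_cigar":
        if axis is None:
            raise ValueError("depth cigar cloud requires a lead axis")
        axis = np.asarray(axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        half = geom.length / 2.0
        p0 = center - half * axis
        p1 = center + half * axis
        reach = half + r
    else:
        p0 = p1 = center
        reach = r
        if volume.surface is None:
            raise ValueError("grid disk cloud requires a surface voxel mask")

    lo_w = np.minimum(p0, p1) - reach - 1.0
    hi_w = np.maximum(p0, p1) + reach + 1.0
    lo = np.maximum(volume.world_to_voxel(lo_w), 0)
    hi = np.minimum(volume.world_to_voxel(hi_w), np.array(volume.shape) - 1)
    if np.any(lo > hi):
        raise ValueError("electrode cloud lies entirely outside the label volume")

    ii, jj, kk = np.meshgrid(
        np.arange(lo[0], hi[0] + 1),
        np.arange(lo[1], hi[1] + 1),
        np.arange(lo[2], hi[2] + 1),
        indexing="ij",
    )
    idx = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    pts = volume.voxel_to_world(idx)

    if geom.kind == "depth_cigar":
        # distance from each voxel center to the axial segment p0-p1
        seg = p1 - p0
        seg_len2 = float(seg @ seg)
        if seg_len2 == 0:
            dist = np.linalg.norm(pts - p0, axis=1)
        else:
            t = np.clip((pts - p0) @ seg / seg_len2, 0.0, 1.0)
            proj = p0 + t[:, None] * seg
            dist = np.linalg.norm(pts - proj, axis=1)
        inside = dist <= r
    else:
        inside = np.linalg.norm(pts - center, axis=1) <= r
        surf = volume.surface[idx[:, 0], idx[:, 1], idx[:, 2]]
        inside &= surf
    return idx[inside]


def label_electrode(
    center: np.ndarray,
    axis: np.ndarray | None,
    geom: CloudGeometry,
    volume: LabelVolume,
) -> tuple[str, list[LabelProbability]]:
    """Assign a region to one electrode, expanding the cloud as needed.

    Returns ``(winning_label, [LabelProbability...])``. Probability is
    intersecting voxels / cloud voxels per region. If no region
    intersects, the geometry grows by its expansion step (up to
    ``MAX_EXPANSIONS`` times) before giving up.
    """
    center = np.asarray(center, dtype=float)
    for n_exp in range(MAX_EXPANSIONS + 1):
        cloud = electrode_cloud(center, axis, geom.expanded(n_exp), volume)
        if cloud.shape[0] == 0:
            continue
        labs = volume.labels[cloud[:, 0], cloud[:, 1], cloud[:, 2]]
        hit = labs > 0
        if not hit.any():
            continue
        n_cloud = cloud.shape[0]
        probs = []
        best = None
        for lab_id in np.unique(labs[hit]):
            sel = labs == lab_id
            p = float(sel.sum()) / n_cloud
            name = volume.names[int(lab_id)]
            centroid = volume.voxel_to_world(cloud[sel]).mean(axis=0)
            d = float(np.linalg.norm(centroid - center))
            probs.append(LabelProbability(name, p, n_exp))
            key = (-p, d, name)
            if best is None or key < best[0]:
                best = (key, name)
        probs.sort(key=lambda lp: -lp.probability)
        return best[1], probs
    raise ValueError(f"unlabelable electrode at {center} after {MAX_EXPANSIONS} expansions")


def _lead_axes(channels: pd.DataFrame) -> dict:
    """Unit lead direction per lead id from the contact coordinates."""
    axes = {}
    for lead, grp in channels.groupby("lead", sort=False):
        grp = grp.sort_values("contact")
        xyz = grp[["x", "y", "z"]].to_numpy(dtype=float)
        if len(xyz) >= 2:
            v = xyz[-1] - xyz[0]
        else:
            v = np.array([1.0, 0.0, 0.0])
        n = np.linalg.norm(v)
        axes[lead] = v / n if n > 0 else np.array([1.0, 0.0, 0.0])
    return axes


def label_channels(
    channels: pd.DataFrame,
    volume: LabelVolume,
    geom_depth: CloudGeometry | None = None,
    geom_grid: CloudGeometry | None = None,
) -> pd.DataFrame:
    """Label every channel in the table; returns a copy with ``label``,
    ``label_probability`` and ``expansions`` columns filled."""
    geom_depth = geom_depth or CloudGeometry.depth()
    geom_grid = geom_grid or CloudGeometry.grid()
    axes = _lead_axes(channels)
    out = channels.reset_index(drop=True).copy()
    labels, probs, exps = [], [], []
    for _, row in out.iterrows():
        center = np.array([row["x"], row["y"], row["z"]])
        if row["kind"] == "depth":
            win, lp = label_electrode(center, axes[row["lead"]], geom_depth, volume)
        else:
            win, lp = label_electrode(center, None, geom_grid, volume)
        top = next(p for p in lp if p.label == win)
        labels.append(win)
        probs.append(top.probability)
        exps.append(top.expansions_used)
    out["label"] = labels
    out["label_probability"] = probs
    out["expansions"] = exps
    return out
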