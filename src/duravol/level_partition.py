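"""Clipping planes through intervertebral disc spaces and the resulting
partition of the dural sac into level segments L3..S1.

A segment is bounded by an upper (cranial) and a lower (caudal) plane.
Membership is half-open — a dural voxel belongs to the most caudal plane
it lies on or below, so no voxel is counted twice and the four segments
exactly cover the dural voxels between the outermost planes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volumes import LabelVolume

__all__ = ["Plane", "LevelPartition", "fit_clipping_planes", "partition_dural_sac", "VERTEBRAE"]

VERTEBRAE = ("L3", "L4", "L5", "S1")
_SEGMENTS = ("L3", "L4", "L5", "S1")


@dataclass(frozen=True)
class Plane:
    """Oriented plane: a point on it and a unit normal pointing cranially."""

    point: tuple[float, float, float]
    normal: tuple[float, float, float]

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=float)
        norm = np.linalg.norm(n)
        if not np.isclose(norm, 1.0, atol=1e-8):
            raise ValueError("plane normal must be a unit vector")
        if n[2] <= 0:
            raise ValueError("plane normal must point cranially (positive z)")
        object.__setattr__(self, "point", tuple(float(v) for v in self.point))
        object.__setattr__(self, "normal", tuple(float(v) for v in n))

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        """Signed distance of points (..., 3) — positive cranial of the plane."""
        p = np.asarray(points, dtype=float)
        n = np.asarray(self.normal)
        q = np.asarray(self.point)
        return (p - q) @ n

    def angle_deg_to(self, other: "Plane") -> float:
        cosang = float(np.clip(np.dot(self.normal, other.normal), -1.0, 1.0))
        return float(np.degrees(np.arccos(cosang)))


@dataclass
class LevelPartition:
    """Ordered clipping planes and the per-level dural voxel masks."""

    planes: list[Plane]  # above-L3, L3/L4, L4/L5, L5/S1, below-S1
    segment_masks: dict[str, np.ndarray]
    voxel_spacing: tuple[float, float, float]

    def segment_volume_ml(self, level: str) -> float:
        s = self.voxel_spacing
        return float(self.segment_masks[level].sum()) * s[0] * s[1] * s[2] / 1000.0

    def mid_plane(self, level: str) -> Plane:
        """Plane halfway between a level's bounding clipping planes."""
        i = _SEGMENTS.index(level)
        up, lo = self.planes[i], self.planes[i + 1]
        point = tuple((np.asarray(up.point) + np.asarray(lo.point)) / 2.0)
        n = np.asarray(up.normal) + np.asarray(lo.normal)
        n = n / np.linalg.norm(n)
        return Plane(point=point, normal=tuple(n))


def _centroid_mm(mask: np.ndarray, spacing) -> np.ndarray:
    idx = np.argwhere(mask)
    if idx.size == 0:
        raise ValueError("empty mask")
    return idx.mean(axis=0) * np.asarray(spacing)


def _slab_centroid(coords: np.ndarray, axis: np.ndarray, end: str, thickness: float = 2.0) -> np.ndarray:
    """Centroid of the extreme ``thickness``-mm slab of a voxel cloud along
    ``axis`` (``end`` = 'top' for the most cranial slab w.r.t. axis)."""
    t = coords @ axis
    if end == "top":
        sel = t >= t.max() - thickness
    else:
        sel = t <= t.min() + thickness
    return coords[sel].mean(axis=0)


def fit_clipping_planes(labels: LabelVolume) -> list[Plane]:
    """Fit the five clipping planes bounding dural segments L3..S1.

    For each adjacent vertebra pair the plane passes through the midpoint
    of the two facing endplate centroids (the extreme 2 mm voxel slab of
    each body along the inter-centroid axis) with the inter-centroid
    direction as normal.  The outer boundary planes sit half a disc gap
    outside the outer endplates of L3 and S1; the gap is estimated as the
    mean endplate-to-endplate distance of the three interior discs.
    """
    spacing = np.asarray(labels.voxel_spacing)
    coords: dict[str, np.ndarray] = {}
    centroids: dict[str, np.ndarray] = {}
    for name in VERTEBRAE + ("dural_sac",):
        try:
            lid = labels.label_for(name)
        except KeyError as e:
            raise ValueError(f"missing label: {name}") from e
        idx = np.argwhere(labels.grid == lid)
        if idx.size == 0:
            raise ValueError(f"missing label: {name}")
        coords[name] = idx * spacing
        centroids[name] = coords[name].mean(axis=0)

    for a, b in zip(VERTEBRAE[:-1], VERTEBRAE[1:]):
        if np.linalg.norm(centroids[a] - centroids[b]) < max(spacing):
            raise ValueError(f"degenerate vertebral masks: {a} and {b} overlap")

    interior: list[Plane] = []
    gaps: list[float] = []
    for upper, lower in zip(VERTEBRAE[:-1], VERTEBRAE[1:]):
        axis = centroids[upper] - centroids[lower]
        axis = axis / np.linalg.norm(axis)
        e_up = _slab_centroid(coords[upper], axis, end="bottom")
        e_lo = _slab_centroid(coords[lower], axis, end="top")
        gaps.append(float((e_up - e_lo) @ axis))
        point = (e_up + e_lo) / 2.0
        interior.append(Plane(point=tuple(point), normal=tuple(axis)))
    half_gap = max(float(np.mean(gaps)) / 2.0, 0.0)

    # boundary planes from the outer endplates, offset outward
    axis_top = centroids["L3"] - centroids["L4"]
    axis_top = axis_top / np.linalg.norm(axis_top)
    top_point = _slab_centroid(coords["L3"], axis_top, end="top") + axis_top * half_gap
    axis_bot = centroids["L5"] - centroids["S1"]
    axis_bot = axis_bot / np.linalg.norm(axis_bot)
    bot_point = _slab_centroid(coords["S1"], axis_bot, end="bottom") - axis_bot * half_gap

    return [Plane(point=tuple(top_point), normal=tuple(axis_top)), *interior,
            Plane(point=tuple(bot_point), normal=tuple(axis_bot))]


def partition_dural_sac(labels: LabelVolume, planes: list[Plane]) -> LevelPartition:
    """Partition the dural sac voxels into level segments by the planes.

    Requires the five planes ordered cranial to caudal (strictly
    decreasing z of the plane points).  A voxel center at or below k of
    the planes belongs to segment k-1 (half-open, upper-closed); voxels
    outside the outermost planes stay unassigned.
    """
    if len(planes) != 5:
        raise ValueError("expected 5 planes (above-L3 .. below-S1)")
    zs = [p.point[2] for p in planes]
    if not all(a > b for a, b in zip(zs[:-1], zs[1:])):
        raise ValueError("planes must be ordered cranial to caudal (strictly decreasing z)")

    dural = labels.mask(labels.label_for("dural_sac"))
    idx = np.argwhere(dural)
    if idx.size == 0:
        raise ValueError("missing label: dural_sac")
    pts = idx * np.asarray(labels.voxel_spacing)

    below = np.stack([p.signed_distance(pts) <= 0 for p in planes], axis=0)
    count = below.sum(axis=0)  # how many planes the voxel is at/below

    masks: dict[str, np.ndarray] = {}
    for i, level in enumerate(_SEGMENTS):
        sel = count == i + 1
        m = np.zeros_like(dural)
        m[tuple(idx[sel].T)] = True
        if not m.any():
            raise ValueError(f"planes do not intersect the dural extent at level {level}")
        masks[level] = m
    return LevelPartition(planes=list(planes), segment_masks=masks,
                          voxel_spacing=labels.voxel_spacing)
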