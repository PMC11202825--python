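"""Voxel-count volumetry and anteroposterior diameter measurement.

Volumes are voxel counts times voxel volume (mm^3 -> mL).  AP diameters
are the y-extent of a structure's voxels within the midsagittal slab
(one voxel either side of the sagittal plane through the structure
centroid) at a reference axial level: the body centroid level for
vertebrae, the mid-plane between the bounding clipping planes for dural
segments, and 2 mm end slabs for the S1 endplates.  A single voxel reads
as one voxel spacing.  Nothing is rounded internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .level_partition import LevelPartition, Plane
from .volumes import LabelVolume

__all__ = ["MeasurementSet", "label_volume_ml", "ap_diameter", "s1_scalloping", "measure_all"]

_VERT_ORDER = ("L3", "L4", "L5", "S1")


@dataclass
class MeasurementSet:
    """Per-patient image-derived quantities (volumes mL, diameters mm)."""

    patient_id: str = ""
    dural_volume: dict[str, float] = field(default_factory=dict)  # L3..S1
    vertebral_volume: dict[str, float] = field(default_factory=dict)  # L3..L5
    dural_diameter: dict[str, float] = field(default_factory=dict)
    vertebral_diameter: dict[str, float] = field(default_factory=dict)
    s1_endplate_upper_diameter: float | None = None
    s1_endplate_lower_diameter: float | None = None
    s1_scalloping: float | None = None
    height: float | None = None  # cm
    weight: float | None = None  # kg

    def to_row(self) -> dict[str, float | str]:
        row: dict[str, float | str] = {"patient_id": self.patient_id}
        for lvl, v in self.dural_volume.items():
            row[f"dural_volume_{lvl}"] = v
        for lvl, v in self.vertebral_volume.items():
            row[f"vertebral_volume_{lvl}"] = v
        for lvl, v in self.dural_diameter.items():
            row[f"dural_diameter_{lvl}"] = v
        for lvl, v in self.vertebral_diameter.items():
            row[f"vertebral_diameter_{lvl}"] = v
        for name in ("s1_endplate_upper_diameter", "s1_endplate_lower_diameter",
                     "s1_scalloping", "height", "weight"):
            v = getattr(self, name)
            if v is not None:
                row[name] = v
        return row


def label_volume_ml(labels: LabelVolume, label_id: int) -> float:
    """Voxel-count volume of one label in mL."""
    n = int(np.count_nonzero(labels.grid == label_id))
    if n == 0:
        raise ValueError(f"label {label_id} absent from volume")
    return n * labels.voxel_volume_mm3 / 1000.0


def _structure_points(labels: LabelVolume, label_id: int) -> np.ndarray:
    idx = np.argwhere(labels.grid == label_id)
    if idx.size == 0:
        raise ValueError(f"label {label_id} absent from volume")
    return idx * np.asarray(labels.voxel_spacing)


def ap_diameter(labels: LabelVolume, structure: int, reference_plane: Plane) -> float:
    """AP (y) extent of a structure in the midsagittal slab at a plane.

    Voxels within half a voxel of the reference plane and within one
    voxel laterally of the structure's sagittal centroid plane are kept;
    the diameter is their y range plus one voxel spacing.
    """
    pts = _structure_points(labels, structure)
    sx, sy, sz = labels.voxel_spacing
    cx = pts[:, 0].mean()
    slab = np.abs(reference_plane.signed_distance(pts)) <= sz / 2.0
    sag = np.abs(pts[:, 0] - cx) <= sx
    sel = pts[slab & sag]
    if sel.size == 0:
        raise ValueError("structure does not intersect the reference plane slab")
    return float(sel[:, 1].max() - sel[:, 1].min() + sy)


def s1_scalloping(d_mid_s1: float, d_upper_endplate: float, d_lower_endplate: float) -> float:
    """Posterior S1 erosion: mean endplate diameter minus mid-body diameter.

    Positive values indicate scalloping (the mid-body is narrower than
    the endplates).
    """
    if min(d_mid_s1, d_upper_endplate, d_lower_endplate) <= 0:
        raise ValueError("diameters must be positive")
    return (d_upper_endplate + d_lower_endplate) / 2.0 - d_mid_s1


def _endplate_diameter(labels: LabelVolume, label_id: int, end: str,
                       slab_mm: float = 2.0) -> float:
    pts = _structure_points(labels, label_id)
    sx, sy, _ = labels.voxel_spacing
    cx = pts[:, 0].mean()
    z = pts[:, 2]
    sel = z >= z.max() - slab_mm if end == "upper" else z <= z.min() + slab_mm
    sel &= np.abs(pts[:, 0] - cx) <= sx
    pick = pts[sel]
    if pick.size == 0:
        raise ValueError("empty endplate slab")
    return float(pick[:, 1].max() - pick[:, 1].min() + sy)


def measure_all(labels: LabelVolume, partition: LevelPartition) -> MeasurementSet:
    """Fill every image-derivable measurement from labels and partition."""
    missing = [lvl for lvl in _VERT_ORDER if lvl not in partition.segment_masks]
    if missing:
        raise ValueError(f"partition missing levels: {missing}")
    m = MeasurementSet()
    s = labels.voxel_spacing
    voxel_ml = s[0] * s[1] * s[2] / 1000.0
    for lvl in _VERT_ORDER:
        m.dural_volume[lvl] = float(partition.segment_masks[lvl].sum()) * voxel_ml
    for lvl in ("L3", "L4", "L5"):
        m.vertebral_volume[lvl] = label_volume_ml(labels, labels.label_for(lvl))

    for lvl in _VERT_ORDER:
        lid = labels.label_for(lvl)
        pts = _structure_points(labels, lid)
        centroid = pts.mean(axis=0)
        plane = Plane(point=tuple(centroid), normal=(0.0, 0.0, 1.0))
        m.vertebral_diameter[lvl] = ap_diameter(labels, lid, plane)
        m.dural_diameter[lvl] = ap_diameter(
            labels, labels.label_for("dural_sac"), partition.mid_plane(lvl)
        )

    s1 = labels.label_for("S1")
    m.s1_endplate_upper_diameter = _endplate_diameter(labels, s1, "upper")
    m.s1_endplate_lower_diameter = _endplate_diameter(labels, s1, "lower")
    m.s1_scalloping = s1_scalloping(
        m.vertebral_diameter["S1"],
        m.s1_endplate_upper_diameter,
        m.s1_endplate_lower_diameter,
    )
    return m
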