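"""In-memory containers for 3D image and label grids.

Axis convention (right-handed, tag ``"RAS"``): array axis 0 = x
(left -> right), axis 1 = y (posterior -> anterior), axis 2 = z
(caudal -> cranial).  Anteroposterior measurements run along +y.
Voxel centers sit at ``index * spacing`` in continuous physical mm;
indices are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LabelVolume", "IntensityVolume", "DEFAULT_LABEL_MAP", "LABEL_IDS"]

#: Canonical structure labels.
DEFAULT_LABEL_MAP = {1: "L3", 2: "L4", 3: "L5", 4: "S1", 10: "dural_sac"}
LABEL_IDS = {v: k for k, v in DEFAULT_LABEL_MAP.items()}


@dataclass
class LabelVolume:
    """Integer label grid with isotropic-or-not voxel spacing in mm."""

    grid: np.ndarray
    voxel_spacing: tuple[float, float, float]
    orientation: str = "RAS"
    label_map: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_LABEL_MAP))

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if not np.issubdtype(self.grid.dtype, np.integer):
            raise TypeError("label grid must be integer-valued")
        if self.grid.ndim != 3:
            raise ValueError("label grid must be 3D")
        self.voxel_spacing = tuple(float(s) for s in np.atleast_1d(self.voxel_spacing).repeat(
            3 if np.size(self.voxel_spacing) == 1 else 1
        ))[:3]
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel spacing must be positive")
        declared = set(self.label_map) | {0}
        present = set(np.unique(self.grid).tolist())
        if not present <= declared:
            raise ValueError(f"undeclared labels present: {sorted(present - declared)}")

    @property
    def voxel_volume_mm3(self) -> float:
        s = self.voxel_spacing
        return s[0] * s[1] * s[2]

    def mask(self, label_id: int) -> np.ndarray:
        return self.grid == label_id

    def label_for(self, name: str) -> int:
        for lid, lname in self.label_map.items():
            if lname == name:
                return lid
        raise KeyError(f"no label named {name!r}")

    def voxel_centers_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical coordinates of voxel centers as open mesh (x, y, z)."""
        sx, sy, sz = self.voxel_spacing
        nx, ny, nz = self.grid.shape
        return (
            np.arange(nx)[:, None, None] * sx,
            np.arange(ny)[None, :, None] * sy,
            np.arange(nz)[None, None, :] * sz,
        )


@dataclass
class IntensityVolume:
    """Non-negative real-valued image grid (arbitrary signal units)."""

    grid: np.ndarray
    voxel_spacing: tuple[float, float, float]
    orientation: str = "RAS"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 3:
            raise ValueError("intensity grid must be 3D")
        if not np.all(np.isfinite(self.grid)):
            raise ValueError("intensity grid must be finite")
        self.voxel_spacing = tuple(float(s) for s in np.atleast_1d(self.voxel_spacing).repeat(
            3 if np.size(self.voxel_spacing) == 1 else 1
        ))[:3]
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel spacing must be positive")
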