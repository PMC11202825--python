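"""Derived indices: dural sac volume/diameter ratios, BSA, BMI.

DSVR (dural sac volume ratio) at a level is the dural segment volume
over the vertebral body volume at that level; at S1 the denominator is
the L5 vertebral volume, since the sacral body is not measured
volumetrically.  DSDR (dural sac diameter ratio) is the AP dural
diameter over the AP vertebral diameter at the same level.  BMI-corrected
variants are simple quotients value / BMI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .morphometry import MeasurementSet

__all__ = ["RatioSet", "dsvr", "du_bois_bsa", "bmi", "compute_ratio_table"]

#: Du Bois & Du Bois body-surface-area coefficients (kg, cm -> m^2).
DU_BOIS_COEF = 0.007184
DU_BOIS_EXP_WEIGHT = 0.425
DU_BOIS_EXP_HEIGHT = 0.725


@dataclass
class RatioSet:
    """Per-level ratios plus demographic indices for one patient."""

    patient_id: str = ""
    dsvr: dict[str, float] = field(default_factory=dict)  # L3..S1
    dsdr: dict[str, float] = field(default_factory=dict)  # up to L1..S1
    bmi: float | None = None  # kg/m^2
    bsa: float | None = None  # m^2
    bmi_corrected: dict[str, float] = field(default_factory=dict)

    def to_row(self) -> dict[str, float | str]:
        row: dict[str, float | str] = {"patient_id": self.patient_id}
        for lvl, v in self.dsvr.items():
            row[f"dsvr_{lvl}"] = v
        for lvl, v in self.dsdr.items():
            row[f"dsdr_{lvl}"] = v
        if self.bmi is not None:
            row["bmi"] = self.bmi
        if self.bsa is not None:
            row["bsa"] = self.bsa
        for name, v in self.bmi_corrected.items():
            row[f"{name}_per_bmi"] = v
        return row


def dsvr(dural_volume: float, vertebral_volume: float) -> float:
    """Dural sac volume ratio (dimensionless)."""
    if vertebral_volume <= 0:
        raise ValueError("vertebral volume must be positive")
    return dural_volume / vertebral_volume


def du_bois_bsa(height: float, weight: float) -> float:
    """Du Bois body surface area in m^2 from height (cm) and weight (kg)."""
    if height <= 0 or weight <= 0:
        raise ValueError("height and weight must be positive")
    return DU_BOIS_COEF * weight ** DU_BOIS_EXP_WEIGHT * height ** DU_BOIS_EXP_HEIGHT


def bmi(height: float, weight: float) -> float:
    """Body mass index in kg/m^2 from height (cm) and weight (kg)."""
    if height <= 0 or weight <= 0:
        raise ValueError("height and weight must be positive")
    return weight / (height / 100.0) ** 2


def compute_ratio_table(m: MeasurementSet) -> RatioSet:
    """Derive all ratios available from a MeasurementSet.

    dsvr_S1 always divides by the L5 vertebral volume.  DSDR is computed
    for every level with both diameters.  If height and weight are
    present, BMI, BSA and BMI-corrected values of all measured volumes,
    diameters and scalloping are filled in as well.
    """
    r = RatioSet(patient_id=m.patient_id)
    for lvl in ("L3", "L4", "L5"):
        if lvl in m.dural_volume and lvl in m.vertebral_volume:
            r.dsvr[lvl] = dsvr(m.dural_volume[lvl], m.vertebral_volume[lvl])
    if "S1" in m.dural_volume:
        if "L5" not in m.vertebral_volume:
            raise ValueError("dsvr_S1 requires the L5 vertebral volume")
        r.dsvr["S1"] = dsvr(m.dural_volume["S1"], m.vertebral_volume["L5"])

    for lvl, d in m.dural_diameter.items():
        if lvl in m.vertebral_diameter:
            if m.vertebral_diameter[lvl] <= 0:
                raise ValueError(f"non-positive vertebral diameter at {lvl}")
            r.dsdr[lvl] = d / m.vertebral_diameter[lvl]

    if m.height is not None and m.weight is not None:
        r.bmi = bmi(m.height, m.weight)
        r.bsa = du_bois_bsa(m.height, m.weight)
        for lvl, v in m.dural_volume.items():
            r.bmi_corrected[f"dural_volume_{lvl}"] = v / r.bmi
        for lvl, v in m.vertebral_volume.items():
            r.bmi_corrected[f"vertebral_volume_{lvl}"] = v / r.bmi
        for lvl, v in m.dural_diameter.items():
            r.bmi_corrected[f"dural_diameter_{lvl}"] = v / r.bmi
        for lvl, v in m.vertebral_diameter.items():
            r.bmi_corrected[f"vertebral_diameter_{lvl}"] = v / r.bmi
        if m.s1_scalloping is not None:
            r.bmi_corrected["s1_scalloping"] = m.s1_scalloping / r.bmi
    return r
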