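"""Synthetic patient cohorts for the diagnostics stage.

Generates per-patient measurement tables whose group-wise (Marfan vs.
non-Marfan) distributions match published per-level summary statistics, so
that the ROC/Youden/McNemar machinery can be exercised and calibrated
without access to patient data.

Each variable is described by its group mean and standard deviation and a
marginal family.  Strictly positive, right-skewed quantities (volumes,
diameters, ratios) default to a moment-matched lognormal; demographics
(height, weight) to a normal truncated at zero.  Variables are sampled
independently unless a correlation matrix is supplied, in which case a
Gaussian copula couples the marginals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupDistributionSpec",
    "CohortTable",
    "default_group_specs",
    "sample_cohort",
    "lognormal_params",
    "LEVELS_VOLUME",
    "LEVELS_DIAMETER",
]

#: Levels at which dural sac segment volumes (and volume ratios) exist.
LEVELS_VOLUME = ("L3", "L4", "L5", "S1")
#: Levels at which AP diameters (and diameter ratios) exist.
LEVELS_DIAMETER = ("L1", "L2", "L3", "L4", "L5", "S1")

_FAMILIES = ("truncated_normal", "lognormal")


def lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Solve for (mu, sigma) of a lognormal with the given mean and sd.

    sigma^2 = ln(1 + (sd/mean)^2);  mu = ln(mean) - sigma^2 / 2.
    """
    if mean <= 0 or sd <= 0:
        raise ValueError("lognormal moment matching needs mean > 0 and sd > 0")
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return float(mu), float(np.sqrt(sigma2))


@dataclass
class GroupDistributionSpec:
    """Marginal (and optionally copula) description of one study group.

    Parameters
    ----------
    group:
        ``"MFS"`` or ``"nonMFS"``.
    variables:
        Mapping variable name -> (mean, sd).  Units follow the variable
        name convention: volumes in mL, diameters in mm, ratios
        dimensionless, height in cm, weight in kg.
    family:
        Default marginal family for variables without an override.
    family_overrides:
        Per-variable family, taking precedence over ``family``.
    correlation:
        Optional correlation matrix (order = insertion order of
        ``variables``).  Must be symmetric PSD with unit diagonal.
    """

    group: str
    variables: dict[str, tuple[float, float]]
    family: str = "lognormal"
    family_overrides: dict[str, str] = field(default_factory=dict)
    correlation: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.group not in ("MFS", "nonMFS"):
            raise ValueError(f"unknown group {self.group!r}")
        if self.family not in _FAMILIES:
            raise ValueError(f"invalid family {self.family!r}")
        for v, fam in self.family_overrides.items():
            if fam not in _FAMILIES:
                raise ValueError(f"invalid family {fam!r} for variable {v!r}")
        for name, (mean, sd) in self.variables.items():
            if sd < 0:
                raise ValueError(f"{name}: sd must be >= 0")
            if mean <= 0:
                raise ValueError(f"{name}: mean of a physical quantity must be > 0")
        if self.correlation is not None:
            c = np.asarray(self.correlation, dtype=float)
            k = len(self.variables)
            if c.shape != (k, k):
                raise ValueError("correlation matrix shape mismatch")
            if not np.allclose(c, c.T):
                raise ValueError("correlation matrix must be symmetric")
            if not np.allclose(np.diag(c), 1.0):
                raise ValueError("correlation matrix must have unit diagonal")
            w = np.linalg.eigvalsh(c)
            if w.min() < -1e-10:
                raise ValueError("correlation matrix must be positive semi-definite")
            self.correlation = c

    def family_of(self, name: str) -> str:
        return self.family_overrides.get(name, self.family)

    # -- JSON round trip -------------------------------------------------

    def to_json(self) -> str:
        d = {
            "group": self.group,
            "variables": {k: list(v) for k, v in self.variables.items()},
            "family": self.family,
            "family_overrides": self.family_overrides,
            "correlation": None
            if self.correlation is None
            else np.asarray(self.correlation).tolist(),
        }
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GroupDistributionSpec":
        d = json.loads(text)
        corr = d.get("correlation")
        return cls(
            group=d["group"],
            variables={k: (float(v[0]), float(v[1])) for k, v in d["variables"].items()},
            family=d.get("family", "lognormal"),
            family_overrides=d.get("family_overrides", {}),
            correlation=None if corr is None else np.asarray(corr, dtype=float),
        )


@dataclass
class CohortTable:
    """A sampled cohort plus the provenance needed to regenerate it."""

    table: pd.DataFrame
    spec_mfs: GroupDistributionSpec
    spec_non: GroupDistributionSpec
    seed: int

    def __len__(self) -> int:
        return len(self.table)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


# Published per-group summary statistics (mean, sd).  Volumes mL,
# diameters mm, ratios dimensionless, sleeve/scalloping mm, height cm,
# weight kg.
_MFS_VARS: dict[str, tuple[float, float]] = {
    "dural_volume_L3": (12.8, 2.8),
    "dural_volume_L4": (12.0, 3.3),
    "dural_volume_L5": (11.6, 4.2),
    "dural_volume_S1": (13.3, 8.4),
    "vertebral_volume_L3": (36.7, 7.4),
    "vertebral_volume_L4": (37.4, 7.6),
    "vertebral_volume_L5": (33.2, 7.8),
    "dsvr_L3": (0.36, 0.10),
    "dsvr_L4": (0.33, 0.11),
    "dsvr_L5": (0.36, 0.14),
    "dsvr_S1": (0.41, 0.28),
    "dural_diameter_L1": (18.6, 3.3),
    "dural_diameter_L2": (17.6, 2.1),
    "dural_diameter_L3": (17.0, 2.5),
    "dural_diameter_L4": (17.6, 3.0),
    "dural_diameter_L5": (19.3, 4.1),
    "dural_diameter_S1": (19.1, 6.9),
    "vertebral_diameter_L1": (28.6, 5.8),
    "vertebral_diameter_L2": (30.1, 4.3),
    "vertebral_diameter_L3": (31.5, 3.7),
    "vertebral_diameter_L4": (31.7, 3.3),
    "vertebral_diameter_L5": (29.5, 3.4),
    "vertebral_diameter_S1": (19.3, 4.4),
    "dsdr_L1": (0.67, 0.12),
    "dsdr_L2": (0.60, 0.11),
    "dsdr_L3": (0.55, 0.10),
    "dsdr_L4": (0.56, 0.11),
    "dsdr_L5": (0.66, 0.16),
    "dsdr_S1": (1.11, 0.68),
    "nerve_root_sleeve_L5": (6.1, 1.2),
    "s1_scalloping": (5.0, 2.5),
    "height": (187.8, 10.6),
    "weight": (79.4, 13.7),
}

_NON_VARS: dict[str, tuple[float, float]] = {
    "dural_volume_L3": (9.8, 2.0),
    "dural_volume_L4": (8.5, 2.4),
    "dural_volume_L5": (7.5, 2.6),
    "dural_volume_S1": (4.9, 2.4),
    "vertebral_volume_L3": (36.6, 9.6),
    "vertebral_volume_L4": (36.8, 8.9),
    "vertebral_volume_L5": (34.9, 7.8),
    "dsvr_L3": (0.28, 0.07),
    "dsvr_L4": (0.24, 0.07),
    "dsvr_L5": (0.22, 0.07),
    "dsvr_S1": (0.14, 0.06),
    "dural_diameter_L1": (16.7, 2.3),
    "dural_diameter_L2": (15.7, 2.0),
    "dural_diameter_L3": (15.2, 1.9),
    "dural_diameter_L4": (14.5, 2.7),
    "dural_diameter_L5": (14.9, 3.0),
    "dural_diameter_S1": (11.9, 3.3),
    "vertebral_diameter_L1": (28.0, 3.8),
    "vertebral_diameter_L2": (29.6, 3.6),
    "vertebral_diameter_L3": (31.1, 3.7),
    "vertebral_diameter_L4": (31.2, 3.6),
    "vertebral_diameter_L5": (30.2, 3.1),
    "vertebral_diameter_S1": (23.8, 3.2),
    "dsdr_L1": (0.60, 0.11),
    "dsdr_L2": (0.54, 0.09),
    "dsdr_L3": (0.49, 0.09),
    "dsdr_L4": (0.48, 0.10),
    "dsdr_L5": (0.50, 0.12),
    "dsdr_S1": (0.50, 0.14),
    "nerve_root_sleeve_L5": (6.0, 1.0),
    "s1_scalloping": (3.1, 1.3),
    "height": (182.0, 9.8),
    "weight": (70.8, 15.5),
}

_DEMOGRAPHICS = ("height", "weight")


def default_group_specs(
    family: str = "lognormal",
) -> tuple[GroupDistributionSpec, GroupDistributionSpec]:
    """Return (MFS, non-MFS) specs pre-loaded with the published group
    means and standard deviations for every per-level volume, ratio,
    diameter, the L5 nerve-root-sleeve diameter, S1 scalloping, height
    and weight.

    ``family`` sets the marginal for the measured quantities; height and
    weight are always truncated-normal (they are symmetric at these
    coefficients of variation).
    """
    overrides = {v: "truncated_normal" for v in _DEMOGRAPHICS}
    mfs = GroupDistributionSpec(
        group="MFS", variables=dict(_MFS_VARS), family=family, family_overrides=overrides
    )
    non = GroupDistributionSpec(
        group="nonMFS", variables=dict(_NON_VARS), family=family, family_overrides=overrides
    )
    return mfs, non


def _sample_group(
    spec: GroupDistributionSpec, n: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    names = list(spec.variables)
    k = len(names)
    if spec.correlation is None:
        # independent: one uniform column per variable
        u = rng.random((n, k))
    else:
        # Gaussian copula: correlated normals -> uniforms
        chol_mat = np.linalg.cholesky(
            spec.correlation + 1e-12 * np.eye(k)
        )
        z = rng.standard_normal((n, k)) @ chol_mat.T
        u = stats.norm.cdf(z)
    out: dict[str, np.ndarray] = {}
    for j, name in enumerate(names):
        mean, sd = spec.variables[name]
        fam = spec.family_of(name)
        if sd == 0:
            out[name] = np.full(n, mean)
        elif fam == "lognormal":
            mu, sigma = lognormal_params(mean, sd)
            out[name] = np.exp(stats.norm.ppf(u[:, j]) * sigma + mu)
        else:  # truncated_normal: N(mean, sd) truncated at 0, not re-matched
            a = -mean / sd
            out[name] = stats.truncnorm.ppf(u[:, j], a, np.inf, loc=mean, scale=sd)
    return out


def sample_cohort(
    spec_mfs: GroupDistributionSpec,
    spec_non: GroupDistributionSpec,
    n_mfs: int,
    n_non: int,
    seed: int,
) -> CohortTable:
    """Draw a reproducible synthetic cohort.

    Values are drawn per variable from the spec's marginal family,
    moment-matched to the spec (mean, sd); the truncated-normal family
    truncates N(mean, sd) at zero without re-standardising, a documented
    (small) upward bias.  Identical inputs give identical tables.
    """
    if n_mfs < 0 or n_non < 0:
        raise ValueError("group sizes must be non-negative")
    rng = np.random.default_rng(seed)
    frames = []
    for spec, n, prefix in ((spec_mfs, n_mfs, "MFS"), (spec_non, n_non, "non")):
        cols = _sample_group(spec, n, rng)
        df = pd.DataFrame(cols)
        df.insert(0, "group", spec.group)
        df.insert(0, "patient_id", [f"{prefix}{i + 1:04d}" for i in range(n)])
        frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    return CohortTable(table=table, spec_mfs=spec_mfs, spec_non=spec_non, seed=seed)
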