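"""Synthetic 3D lumbosacral phantoms with analytically known geometry.

The phantom emulates the segmented anatomy that the volumetry pipeline
consumes: vertebral bodies L3..S1 as elliptic cylinders with optional
concave lateral surfaces (and optional anteroposterior concavity to model
posterior scalloping), and the dural sac as a tube with a sagittally
curved centerline and a piecewise-linear radius profile tapering towards
the sacrum.  An ectasia factor >= 1 widens the tube caudal of the L5/S1
disc.  Because every surface is analytic, volumes, diameters and disc
mid-planes are known exactly, which makes the downstream voxel-count
volumetry and plane fitting testable against closed forms.

Rasterization rule: a voxel belongs to a structure iff its center lies
inside the analytic surface.  Intensities are per-structure base signals
(dural sac bright, bone intermediate, background dark) with Rician noise.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage
from scipy.integrate import quad

from .level_partition import Plane
from .volumes import DEFAULT_LABEL_MAP, IntensityVolume, LabelVolume

__all__ = [
    "VertebraSpec",
    "PhantomSpec",
    "GroundTruth",
    "default_phantom_spec",
    "build_phantom",
    "perturb_labels",
    "simple_segment",
    "elliptic_body_volume_ml",
    "dural_volume_ml_between",
    "fine_grid_segment_volumes",
]

_VERT_ORDER = ("L3", "L4", "L5", "S1")
_VERT_LABEL = {"L3": 1, "L4": 2, "L5": 3, "S1": 4}
DURAL_LABEL = 10


@dataclass
class VertebraSpec:
    """Elliptic-cylinder vertebral body.

    ``ap_semi_axis_mm`` runs along +y, ``lat_semi_axis_mm`` along x.
    The concavity depths shrink the respective semi-axis at mid-height by
    a parabolic profile (zero at the endplates, maximal at mid-body).
    """

    center: tuple[float, float, float]
    height_mm: float
    ap_semi_axis_mm: float
    lat_semi_axis_mm: float
    lat_concavity_mm: float = 0.0
    ap_concavity_mm: float = 0.0

    def __post_init__(self) -> None:
        if min(self.height_mm, self.ap_semi_axis_mm, self.lat_semi_axis_mm) <= 0:
            raise ValueError("vertebra extents must be positive")
        if self.lat_concavity_mm < 0 or self.ap_concavity_mm < 0:
            raise ValueError("concavity depths must be >= 0")
        if self.lat_concavity_mm >= self.lat_semi_axis_mm:
            raise ValueError("lateral concavity exceeds semi-axis")
        if self.ap_concavity_mm >= self.ap_semi_axis_mm:
            raise ValueError("AP concavity exceeds semi-axis")


@dataclass
class PhantomSpec:
    """Full phantom geometry plus imaging parameters."""

    voxel_spacing: float = 1.0
    grid_shape: tuple[int, int, int] = (96, 96, 224)
    vertebrae: dict[str, VertebraSpec] = field(default_factory=dict)
    disc_gap_mm: float = 6.0
    dural_center_x: float = 47.6
    #: sagittal centerline as (z, y) control points, any order in z
    dural_centerline: list[tuple[float, float]] = field(default_factory=list)
    #: radius profile as (z, r) control points; domain = tube z extent
    dural_radius: list[tuple[float, float]] = field(default_factory=list)
    ectasia_factor: float = 1.0
    noise_sigma_frac: float = 0.05
    signals: dict[str, float] = field(
        default_factory=lambda: {"dural": 1.0, "bone": 0.45, "background": 0.05}
    )

    def __post_init__(self) -> None:
        if self.voxel_spacing <= 0:
            raise ValueError("voxel spacing must be positive")
        if self.ectasia_factor < 1.0:
            raise ValueError("ectasia factor must be >= 1")
        if self.disc_gap_mm < 0:
            raise ValueError("disc gap must be >= 0")
        if len(self.dural_radius) < 1:
            raise ValueError("dural radius profile needs at least one control point")
        if any(r <= 0 for _, r in self.dural_radius):
            raise ValueError("dural radii must be positive")

    # -- dural sac geometry ---------------------------------------------

    def _z_extent(self) -> tuple[float, float]:
        zs = [z for z, _ in self.dural_radius]
        return min(zs), max(zs)

    def centerline_y(self, z: np.ndarray | float) -> np.ndarray | float:
        pts = sorted(self.dural_centerline)
        zp = [p[0] for p in pts]
        yp = [p[1] for p in pts]
        return np.interp(z, zp, yp)

    def radius(self, z: np.ndarray | float) -> np.ndarray | float:
        """Effective tube radius, including the ectasia widening which
        ramps in linearly across the L5/S1 disc gap."""
        pts = sorted(self.dural_radius)
        zp = [p[0] for p in pts]
        rp = [p[1] for p in pts]
        r = np.interp(z, zp, rp)
        f = self.ectasia_factor
        if f != 1.0:
            z_ls = self.true_disc_plane_z()[3]
            g = max(self.disc_gap_mm, 1e-6)
            w = np.clip((z_ls + g / 2.0 - np.asarray(z)) / g, 0.0, 1.0)
            r = r * (1.0 + (f - 1.0) * w)
        return r

    def true_disc_plane_z(self) -> list[float]:
        """z of the five true planes: above-L3, L3/L4, L4/L5, L5/S1, below-S1."""
        tops = {n: v.center[2] + v.height_mm / 2 for n, v in self.vertebrae.items()}
        bots = {n: v.center[2] - v.height_mm / 2 for n, v in self.vertebrae.items()}
        out = [tops["L3"] + self.disc_gap_mm / 2]
        for up, lo in zip(_VERT_ORDER[:-1], _VERT_ORDER[1:]):
            out.append((bots[up] + tops[lo]) / 2.0)
        out.append(bots["S1"] - self.disc_gap_mm / 2)
        return out

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PhantomSpec":
        d = json.loads(text)
        d["vertebrae"] = {k: VertebraSpec(**{**v, "center": tuple(v["center"])})
                          for k, v in d["vertebrae"].items()}
        d["grid_shape"] = tuple(d["grid_shape"])
        d["dural_centerline"] = [tuple(p) for p in d["dural_centerline"]]
        d["dural_radius"] = [tuple(p) for p in d["dural_radius"]]
        return cls(**d)


@dataclass
class GroundTruth:
    """Analytic reference values for one phantom."""

    structure_volumes_ml: dict[str, float]  # L3..S1 bodies; dural_sac = between outer planes
    segment_volumes_ml: dict[str, float]  # dural segments L3..S1
    dural_diameters_mm: dict[str, float]  # AP = 2 r at segment mid-z
    vertebral_diameters_mm: dict[str, float]  # AP at mid-body
    s1_endplate_upper_diameter_mm: float
    s1_endplate_lower_diameter_mm: float
    s1_scalloping_mm: float
    disc_planes: list[Plane]

    def to_json(self) -> str:
        d = asdict(self)
        d["disc_planes"] = [{"point": p["point"], "normal": p["normal"]}
                            for p in d["disc_planes"]]
        return json.dumps(d, indent=1)


def default_phantom_spec(ectasia_factor: float = 1.0,
                         noise_sigma_frac: float = 0.05) -> PhantomSpec:
    """A normal-anatomy lumbosacral phantom at 1 mm isotropic spacing.

    Vertebral bodies are 28 mm high with 6 mm disc gaps; the dural sac
    runs posterior to the bodies with a ventrally convex lumbar bow and
    tapers from 8 mm radius cranially to ~4.5 mm at the sacrum.  S1
    carries a 2.5 mm AP concavity so that posterior scalloping is a
    measurable, non-trivial quantity.
    """
    cx, cy = 47.6, 60.3
    verts = {}
    z_centers = {"L3": 180.4, "L4": 146.4, "L5": 112.4, "S1": 78.4}
    for name, cz in z_centers.items():
        if name == "S1":
            verts[name] = VertebraSpec(center=(cx, cy, cz), height_mm=28.0,
                                       ap_semi_axis_mm=13.0, lat_semi_axis_mm=15.0,
                                       lat_concavity_mm=2.5, ap_concavity_mm=2.5)
        else:
            verts[name] = VertebraSpec(center=(cx, cy, cz), height_mm=28.0,
                                       ap_semi_axis_mm=15.0, lat_semi_axis_mm=17.0,
                                       lat_concavity_mm=3.0)
    return PhantomSpec(
        vertebrae=verts,
        dural_center_x=cx,
        dural_centerline=[(40.0, 30.0), (78.0, 31.0), (146.0, 36.0), (215.0, 33.0)],
        dural_radius=[(40.0, 4.5), (95.0, 5.5), (180.0, 8.0), (215.0, 8.0)],
        ectasia_factor=ectasia_factor,
        noise_sigma_frac=noise_sigma_frac,
    )


# ---------------------------------------------------------------------
# analytic oracles


def elliptic_body_volume_ml(v: VertebraSpec) -> float:
    """Closed-form volume of a concave elliptic body in mL.

    Cross-sections are ellipses with semi-axes a - da(1-zeta^2) and
    b - db(1-zeta^2); the z integral of their area is polynomial.
    """
    a, b = v.ap_semi_axis_mm, v.lat_semi_axis_mm
    da, db = v.ap_concavity_mm, v.lat_concavity_mm
    h = v.height_mm
    vol = math.pi * h / 2.0 * (2 * a * b - (4.0 / 3.0) * (a * db + b * da)
                               + (16.0 / 15.0) * da * db)
    return vol / 1000.0


def dural_volume_ml_between(spec: PhantomSpec, z_lo: float, z_hi: float) -> float:
    """Exact tube volume between two horizontal planes (mL).

    Horizontal cross-sections are circles of radius ``spec.radius(z)``
    regardless of the centerline curve, so the volume is the z integral
    of pi r(z)^2, evaluated adaptively with the profile breakpoints.
    """
    z_min, z_max = spec._z_extent()
    z_lo, z_hi = max(z_lo, z_min), min(z_hi, z_max)
    if z_hi <= z_lo:
        return 0.0
    pts = sorted({z for z, _ in spec.dural_radius} |
                 {spec.true_disc_plane_z()[3] + s * spec.disc_gap_mm / 2 for s in (-1, 1)})
    pts = [z for z in pts if z_lo < z < z_hi]
    val, _ = quad(lambda z: math.pi * float(spec.radius(z)) ** 2, z_lo, z_hi,
                  points=pts or None, limit=200)
    return val / 1000.0


def fine_grid_segment_volumes(spec: PhantomSpec, planes: list[Plane],
                              subdivision: int = 4) -> dict[str, float]:
    """Fine-grid oracle: dural segment volumes (mL) for arbitrary
    (possibly tilted) planes, on a grid refined by ``subdivision``."""
    fs = spec.voxel_spacing / subdivision
    z_min, z_max = spec._z_extent()
    rmax = max(float(np.max(spec.radius(np.linspace(z_min, z_max, 512)))), 1.0)
    ys = [y for _, y in spec.dural_centerline]
    x0, x1 = spec.dural_center_x - rmax - fs, spec.dural_center_x + rmax + fs
    y0, y1 = min(ys) - rmax - fs, max(ys) + rmax + fs
    xs = np.arange(x0, x1, fs)[:, None, None]
    yv = np.arange(y0, y1, fs)[None, :, None]
    zv = np.arange(z_min, z_max + fs / 2, fs)[None, None, :]
    yc = np.asarray(spec.centerline_y(zv))
    rr = np.asarray(spec.radius(zv))
    inside = (xs - spec.dural_center_x) ** 2 + (yv - yc) ** 2 <= rr ** 2
    idx = np.argwhere(inside)
    pts = np.empty((len(idx), 3))
    pts[:, 0] = x0 + idx[:, 0] * fs
    pts[:, 1] = y0 + idx[:, 1] * fs
    pts[:, 2] = z_min + idx[:, 2] * fs
    below = np.stack([p.signed_distance(pts) <= 0 for p in planes], axis=0)
    count = below.sum(axis=0)
    out = {}
    for i, level in enumerate(_VERT_ORDER):
        out[level] = float(np.sum(count == i + 1)) * fs ** 3 / 1000.0
    return out


# ---------------------------------------------------------------------
# rasterization


def _vertebra_mask(v: VertebraSpec, xs, ys, zs) -> np.ndarray:
    cx, cy, cz = v.center
    zeta = 2.0 * (zs - cz) / v.height_mm
    in_z = np.abs(zeta) <= 1.0
    shrink = np.where(in_z, 1.0 - zeta ** 2, 0.0)
    a_eff = v.ap_semi_axis_mm - v.ap_concavity_mm * shrink
    b_eff = v.lat_semi_axis_mm - v.lat_concavity_mm * shrink
    return in_z & (((xs - cx) / b_eff) ** 2 + ((ys - cy) / a_eff) ** 2 <= 1.0)


def _dural_mask(spec: PhantomSpec, xs, ys, zs) -> np.ndarray:
    z_min, z_max = spec._z_extent()
    in_z = (zs >= z_min) & (zs <= z_max)
    yc = np.asarray(spec.centerline_y(zs))
    rr = np.asarray(spec.radius(zs))
    return in_z & ((xs - spec.dural_center_x) ** 2 + (ys - yc) ** 2 <= rr ** 2)


def build_phantom(spec: PhantomSpec, seed: int) -> tuple[IntensityVolume, LabelVolume, GroundTruth]:
    """Rasterize the phantom and compute its analytic ground truth.

    Raises if a structure leaves the grid or the dural sac intersects a
    vertebral body.
    """
    if set(spec.vertebrae) != set(_VERT_ORDER):
        raise ValueError(f"phantom needs vertebrae {_VERT_ORDER}")
    s = spec.voxel_spacing
    nx, ny, nz = spec.grid_shape
    xs = np.arange(nx)[:, None, None] * s
    ys = np.arange(ny)[None, :, None] * s
    zs = np.arange(nz)[None, None, :] * s

    grid = np.zeros(spec.grid_shape, dtype=np.int16)
    masks: dict[str, np.ndarray] = {}
    for name in _VERT_ORDER:
        m = _vertebra_mask(spec.vertebrae[name], xs, ys, zs)
        masks[name] = m
        grid[m] = _VERT_LABEL[name]
    dm = _dural_mask(spec, xs, ys, zs)
    for name in _VERT_ORDER:
        if np.any(dm & masks[name]):
            raise ValueError(f"dural sac intersects vertebral body {name}")
    grid[dm] = DURAL_LABEL

    # boundary check: no structure voxel may touch the grid faces
    fg = grid > 0
    if (fg[0].any() or fg[-1].any() or fg[:, 0].any() or fg[:, -1].any()
            or fg[:, :, 0].any() or fg[:, :, -1].any()):
        raise ValueError("structure exceeds grid")

    labels = LabelVolume(grid=grid, voxel_spacing=(s, s, s),
                         label_map=dict(DEFAULT_LABEL_MAP))

    sig = spec.signals
    base = np.full(spec.grid_shape, sig["background"], dtype=float)
    for name in _VERT_ORDER:
        base[masks[name]] = sig["bone"]
    base[dm] = sig["dural"]
    rng = np.random.default_rng(seed)
    sigma = spec.noise_sigma_frac * sig["dural"]
    if sigma > 0:
        n1 = rng.normal(0.0, sigma, spec.grid_shape)
        n2 = rng.normal(0.0, sigma, spec.grid_shape)
        img = np.sqrt((base + n1) ** 2 + n2 ** 2)
    else:
        img = base
    intensity = IntensityVolume(grid=img, voxel_spacing=(s, s, s))

    truth = _ground_truth(spec)
    return intensity, labels, truth


def _ground_truth(spec: PhantomSpec) -> GroundTruth:
    plane_z = spec.true_disc_plane_z()
    cx = spec.dural_center_x
    planes = [Plane(point=(cx, float(spec.centerline_y(z)), z), normal=(0.0, 0.0, 1.0))
              for z in plane_z]

    seg = {}
    for i, level in enumerate(_VERT_ORDER):
        seg[level] = dural_volume_ml_between(spec, plane_z[i + 1], plane_z[i])
    structure = {n: elliptic_body_volume_ml(spec.vertebrae[n]) for n in _VERT_ORDER}
    structure["dural_sac"] = dural_volume_ml_between(spec, plane_z[-1], plane_z[0])

    dural_d = {}
    for i, level in enumerate(_VERT_ORDER):
        z_mid = (plane_z[i] + plane_z[i + 1]) / 2.0
        dural_d[level] = 2.0 * float(spec.radius(z_mid))
    vert_d = {n: 2.0 * (spec.vertebrae[n].ap_semi_axis_mm - spec.vertebrae[n].ap_concavity_mm)
              for n in _VERT_ORDER}
    s1 = spec.vertebrae["S1"]
    d_end = 2.0 * s1.ap_semi_axis_mm
    scallop = (d_end + d_end) / 2.0 - vert_d["S1"]
    return GroundTruth(
        structure_volumes_ml=structure,
        segment_volumes_ml=seg,
        dural_diameters_mm=dural_d,
        vertebral_diameters_mm=vert_d,
        s1_endplate_upper_diameter_mm=d_end,
        s1_endplate_lower_diameter_mm=d_end,
        s1_scalloping_mm=scallop,
        disc_planes=planes,
    )


# ---------------------------------------------------------------------
# label perturbation and plumbing segmenter


def perturb_labels(labels: LabelVolume, boundary_noise_mm: float, seed: int,
                   correlation_mm: float = 10.0) -> LabelVolume:
    """Randomly displace each structure's surface.

    Each structure boundary is moved along its normal by a smooth
    zero-mean Gaussian random field (sd ``boundary_noise_mm``,
    correlation length ``correlation_mm``), implemented by thresholding
    the signed distance map at the field value.  Conflicting claims are
    resolved toward the structure with the smallest displaced distance,
    so labels stay mutually exclusive.
    """
    if boundary_noise_mm < 0:
        raise ValueError("boundary noise must be >= 0")
    if boundary_noise_mm == 0:
        return LabelVolume(grid=labels.grid.copy(), voxel_spacing=labels.voxel_spacing,
                           orientation=labels.orientation, label_map=dict(labels.label_map))
    rng = np.random.default_rng(seed)
    spacing = labels.voxel_spacing
    shape = labels.grid.shape
    sm_sigma = [correlation_mm / sp for sp in spacing]

    new_grid = np.zeros(shape, dtype=labels.grid.dtype)
    score = np.full(shape, np.inf)
    for lid in sorted(labels.label_map):
        mask = labels.grid == lid
        if not mask.any():
            continue
        field_ = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sm_sigma)
        field_ *= boundary_noise_mm / field_.std()
        d_out = ndimage.distance_transform_edt(~mask, sampling=spacing)
        d_in = ndimage.distance_transform_edt(mask, sampling=spacing)
        signed = d_out - d_in  # negative inside
        disp = signed - field_
        claim = disp <= 0
        take = claim & (disp < score)
        new_grid[take] = lid
        score[take] = disp[take]
    return LabelVolume(grid=new_grid, voxel_spacing=spacing,
                       orientation=labels.orientation, label_map=dict(labels.label_map))


def simple_segment(intensity: IntensityVolume,
                   thresholds: dict[str, tuple[float, float]] | None = None) -> LabelVolume:
    """Plumbing-level intensity segmenter for phantom images.

    ``thresholds`` maps ``"dural_sac"`` and/or ``"bone"`` to inclusive
    intensity bounds.  Each band is thresholded and hole-filled; the
    dural sac keeps its largest connected component, the bone band its
    four largest (assigned L3..S1 cranial to caudal by centroid z).
    """
    if thresholds is None:
        thresholds = {"bone": (0.25, 0.7), "dural_sac": (0.7, np.inf)}
    for name, (lo, hi) in thresholds.items():
        if lo > hi:
            raise ValueError(f"thresholds for {name!r} are not ordered")
    grid = np.zeros(intensity.grid.shape, dtype=np.int16)

    if "bone" in thresholds:
        lo, hi = thresholds["bone"]
        band = (intensity.grid >= lo) & (intensity.grid <= hi)
        lab, ncomp = ndimage.label(band)
        if ncomp < 4:
            raise ValueError("empty component: expected 4 vertebral bodies in the bone band")
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, ncomp + 1))
        keep = np.argsort(sizes)[::-1][:4] + 1
        cz = ndimage.center_of_mass(band, lab, keep)
        order = np.argsort([-c[2] for c in cz])  # cranial (high z) first
        for name, comp in zip(_VERT_ORDER, keep[order]):
            m = ndimage.binary_fill_holes(lab == comp)
            grid[m] = _VERT_LABEL[name]

    if "dural_sac" in thresholds:
        lo, hi = thresholds["dural_sac"]
        band = (intensity.grid >= lo) & (intensity.grid <= hi)
        lab, ncomp = ndimage.label(band)
        if ncomp == 0:
            raise ValueError("empty component: dural_sac")
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, ncomp + 1))
        m = ndimage.binary_fill_holes(lab == (int(np.argmax(sizes)) + 1))
        grid[m] = DURAL_LABEL

    if not grid.any():
        raise ValueError("empty component: no structure found")
    return LabelVolume(grid=grid, voxel_spacing=intensity.voxel_spacing,
                       orientation=intensity.orientation, label_map=dict(DEFAULT_LABEL_MAP))
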