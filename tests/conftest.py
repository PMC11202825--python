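import numpy as np
import pytest
from hypothesis import settings

from duravol.phantom import PhantomSpec, VertebraSpec, build_phantom, perturb_labels

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


def compact_spec(spacing: float = 1.0, noise_sigma_frac: float = 0.0,
                 ectasia_factor: float = 1.0) -> PhantomSpec:
    """Small lumbosacral phantom (vertebra height 20 mm, disc gap 4 mm,
    curved tapering dural sac) used throughout the suite."""
    cx, cy = 35.6, 44.3
    zc = {"L3": 118.4, "L4": 94.4, "L5": 70.4, "S1": 46.4}
    verts = {}
    for n, z in zc.items():
        if n == "S1":
            verts[n] = VertebraSpec(center=(cx, cy, z), height_mm=20, ap_semi_axis_mm=10,
                                    lat_semi_axis_mm=11, lat_concavity_mm=2,
                                    ap_concavity_mm=2)
        else:
            verts[n] = VertebraSpec(center=(cx, cy, z), height_mm=20, ap_semi_axis_mm=12,
                                    lat_semi_axis_mm=13, lat_concavity_mm=2)
    shape = tuple(int(round(d / spacing)) for d in (72, 72, 152))
    return PhantomSpec(voxel_spacing=spacing, grid_shape=shape, vertebrae=verts,
                       disc_gap_mm=4.0, dural_center_x=cx,
                       dural_centerline=[(24.0, 20.0), (46.0, 21.0), (94.0, 24.0), (140.0, 22.0)],
                       dural_radius=[(24.0, 4.0), (62.0, 4.8), (118.0, 6.5), (140.0, 6.5)],
                       ectasia_factor=ectasia_factor,
                       noise_sigma_frac=noise_sigma_frac)


def straight_spec(spacing: float = 1.0) -> PhantomSpec:
    """Straight-anatomy phantom: coaxial elliptic-cylinder bodies (no
    concavity) and a vertical constant-radius 8 mm dural tube; the true
    clipping planes are horizontal and 30 mm apart."""
    cx, cy = 35.6, 44.3
    zc = {"L3": 139.4, "L4": 109.4, "L5": 79.4, "S1": 49.4}
    verts = {n: VertebraSpec(center=(cx, cy, z), height_mm=26, ap_semi_axis_mm=12,
                             lat_semi_axis_mm=13)
             for n, z in zc.items()}
    shape = tuple(int(round(d / spacing)) for d in (72, 72, 184))
    return PhantomSpec(voxel_spacing=spacing, grid_shape=shape, vertebrae=verts,
                       disc_gap_mm=4.0, dural_center_x=cx,
                       dural_centerline=[(24.0, 22.0), (166.0, 22.0)],
                       dural_radius=[(24.0, 8.0), (166.0, 8.0)],
                       noise_sigma_frac=0.0)


@pytest.fixture(scope="session")
def compact_bundle():
    spec = compact_spec()
    intensity, labels, truth = build_phantom(spec, seed=11)
    return spec, intensity, labels, truth


@pytest.fixture(scope="session")
def straight_bundle():
    spec = straight_spec()
    intensity, labels, truth = build_phantom(spec, seed=11)
    return spec, intensity, labels, truth


@pytest.fixture(scope="session")
def perturbed_labels_05(compact_bundle):
    """Twenty 0.5 mm boundary-noise realisations of the compact phantom."""
    _, _, labels, _ = compact_bundle
    return [perturb_labels(labels, 0.5, seed=100 + i) for i in range(20)]
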