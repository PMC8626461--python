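"""Shared fixtures: small, fast synthetic configurations and datasets."""

import numpy as np
import pytest

from marrowmap.config import SyntheticConfig
from marrowmap.synthetic import Segment, VesselTree, generate_dataset, voxelize


def small_config(seed: int = 0, n_spots: int = 40) -> SyntheticConfig:
    """A ~96³-scale marrow phantom with reduced vessel calibres (fast)."""
    cfg = SyntheticConfig(shape=(32, 96, 96), spacing=(2.0, 1.0, 1.0), seed=seed)
    cfg.vessels.n_arterioles = 2
    cfg.vessels.radius_um = {"arterial": (5.0, 0.5), "type_h": (3.5, 0.4), "type_l": (6.0, 0.8)}
    cfg.vessels.segment_length_um = {
        "arterial": (50.0, 8.0),
        "type_h": (40.0, 5.0),
        "type_l": (45.0, 8.0),
    }
    cfg.bone.cortical_thickness_um = 8.0
    cfg.bone.n_trabecular_plates = 1
    cfg.bone.trabecular_extent_um = (25.0, 35.0)
    cfg.dtc.n_spots = n_spots
    cfg.sprouts.density_per_100um = 1.0
    return cfg


@pytest.fixture(scope="session")
def small_cfg() -> SyntheticConfig:
    return small_config()


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    return generate_dataset(small_cfg)


def tube_config(shape=(40, 40, 224), spacing=(1.0, 1.0, 1.0), lumen_fraction=0.5):
    """Config for analytic straight-tube fixtures (no bone, no spots)."""
    cfg = SyntheticConfig(shape=shape, spacing=spacing)
    cfg.bone.cortical_thickness_um = 0.0
    cfg.bone.n_trabecular_plates = 0
    cfg.vessels.lumen_fraction = lumen_fraction
    cfg.dtc.n_spots = 0
    return cfg


def straight_tube_masks(
    radius_um: float = 10.0,
    length_um: float = 200.0,
    spacing=(1.0, 1.0, 1.0),
    lumen_fraction: float = 0.5,
    subtype: str = "type_l",
    margin_um: float = 12.0,
):
    """Voxelized straight capsule along x, returning (cfg, tree, masks)."""
    sz, sy, sx = spacing
    half = radius_um + margin_um
    shape = (
        int(np.ceil(2 * half / sz)),
        int(np.ceil(2 * half / sy)),
        int(np.ceil((length_um + 2 * margin_um) / sx)),
    )
    cfg = tube_config(shape=shape, spacing=spacing, lumen_fraction=lumen_fraction)
    # centre on a voxel centre: exactly even-symmetric tubes are a known
    # degenerate case for topological thinning
    c_z = (shape[0] // 2) * sz
    c_y = (shape[1] // 2) * sy
    pts = np.array([[c_z, c_y, margin_um], [c_z, c_y, margin_um + length_um]])
    tree = VesselTree(
        segments=[Segment(0, subtype, None, pts, radius_um)], extent_um=cfg.extent_um
    )
    return cfg, tree, voxelize(tree, cfg)


def solid_cylinder_mask(radius_um=10.0, length_um=200.0, spacing=(1.0, 1.0, 1.0)):
    """Flat-ended solid cylinder along x (direct rasterization, no caps)."""
    from marrowmap.grid import StructureMask

    sz, sy, sx = spacing
    half = radius_um + 4
    nz, ny = int(2 * half / sz) + 1, int(2 * half / sy) + 1
    nx = int(length_um / sx)
    zz, yy = np.ogrid[:nz, :ny]
    cz, cy = (nz - 1) * sz / 2, (ny - 1) * sy / 2
    disc = (zz * sz - cz) ** 2 + (yy * sy - cy) ** 2 <= radius_um**2
    vox = np.repeat(disc[:, :, None], nx, axis=2)
    return StructureMask("cylinder", vox, spacing)
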