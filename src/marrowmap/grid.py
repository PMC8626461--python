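"""Core raster and point containers.

Conventions
-----------
Arrays are indexed ``(z, y, x)`` with physical voxel spacing ``(sz, sy, sx)``
in µm.  Voxel index ``i`` along an axis sits at physical position
``i * spacing`` (the origin is the centre of voxel 0), so all distances,
areas and lengths downstream are in µm-based units.  Channel intensities are
arbitrary non-negative units; the acquisition instrument scale is unknown and
never assumed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

CHANNEL_NAMES = ("nuclear", "cd31", "emcn", "tumour", "bone")

STRUCTURE_NAMES = (
    "bone_surface",
    "vessel_any",
    "arterial",
    "type_h",
    "type_l",
    "lumen",
    "marrow_admissible",
    "tumour_region",
)

#: Columns every spot table must carry, in canonical order.
SPOT_COLUMNS = ("id", "x_um", "y_um", "z_um", "radius_um", "kind")


@dataclass
class ImageVolume:
    """Multi-channel 3D intensity volume with anisotropic spacing.

    Parameters
    ----------
    channels
        Mapping channel name -> 3D array, shape ``(nz, ny, nx)``.
    spacing
        ``(sz, sy, sx)`` µm per voxel, each > 0.
    """

    channels: dict[str, np.ndarray]
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValidationError("ImageVolume needs at least one channel")
        shapes = {c.shape for c in self.channels.values()}
        if len(shapes) != 1:
            raise ValidationError(f"channels disagree on shape: {shapes}")
        (shape,) = shapes
        if len(shape) != 3:
            raise ValidationError("channels must be 3D (nz, ny, nx)")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be three positive µm values, got {self.spacing}")
        for name, arr in self.channels.items():
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"channel {name!r} has non-finite intensities")
            if np.any(arr < 0):
                raise ValidationError(f"channel {name!r} has negative intensities")

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def extent_um(self) -> tuple[float, float, float]:
        """Physical size (z, y, x) in µm, measured centre-of-first to centre-of-last voxel +1."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing))

    def channel(self, name: str) -> np.ndarray:
        if name not in self.channels:
            raise ValidationError(f"channel {name!r} not present (have {sorted(self.channels)})")
        return self.channels[name]


@dataclass
class StructureMask:
    """Binary mask of one anatomical structure class on the volume grid."""

    name: str
    voxels: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.ndim != 3:
            raise ValidationError("mask must be 3D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValidationError("mask spacing must be positive")

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.spacing))

    def volume_um3(self) -> float:
        return float(self.voxels.sum()) * self.voxel_volume_um3

    def is_empty(self) -> bool:
        return not bool(self.voxels.any())


@dataclass
class SpotSet:
    """Point objects (DTCs or null-model random spots) in physical µm coordinates.

    The table always carries :data:`SPOT_COLUMNS`; extra columns (quality,
    placement_class, is_cluster, ...) are preserved through I/O.
    """

    table: pd.DataFrame
    source: str = ""
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in SPOT_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValidationError(f"spot table missing columns: {missing}")
        if len(self.table) and self.table["id"].duplicated().any():
            raise ValidationError("spot ids must be unique")
        if len(self.table) and (self.table["radius_um"] <= 0).any():
            raise ValidationError("spot radii must be positive")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def coords_zyx(self) -> np.ndarray:
        """Spot centres as an ``(n, 3)`` array in (z, y, x) µm order."""
        return self.table[["z_um", "y_um", "x_um"]].to_numpy(dtype=float)

    @classmethod
    def from_coords_zyx(
        cls,
        coords: np.ndarray,
        radius_um: float | np.ndarray,
        kind: str,
        source: str = "",
        **extra_columns,
    ) -> "SpotSet":
        coords = np.atleast_2d(np.asarray(coords, dtype=float))
        if coords.size == 0:
            coords = coords.reshape(0, 3)
        tab = pd.DataFrame(
            {
                "id": np.arange(len(coords)),
                "x_um": coords[:, 2],
                "y_um": coords[:, 1],
                "z_um": coords[:, 0],
                "radius_um": np.broadcast_to(np.asarray(radius_um, dtype=float), len(coords)).copy(),
                "kind": kind,
            }
        )
        for name, values in extra_columns.items():
            tab[name] = values
        return cls(table=tab, source=source)


def vessel_union(masks: dict[str, StructureMask]) -> StructureMask:
    """Union of the three vessel-subtype masks (or an explicit vessel_any mask)."""
    if "vessel_any" in masks:
        return masks["vessel_any"]
    parts = [masks[k].voxels for k in ("arterial", "type_h", "type_l") if k in masks]
    if not parts:
        raise ValidationError("no vessel masks available")
    out = parts[0].copy()
    for p in parts[1:]:
        out |= p
    return StructureMask("vessel_any", out, masks[next(iter(masks))].spacing)
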