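"""Structured configuration for the synthetic generator and pipeline stages.

Every tunable lives in a dataclass with documented defaults and is
JSON-round-trippable; :func:`synthetic_config_from_dict` validates nested
dicts (unknown keys are configuration errors, not silently ignored).

Defaults describe a metaphyseal marrow field of view: a 256×256×64-voxel
stack at (2, 1, 1) µm spacing (~100 µm-deep confocal acquisition with z
undersampling), a hierarchical network of arterioles (radius ≈ 8 µm)
branching into type H capillaries (≈ 5 µm) and wide type L sinusoids
(≈ 12 µm), a cortical bone plate with trabecular spurs, and ~500 DTC-sized
(10 µm diameter) tumour spots placed with configurable preference for
perivascular, endosteal or type-H-adjacent shells of 10 µm.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

from .errors import ConfigurationError, ValidationError


@dataclass
class VesselNetworkConfig:
    n_arterioles: int = 3
    branch_factor: int = 2
    #: per-subtype radius mean and s.d. in µm
    radius_um: dict = field(
        default_factory=lambda: {
            "arterial": (8.0, 1.0),
            "type_h": (6.0, 0.7),
            "type_l": (12.0, 1.5),
        }
    )
    #: per-subtype segment length mean and s.d. in µm
    segment_length_um: dict = field(
        default_factory=lambda: {
            "arterial": (120.0, 20.0),
            "type_h": (90.0, 12.0),
            "type_l": (90.0, 15.0),
        }
    )
    lumen_fraction: float = 0.5
    #: bounded perpendicular jitter of centerline waypoints, µm
    tortuosity_um: float = 4.0
    #: spacing between centerline waypoints, µm
    waypoint_step_um: float = 10.0

    def validate(self) -> None:
        if self.n_arterioles < 0 or self.branch_factor < 1:
            raise ValidationError("n_arterioles must be >= 0 and branch_factor >= 1")
        for sub in ("arterial", "type_h", "type_l"):
            mean, sd = self.radius_um[sub]
            if mean <= 0 or sd < 0:
                raise ValidationError(f"radius for {sub} must be positive (sd >= 0)")
            mean, sd = self.segment_length_um[sub]
            if mean <= 0 or sd < 0:
                raise ValidationError(f"segment length for {sub} must be positive")
        if not 0.0 <= self.lumen_fraction < 1.0:
            raise ValidationError("lumen_fraction must be in [0, 1)")
        if self.tortuosity_um < 0 or self.waypoint_step_um <= 0:
            raise ValidationError("tortuosity must be >= 0 and waypoint step > 0")


@dataclass
class BoneConfig:
    #: cortical shell thickness along the x=0 face, µm (0 disables)
    cortical_thickness_um: float = 12.0
    n_trabecular_plates: int = 2
    trabecular_thickness_um: float = 8.0
    #: in-plane extent of each trabecular plate, (x_len, z_len) µm
    trabecular_extent_um: tuple = (40.0, 60.0)
    #: metaphyseal band along y where trabecular plates live, as fractions of the y extent
    metaphyseal_band: tuple = (0.1, 0.6)

    def validate(self) -> None:
        if self.cortical_thickness_um < 0 or self.trabecular_thickness_um <= 0:
            raise ValidationError("bone thicknesses must be non-negative / positive")
        if self.n_trabecular_plates < 0:
            raise ValidationError("n_trabecular_plates must be >= 0")
        lo, hi = self.metaphyseal_band
        if not (0 <= lo < hi <= 1):
            raise ValidationError("metaphyseal_band must be an increasing pair in [0, 1]")


@dataclass
class IntensityConfig:
    """Class-conditional mean intensities (arbitrary units) and the noise model.

    Arterial vessels render CD31-high / EMCN-at-background, type H high in
    both channels, type L low-positive in both; these separations make the
    data gateable by per-channel 3-class Otsu at the default noise level.
    """

    cd31_means: dict = field(
        default_factory=lambda: {"arterial": 200.0, "type_h": 200.0, "type_l": 60.0}
    )
    emcn_means: dict = field(
        default_factory=lambda: {"arterial": 5.0, "type_h": 200.0, "type_l": 60.0}
    )
    background_cd31: float = 5.0
    background_emcn: float = 5.0
    noise_sd: float = 10.0
    blur_sigma_um: float = 0.0
    nuclear_background: float = 40.0
    nuclear_texture_sd: float = 8.0
    nuclear_texture_scale_um: float = 4.0
    tumour_intensity: float = 150.0
    tumour_background: float = 5.0

    def validate(self) -> None:
        if self.noise_sd < 0 or self.blur_sigma_um < 0:
            raise ValidationError("noise_sd and blur_sigma_um must be >= 0")
        for d in (self.cd31_means, self.emcn_means):
            for sub in ("arterial", "type_h", "type_l"):
                if sub not in d:
                    raise ValidationError(f"intensity means missing subtype {sub!r}")


@dataclass
class SproutConfig:
    #: expected sprout anchors per 100 µm of vessel length (Poisson rate)
    density_per_100um: float = 1.0
    length_um: tuple = (8.0, 2.0)
    radius_um: float = 1.5
    #: subtypes that carry sprouts; arterioles are spared by default
    subtypes: tuple = ("type_h", "type_l")

    def validate(self) -> None:
        if self.density_per_100um < 0:
            raise ValidationError("sprout density must be >= 0")
        mean, sd = self.length_um
        if mean <= 0 or sd < 0 or self.radius_um <= 0:
            raise ValidationError("sprout length/radius must be positive")


@dataclass
class DtcConfig:
    n_spots: int = 500
    #: spot radius, µm (10 µm diameter DTC convention)
    radius_um: float = 5.0
    #: placement mix; the remainder to 1 is placed uniformly in admissible marrow
    placement_mix: dict = field(
        default_factory=lambda: {
            "perivascular_any": 0.5,
            "near_bone": 0.05,
            "near_type_h": 0.2,
        }
    )
    #: "near" means centre within this distance of the target structure, µm
    shell_um: float = 10.0
    #: minimum centre-to-centre separation between spots (clusters count once)
    min_separation_um: float = 12.0

    def validate(self) -> None:
        if self.n_spots < 0:
            raise ValidationError("n_spots must be >= 0")
        if self.radius_um <= 0 or self.shell_um <= 0:
            raise ValidationError("spot radius and shell distance must be > 0")
        if self.min_separation_um < 0:
            raise ValidationError("min_separation_um must be >= 0")
        fracs = list(self.placement_mix.values())
        if any(not 0 <= f <= 1 for f in fracs) or sum(fracs) > 1 + 1e-9:
            raise ValidationError("placement fractions must lie in [0,1] and sum to <= 1")
        known = {"perivascular_any", "near_bone", "near_type_h"}
        unknown = set(self.placement_mix) - known
        if unknown:
            raise ValidationError(f"unknown placement classes: {sorted(unknown)}")


@dataclass
class SyntheticConfig:
    shape: tuple = (64, 256, 256)
    spacing: tuple = (2.0, 1.0, 1.0)
    vessels: VesselNetworkConfig = field(default_factory=VesselNetworkConfig)
    bone: BoneConfig = field(default_factory=BoneConfig)
    intensity: IntensityConfig = field(default_factory=IntensityConfig)
    sprouts: SproutConfig = field(default_factory=SproutConfig)
    dtc: DtcConfig = field(default_factory=DtcConfig)
    seed: int = 0

    def validate(self) -> None:
        if len(self.shape) != 3 or any(int(n) <= 0 for n in self.shape):
            raise ValidationError(f"shape must be three positive ints, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be three positive µm values, got {self.spacing}")
        self.vessels.validate()
        self.bone.validate()
        self.intensity.validate()
        self.sprouts.validate()
        self.dtc.validate()

    @property
    def extent_um(self) -> tuple:
        return tuple(int(n) * float(s) for n, s in zip(self.shape, self.spacing))


_SECTION_TYPES = {
    "vessels": VesselNetworkConfig,
    "bone": BoneConfig,
    "intensity": IntensityConfig,
    "sprouts": SproutConfig,
    "dtc": DtcConfig,
}


def _build_section(cls, data: dict, path: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigurationError(f"{path}: unknown keys {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        if key in ("radius_um", "segment_length_um") and isinstance(value, dict):
            value = {k: tuple(v) if isinstance(v, (list, tuple)) else v for k, v in value.items()}
        elif isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


def synthetic_config_from_dict(data: dict) -> SyntheticConfig:
    """Build and validate a :class:`SyntheticConfig` from a (JSON) dict."""
    data = dict(data)
    kwargs = {}
    for section, cls in _SECTION_TYPES.items():
        if section in data:
            sec = data.pop(section)
            if not isinstance(sec, dict):
                raise ConfigurationError(f"synthetic.{section} must be an object")
            kwargs[section] = _build_section(cls, sec, f"synthetic.{section}")
    top = {f.name for f in dataclasses.fields(SyntheticConfig)} - set(_SECTION_TYPES)
    unknown = set(data) - top
    if unknown:
        raise ConfigurationError(f"synthetic: unknown keys {sorted(unknown)}")
    for key in ("shape", "spacing"):
        if key in data:
            data[key] = tuple(data[key])
    cfg = SyntheticConfig(**data, **kwargs)
    cfg.validate()
    return cfg


def synthetic_config_to_dict(cfg: SyntheticConfig) -> dict:
    return dataclasses.asdict(cfg)
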