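"""Vessel subtype phenotyping from joint CD31–EMCN voxel intensities.

The marrow endothelium separates into three phenotypes in CD31/EMCN
intensity space: arterial (CD31-high, EMCN-negative), type H capillaries
(high in both) and type L sinusoids (low-positive in both).  This module
derives the intensity gates (3-class Otsu per channel by default, manual
override available), classifies voxels, and extracts per-vessel connected
components with summary statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal
from skimage.filters import threshold_multiotsu

from .errors import GatingError, ValidationError
from .grid import ImageVolume

LABELS = {"background": 0, "arterial": 1, "type_h": 2, "type_l": 3}
LABEL_NAMES = {v: k for k, v in LABELS.items()}
_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class GateConfig:
    """Intensity thresholds splitting CD31/EMCN space into subtype gates."""

    vessel_presence: float  # CD31 below this is background
    cd31_lo_hi: float
    emcn_neg_lo: float
    emcn_lo_hi: float
    strategy: str = "auto"

    def __post_init__(self) -> None:
        vals = (self.vessel_presence, self.cd31_lo_hi, self.emcn_neg_lo, self.emcn_lo_hi)
        if not all(np.isfinite(v) for v in vals):
            raise ValidationError("gate thresholds must be finite")
        if self.vessel_presence > self.cd31_lo_hi:
            raise ValidationError("vessel_presence must be <= cd31_lo_hi")
        if self.emcn_neg_lo > self.emcn_lo_hi:
            raise ValidationError("emcn_neg_lo must be <= emcn_lo_hi")


@dataclass
class VesselClassMap:
    labels: np.ndarray  # uint8 per-voxel label per LABELS
    gates: GateConfig
    spacing: tuple[float, float, float]


@dataclass
class VesselComponent:
    id: int
    subtype: str
    voxel_indices: np.ndarray  # flat indices into the volume grid
    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    volume_um3: float
    bbox: tuple  # ((z0,z1),(y0,y1),(x0,x1)) half-open
    mean_cd31: float = np.nan
    mean_emcn: float = np.nan

    def mask(self) -> np.ndarray:
        out = np.zeros(self.shape, dtype=bool)
        out.ravel()[self.voxel_indices] = True
        return out


def joint_intensity_histogram(
    vol: ImageVolume,
    bins: int = 64,
    vessel_mask: np.ndarray | None = None,
):
    """2D voxel-count histogram over (CD31, EMCN) intensity, the gating density plot."""
    if bins < 2:
        raise ValidationError("bins must be >= 2")
    cd31 = vol.channel("cd31").ravel()
    emcn = vol.channel("emcn").ravel()
    if vessel_mask is not None:
        keep = np.asarray(vessel_mask, dtype=bool).ravel()
        cd31, emcn = cd31[keep], emcn[keep]
    hist, cd31_edges, emcn_edges = np.histogram2d(cd31, emcn, bins=bins)
    return hist, cd31_edges, emcn_edges


def _n_modes(values: np.ndarray, nbins: int = 128) -> int:
    """Count peaks in the smoothed log-histogram (coarse multimodality check)."""
    hist, _ = np.histogram(values, bins=nbins)
    smooth = ndimage.gaussian_filter1d(np.log1p(hist.astype(float)), sigma=2.0)
    # a peak flush against either edge is not found by find_peaks; pad
    padded = np.concatenate([[smooth.min()], smooth, [smooth.min()]])
    peaks, _ = signal.find_peaks(padded, prominence=1.0)
    return int(len(peaks))


def _multiotsu_or_raise(values: np.ndarray, channel: str) -> tuple[float, float]:
    if np.unique(values[: 200000] if values.size > 200000 else values).size < 3:
        raise GatingError(
            f"{channel}: fewer than 3 distinct intensity levels; supply manual gates"
        )
    if _n_modes(values) < 2:
        raise GatingError(
            f"{channel}: intensity histogram looks unimodal; automatic gating is "
            "unreliable — supply manual gates"
        )
    try:
        t1, t2 = threshold_multiotsu(values, classes=3)
    except ValueError as err:
        raise GatingError(f"{channel}: 3-class Otsu failed ({err}); supply manual gates") from err
    return float(t1), float(t2)


def derive_gates(vol: ImageVolume, strategy: str = "auto", manual: GateConfig | None = None) -> GateConfig:
    """Derive intensity gates.

    ``auto``: vessel_presence and cd31_lo_hi from 3-class Otsu on CD31 over
    all voxels; EMCN thresholds from 3-class Otsu over vessel-presence
    voxels.  ``manual``: the supplied :class:`GateConfig` is returned
    verbatim (strategy tag set to manual).
    """
    if strategy == "manual":
        if manual is None:
            raise ValidationError("manual strategy requires a GateConfig")
        manual.strategy = "manual"
        return manual
    if strategy != "auto":
        raise ValidationError(f"unknown gating strategy {strategy!r}")
    cd31 = vol.channel("cd31").ravel()
    presence, cd31_hi = _multiotsu_or_raise(cd31, "cd31")
    vessel_vox = cd31 >= presence
    if not vessel_vox.any():
        raise GatingError("no voxels above the CD31 presence threshold")
    emcn = vol.channel("emcn").ravel()[vessel_vox]
    emcn_neg, emcn_hi = _multiotsu_or_raise(emcn, "emcn")
    return GateConfig(
        vessel_presence=presence,
        cd31_lo_hi=cd31_hi,
        emcn_neg_lo=emcn_neg,
        emcn_lo_hi=emcn_hi,
        strategy="auto",
    )


def classify_voxels(vol: ImageVolume, gates: GateConfig) -> VesselClassMap:
    """Assign every voxel to background / arterial / type_h / type_l.

    Primary rules: below ``vessel_presence`` on CD31 is background;
    CD31-high with EMCN below ``emcn_neg_lo`` is arterial; CD31-high with
    EMCN at/above ``emcn_lo_hi`` is type H; CD31-low-positive with EMCN in
    the low band is type L.  Voxels falling between gates (the hand-drawn
    gates of the original protocol leave these undefined) go to the class
    with the nearest intensity centroid in normalized gate space.
    """
    cd31 = vol.channel("cd31")
    emcn = vol.channel("emcn")
    labels = np.zeros(cd31.shape, dtype=np.uint8)
    present = cd31 >= gates.vessel_presence
    hi = cd31 >= gates.cd31_lo_hi
    e_neg = emcn < gates.emcn_neg_lo
    e_hi = emcn >= gates.emcn_lo_hi
    e_mid = ~e_neg & ~e_hi

    labels[present & hi & e_neg] = LABELS["arterial"]
    labels[present & hi & e_hi] = LABELS["type_h"]
    labels[present & ~hi & e_mid] = LABELS["type_l"]
    leftover = present & ((hi & e_mid) | (~hi & (e_neg | e_hi)))

    if leftover.any():
        # centroids of the primary-assigned classes, falling back to gate-derived
        # nominal centres when a class is empty
        scale_c = max(float(cd31[present].std()), 1e-9)
        scale_e = max(float(emcn[present].std()), 1e-9)
        nominal = {
            "arterial": (gates.cd31_lo_hi * 1.5, gates.emcn_neg_lo * 0.5),
            "type_h": (gates.cd31_lo_hi * 1.5, gates.emcn_lo_hi * 1.5),
            "type_l": ((gates.vessel_presence + gates.cd31_lo_hi) / 2,
                       (gates.emcn_neg_lo + gates.emcn_lo_hi) / 2),
        }
        cents = []
        for name in ("arterial", "type_h", "type_l"):
            sel = labels == LABELS[name]
            if sel.any():
                cents.append((float(cd31[sel].mean()), float(emcn[sel].mean())))
            else:
                cents.append(nominal[name])
        cents = np.asarray(cents)
        dc = (cd31[leftover][:, None] - cents[None, :, 0]) / scale_c
        de = (emcn[leftover][:, None] - cents[None, :, 1]) / scale_e
        nearest = np.argmin(dc**2 + de**2, axis=1)
        labels[leftover] = nearest.astype(np.uint8) + 1
    return VesselClassMap(labels=labels, gates=gates, spacing=vol.spacing)


def extract_components(
    class_map: VesselClassMap, min_volume_um3: float = 500.0
) -> list[VesselComponent]:
    """26-connected components per subtype, with small-islet continuity merging.

    Components below ``min_volume_um3`` that touch (26-adjacency) a kept
    component of another subtype are relabelled into it — a misgated speck
    inside a continuous vessel belongs to that vessel; isolated small specks
    are dropped.
    """
    spacing = class_map.spacing
    voxel_vol = float(np.prod(spacing))
    labels = class_map.labels
    shape = labels.shape

    comp_label = np.zeros(shape, dtype=np.int32)
    comp_subtype: dict[int, str] = {}
    next_id = 1
    for name in ("arterial", "type_h", "type_l"):
        lab, n = ndimage.label(labels == LABELS[name], structure=_CONN26)
        if n:
            comp_label[lab > 0] = lab[lab > 0] + (next_id - 1)
            for k in range(1, n + 1):
                comp_subtype[next_id - 1 + k] = name
            next_id += n

    sizes = np.bincount(comp_label.ravel(), minlength=next_id)
    min_vox = min_volume_um3 / voxel_vol
    small = [cid for cid in range(1, next_id) if 0 < sizes[cid] < min_vox]
    kept = {cid for cid in range(1, next_id) if sizes[cid] >= min_vox}

    slices = ndimage.find_objects(comp_label)
    for cid in small:
        sl = slices[cid - 1]
        grown = tuple(
            slice(max(s.start - 1, 0), min(s.stop + 1, dim)) for s, dim in zip(sl, shape)
        )
        region = comp_label[grown]
        here = region == cid
        ring = ndimage.binary_dilation(here, structure=_CONN26) & ~here
        neighbours = np.unique(region[ring])
        neighbours = [
            n for n in neighbours if n in kept and comp_subtype[n] != comp_subtype[cid]
        ]
        if neighbours:
            target = max(neighbours, key=lambda n: sizes[n])
            comp_label[grown][here] = target
            sizes[target] += sizes[cid]
        else:
            comp_label[grown][here] = 0
        sizes[cid] = 0

    out = []
    final_slices = ndimage.find_objects(comp_label)
    for cid in sorted(kept):
        sl = final_slices[cid - 1]
        if sl is None:
            continue
        flat = np.flatnonzero((comp_label == cid).ravel())
        bbox = tuple((s.start, s.stop) for s in sl)
        out.append(
            VesselComponent(
                id=cid,
                subtype=comp_subtype[cid],
                voxel_indices=flat,
                shape=shape,
                spacing=spacing,
                volume_um3=float(len(flat)) * voxel_vol,
                bbox=bbox,
            )
        )
    return out


def vessel_mean_intensity(comp: VesselComponent, vol: ImageVolume) -> tuple[float, float]:
    """Arithmetic mean CD31 and EMCN intensity over the component's voxels."""
    if comp.voxel_indices.size == 0:
        raise ValidationError("component has no voxels")
    cd31 = vol.channel("cd31").ravel()[comp.voxel_indices].mean()
    emcn = vol.channel("emcn").ravel()[comp.voxel_indices].mean()
    comp.mean_cd31 = float(cd31)
    comp.mean_emcn = float(emcn)
    return float(cd31), float(emcn)
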