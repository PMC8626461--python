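"""Synthetic bone-marrow phantom with exhaustive ground truth.

Generates 3D multi-channel stacks that emulate cleared-marrow confocal
imaging: a hierarchical vessel network (arterioles branching into type H
capillaries, then type L sinusoids) modelled as capsule unions around
tortuous polyline centerlines, a cortical bone plate with trabecular spurs,
thin endothelial sprouts, and DTC-sized tumour spots placed with
configurable spatial preference.  Every stage records generator-side truth
(masks, spot placements, sprout inventory, per-vessel geometry) so that the
measurement stages can be tested against known answers.

Geometry is in physical µm throughout; arrays are (z, y, x).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .config import SyntheticConfig
from .errors import GenerationError, ValidationError
from .grid import ImageVolume, SpotSet, StructureMask

SUBTYPES = ("arterial", "type_h", "type_l")
_SUBTYPE_LABEL = {"arterial": 1, "type_h": 2, "type_l": 3}


@dataclass
class Segment:
    """One vessel segment: a polyline centerline with constant radius."""

    id: int
    subtype: str
    parent: int | None
    points: np.ndarray  # (n, 3) physical (z, y, x) µm
    radius_um: float

    def length_um(self) -> float:
        d = np.diff(self.points, axis=0)
        return float(np.sqrt((d**2).sum(axis=1)).sum())


@dataclass
class Sprout:
    """A thin endothelial protrusion anchored on a parent segment's wall."""

    parent_segment: int
    anchor: np.ndarray  # (3,) zyx µm, on the vessel surface
    direction: np.ndarray  # (3,) unit vector, outward
    length_um: float
    radius_um: float


@dataclass
class VesselTree:
    segments: list[Segment] = field(default_factory=list)
    sprouts: list[Sprout] = field(default_factory=list)
    extent_um: tuple = (0.0, 0.0, 0.0)

    def by_subtype(self, subtype: str) -> list[Segment]:
        return [s for s in self.segments if s.subtype == subtype]

    def total_length_um(self, subtypes=SUBTYPES) -> float:
        return sum(s.length_um() for s in self.segments if s.subtype in subtypes)

    def validate_hierarchy(self) -> None:
        """Subtype along any root-to-leaf path follows arterial -> type_h -> type_l."""
        order = {"arterial": 0, "type_h": 1, "type_l": 2}
        by_id = {s.id: s for s in self.segments}
        for seg in self.segments:
            if seg.parent is not None:
                parent = by_id[seg.parent]
                if order[seg.subtype] != order[parent.subtype] + 1:
                    raise ValidationError(
                        f"segment {seg.id} breaks hierarchy: {parent.subtype} -> {seg.subtype}"
                    )


@dataclass
class GroundTruth:
    """Generator-side truth used as the oracle for every measurement stage."""

    masks: dict[str, StructureMask]
    spots: SpotSet
    sprouts: pd.DataFrame
    vessels: pd.DataFrame
    tree: VesselTree
    seed: int


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero vector")
    return v / n


def _random_perpendicular(rng: np.random.Generator, d: np.ndarray) -> np.ndarray:
    while True:
        v = rng.normal(size=3)
        v -= v.dot(d) * d
        n = np.linalg.norm(v)
        if n > 1e-6:
            return v / n


def _rotate_towards(d: np.ndarray, perp: np.ndarray, angle_rad: float) -> np.ndarray:
    return _unit(np.cos(angle_rad) * d + np.sin(angle_rad) * perp)


def _polyline(
    rng: np.random.Generator,
    start: np.ndarray,
    direction: np.ndarray,
    length_um: float,
    step_um: float,
    jitter_um: float,
    lo: np.ndarray,
    hi: np.ndarray,
) -> np.ndarray:
    """Tortuous polyline of the requested arc length, reflected at the box walls."""
    pts = [np.clip(start, lo, hi)]
    d = _unit(direction)
    n_steps = max(2, int(round(length_um / step_um)))
    for _ in range(n_steps):
        jitter = rng.normal(scale=jitter_um / 2.0, size=3) if jitter_um > 0 else np.zeros(3)
        jitter -= jitter.dot(d) * d  # perpendicular jitter only
        jitter = np.clip(jitter, -jitter_um, jitter_um)
        p = pts[-1] + d * step_um + jitter
        for ax in range(3):  # reflect at the walls, flipping the travel direction
            if p[ax] < lo[ax]:
                p[ax] = 2 * lo[ax] - p[ax]
                d[ax] = -d[ax]
            elif p[ax] > hi[ax]:
                p[ax] = 2 * hi[ax] - p[ax]
                d[ax] = -d[ax]
        d = _unit(d)
        pts.append(np.clip(p, lo, hi))
    return np.asarray(pts)


def build_vessel_tree(cfg: SyntheticConfig, rng: np.random.Generator | int | None = None) -> VesselTree:
    """Grow the arteriole -> type H -> type L hierarchy inside the volume.

    Each arteriole runs roughly along y, branches into ``branch_factor``
    type H capillaries, each of which feeds ``branch_factor`` type L
    sinusoids.  Tortuosity is bounded random perpendicular jitter of the
    centerline waypoints.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    vc = cfg.vessels
    extent = np.asarray(cfg.extent_um, dtype=float)
    max_r = max(mean for mean, _ in vc.radius_um.values())
    if np.any(extent < 6 * max_r):
        raise GenerationError(
            f"grid extent {tuple(extent)} µm too small for vessels of radius {max_r} µm; "
            f"each axis must span at least {6 * max_r} µm"
        )
    margin = max_r + 2.0
    lo = np.full(3, margin)
    hi = extent - margin

    def draw(pair):
        mean, sd = pair
        return max(0.5, float(rng.normal(mean, sd))) if sd > 0 else float(mean)

    tree = VesselTree(extent_um=tuple(extent))
    next_id = 0
    for _ in range(vc.n_arterioles):
        start = np.array(
            [
                rng.uniform(lo[0] + 0.15 * extent[0], hi[0] - 0.15 * extent[0]) if hi[0] - lo[0] > 0.3 * extent[0] else (lo[0] + hi[0]) / 2,
                lo[1],
                rng.uniform(lo[2] + 0.15 * extent[2], hi[2] - 0.15 * extent[2]) if hi[2] - lo[2] > 0.3 * extent[2] else (lo[2] + hi[2]) / 2,
            ]
        )
        d0 = _unit(np.array([rng.normal(0, 0.15), 1.0, rng.normal(0, 0.15)]))
        art = Segment(
            id=next_id,
            subtype="arterial",
            parent=None,
            points=_polyline(rng, start, d0, draw(vc.segment_length_um["arterial"]),
                             vc.waypoint_step_um, vc.tortuosity_um, lo, hi),
            radius_um=draw(vc.radius_um["arterial"]),
        )
        tree.segments.append(art)
        next_id += 1
        h_segments = []
        end = art.points[-1]
        d_end = _unit(art.points[-1] - art.points[-2])
        perp0 = _random_perpendicular(rng, d_end)
        for k in range(vc.branch_factor):
            phi = 2 * np.pi * k / vc.branch_factor + rng.uniform(-0.3, 0.3)
            perp = _unit(np.cos(phi) * perp0 + np.sin(phi) * np.cross(d_end, perp0))
            d_child = _rotate_towards(d_end, perp, np.deg2rad(rng.uniform(25, 55)))
            seg = Segment(
                id=next_id,
                subtype="type_h",
                parent=art.id,
                points=_polyline(rng, end.copy(), d_child, draw(vc.segment_length_um["type_h"]),
                                 vc.waypoint_step_um, vc.tortuosity_um, lo, hi),
                radius_um=draw(vc.radius_um["type_h"]),
            )
            tree.segments.append(seg)
            h_segments.append(seg)
            next_id += 1
        for h in h_segments:
            end_h = h.points[-1]
            d_h = _unit(h.points[-1] - h.points[-2])
            perp0 = _random_perpendicular(rng, d_h)
            for k in range(vc.branch_factor):
                phi = 2 * np.pi * k / vc.branch_factor + rng.uniform(-0.3, 0.3)
                perp = _unit(np.cos(phi) * perp0 + np.sin(phi) * np.cross(d_h, perp0))
                d_child = _rotate_towards(d_h, perp, np.deg2rad(rng.uniform(25, 55)))
                seg = Segment(
                    id=next_id,
                    subtype="type_l",
                    parent=h.id,
                    points=_polyline(rng, end_h.copy(), d_child, draw(vc.segment_length_um["type_l"]),
                                     vc.waypoint_step_um, vc.tortuosity_um, lo, hi),
                    radius_um=draw(vc.radius_um["type_l"]),
                )
                tree.segments.append(seg)
                next_id += 1
    tree.validate_hierarchy()
    return tree


def add_sprouts(tree: VesselTree, cfg: SyntheticConfig, rng: np.random.Generator) -> VesselTree:
    """Append Poisson-distributed sprout records along selected-subtype segments.

    The anchor count on a segment of length L is Poisson with mean
    ``density_per_100um * L / 100``; anchors sit on the vessel surface and
    sprout lengths are Gaussian draws truncated at 1 µm.
    """
    sc = cfg.sprouts
    if sc.density_per_100um < 0:
        raise ValidationError("sprout density must be >= 0")
    if not tree.segments:
        raise ValidationError("tree has no segments")
    if sc.density_per_100um == 0:
        return tree
    for seg in tree.segments:
        if seg.subtype not in sc.subtypes:
            continue
        L = seg.length_um()
        n = rng.poisson(sc.density_per_100um * L / 100.0)
        if n == 0:
            continue
        # arc-length positions of the anchors
        d = np.diff(seg.points, axis=0)
        steps = np.sqrt((d**2).sum(axis=1))
        cum = np.concatenate([[0.0], np.cumsum(steps)])
        for t in rng.uniform(0, cum[-1], size=n):
            i = min(np.searchsorted(cum, t) - 1, len(steps) - 1)
            i = max(i, 0)
            frac = (t - cum[i]) / steps[i] if steps[i] > 0 else 0.0
            centre = seg.points[i] + frac * d[i]
            tangent = _unit(d[i])
            outward = _random_perpendicular(rng, tangent)
            length = max(1.0, float(rng.normal(*sc.length_um)))
            tree.sprouts.append(
                Sprout(
                    parent_segment=seg.id,
                    anchor=centre + outward * seg.radius_um,
                    direction=outward,
                    length_um=length,
                    radius_um=sc.radius_um,
                )
            )
    return tree


def _stamp_capsules(
    label: np.ndarray,
    best: np.ndarray,
    lumen: np.ndarray | None,
    points: np.ndarray,
    radius_um: float,
    lumen_radius_um: float,
    code: int,
    spacing: np.ndarray,
    step_um: float,
) -> None:
    """Rasterize a polyline capsule; ties go to the nearest centerline sample."""
    shape = np.asarray(label.shape)
    # resample the polyline at sub-voxel arc steps
    d = np.diff(points, axis=0)
    steps = np.sqrt((d**2).sum(axis=1))
    total = steps.sum()
    n_samples = max(2, int(np.ceil(total / step_um)) + 1)
    t = np.linspace(0, total, n_samples)
    cum = np.concatenate([[0.0], np.cumsum(steps)])
    idx = np.clip(np.searchsorted(cum, t) - 1, 0, len(steps) - 1)
    frac = np.where(steps[idx] > 0, (t - cum[idx]) / np.where(steps[idx] > 0, steps[idx], 1), 0)
    samples = points[idx] + frac[:, None] * d[idx]

    r2 = radius_um**2
    lr2 = lumen_radius_um**2
    for p in samples:
        lo = np.maximum(np.ceil((p - radius_um) / spacing).astype(int), 0)
        hi = np.minimum(np.floor((p + radius_um) / spacing).astype(int), shape - 1)
        if np.any(lo > hi):
            continue
        zz = (np.arange(lo[0], hi[0] + 1) * spacing[0] - p[0]) ** 2
        yy = (np.arange(lo[1], hi[1] + 1) * spacing[1] - p[1]) ** 2
        xx = (np.arange(lo[2], hi[2] + 1) * spacing[2] - p[2]) ** 2
        dist2 = zz[:, None, None] + yy[None, :, None] + xx[None, None, :]
        sl = (slice(lo[0], hi[0] + 1), slice(lo[1], hi[1] + 1), slice(lo[2], hi[2] + 1))
        inside = dist2 <= r2
        closer = inside & (dist2 < best[sl])
        best[sl][closer] = dist2[closer]
        label[sl][closer] = code
        if lumen is not None and lumen_radius_um > 0:
            lumen[sl] |= dist2 <= lr2


def _bone_voxels(cfg: SyntheticConfig, rng: np.random.Generator, shape) -> np.ndarray:
    bone = np.zeros(shape, dtype=bool)
    bc = cfg.bone
    sz, sy, sx = cfg.spacing
    ez, ey, ex = cfg.extent_um
    if bc.cortical_thickness_um > 0:
        nx_cort = int(np.ceil(bc.cortical_thickness_um / sx))
        bone[:, :, : min(nx_cort, shape[2])] = True
    x_len, z_len = bc.trabecular_extent_um
    band_lo, band_hi = bc.metaphyseal_band
    for _ in range(bc.n_trabecular_plates):
        y0 = rng.uniform(band_lo * ey, band_hi * ey)
        z0 = rng.uniform(0, max(ez - z_len, 1e-6))
        x0 = bc.cortical_thickness_um
        zi = slice(int(z0 / sz), int(np.ceil((z0 + z_len) / sz)))
        yi = slice(int(y0 / sy), int(np.ceil((y0 + bc.trabecular_thickness_um) / sy)))
        xi = slice(int(x0 / sx), int(np.ceil((x0 + x_len) / sx)))
        bone[zi, yi, xi] = True
    return bone


def voxelize(
    tree: VesselTree,
    cfg: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> dict[str, StructureMask]:
    """Rasterize the tree into per-subtype, lumen, bone and admissible masks.

    A voxel belongs to a vessel iff its centre lies within the local radius
    of a centerline sample (capsule union); overlapping subtypes resolve to
    the nearest centerline sample.  The lumen occupies ``lumen_fraction`` of
    each radius.  ``marrow_admissible`` is everything outside vessels and
    bone — the region where DTCs occur and random spots may be drawn.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    shape = tuple(int(n) for n in cfg.shape)
    spacing = np.asarray(cfg.spacing, dtype=float)
    label = np.zeros(shape, dtype=np.uint8)
    best = np.full(shape, np.inf, dtype=np.float32)
    lumen = np.zeros(shape, dtype=bool)
    step = float(min(spacing)) / 2.0

    for seg in tree.segments:
        _stamp_capsules(
            label, best, lumen, seg.points, seg.radius_um,
            seg.radius_um * cfg.vessels.lumen_fraction,
            _SUBTYPE_LABEL[seg.subtype], spacing, step,
        )
    subtype_of = {s.id: s.subtype for s in tree.segments}
    for spr in tree.sprouts:
        pts = np.stack([spr.anchor, spr.anchor + spr.direction * spr.length_um])
        _stamp_capsules(
            label, best, None, pts, spr.radius_um, 0.0,
            _SUBTYPE_LABEL[subtype_of[spr.parent_segment]], spacing, step,
        )

    vessel = label > 0
    lumen &= vessel
    bone = _bone_voxels(cfg, rng, shape) & ~vessel
    admissible = ~(vessel | bone)
    sp = tuple(cfg.spacing)
    masks = {
        "arterial": StructureMask("arterial", label == 1, sp),
        "type_h": StructureMask("type_h", label == 2, sp),
        "type_l": StructureMask("type_l", label == 3, sp),
        "vessel_any": StructureMask("vessel_any", vessel, sp),
        "lumen": StructureMask("lumen", lumen, sp),
        "bone_surface": StructureMask("bone_surface", bone, sp),
        "marrow_admissible": StructureMask("marrow_admissible", admissible, sp),
    }
    return masks


def render_channels(
    masks: dict[str, StructureMask],
    cfg: SyntheticConfig,
    rng: np.random.Generator | None = None,
    spots: SpotSet | None = None,
    channels: tuple[str, ...] = ("nuclear", "cd31", "emcn", "tumour"),
) -> ImageVolume:
    """Render intensity channels from the structure masks.

    CD31/EMCN take the per-subtype mean plus Gaussian noise (then optional
    blur); the tumour channel renders spots as solid spheres; the nuclear
    channel is a smooth marrow background texture.  Intensities clip at 0.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    ic = cfg.intensity
    known = set(masks)
    for sub in SUBTYPES:
        if sub not in known:
            raise GenerationError(f"mask set lacks subtype {sub!r}")
    shape = masks["arterial"].voxels.shape
    spacing = np.asarray(masks["arterial"].spacing, dtype=float)
    out: dict[str, np.ndarray] = {}

    def _marker(background: float, means: dict) -> np.ndarray:
        img = np.full(shape, background, dtype=np.float32)
        for sub in SUBTYPES:
            img[masks[sub].voxels] = means[sub]
        if ic.noise_sd > 0:
            img += rng.normal(0, ic.noise_sd, size=shape).astype(np.float32)
        if ic.blur_sigma_um > 0:
            ndimage.gaussian_filter(img, sigma=ic.blur_sigma_um / spacing, output=img)
        return np.clip(img, 0, None)

    if "cd31" in channels:
        out["cd31"] = _marker(ic.background_cd31, ic.cd31_means)
    if "emcn" in channels:
        out["emcn"] = _marker(ic.background_emcn, ic.emcn_means)
    if "nuclear" in channels:
        texture = rng.normal(0, 1, size=shape).astype(np.float32)
        ndimage.gaussian_filter(texture, sigma=ic.nuclear_texture_scale_um / spacing, output=texture)
        sd = texture.std()
        if sd > 0:
            texture *= ic.nuclear_texture_sd / sd
        out["nuclear"] = np.clip(ic.nuclear_background + texture, 0, None)
    if "tumour" in channels:
        img = np.full(shape, ic.tumour_background, dtype=np.float32)
        if spots is not None and len(spots):
            coords = spots.coords_zyx()
            radii = spots.table["radius_um"].to_numpy(dtype=float)
            shape_arr = np.asarray(shape)
            for c, r in zip(coords, radii):
                lo = np.maximum(np.ceil((c - r) / spacing).astype(int), 0)
                hi = np.minimum(np.floor((c + r) / spacing).astype(int), shape_arr - 1)
                if np.any(lo > hi):
                    continue
                zz = (np.arange(lo[0], hi[0] + 1) * spacing[0] - c[0]) ** 2
                yy = (np.arange(lo[1], hi[1] + 1) * spacing[1] - c[1]) ** 2
                xx = (np.arange(lo[2], hi[2] + 1) * spacing[2] - c[2]) ** 2
                dist2 = zz[:, None, None] + yy[None, :, None] + xx[None, None, :]
                sl = (slice(lo[0], hi[0] + 1), slice(lo[1], hi[1] + 1), slice(lo[2], hi[2] + 1))
                img[sl][dist2 <= r**2] = ic.tumour_intensity
        if ic.noise_sd > 0:
            img += rng.normal(0, ic.noise_sd, size=shape).astype(np.float32)
        if ic.blur_sigma_um > 0:
            ndimage.gaussian_filter(img, sigma=ic.blur_sigma_um / spacing, output=img)
        out["tumour"] = np.clip(img, 0, None)
    return ImageVolume(channels=out, spacing=tuple(float(s) for s in spacing))


def _allocate_counts(mix: dict[str, float], n: int) -> dict[str, int]:
    """Deterministic rounding of placement fractions to integer spot counts."""
    counts = {k: int(round(f * n)) for k, f in mix.items() if f > 0}
    overshoot = sum(counts.values()) - n
    for k in sorted(counts, key=counts.get, reverse=True):
        if overshoot <= 0:
            break
        take = min(overshoot, counts[k])
        counts[k] -= take
        overshoot -= take
    counts["uniform"] = n - sum(counts.values())
    return counts


def place_dtcs(
    cfg: SyntheticConfig,
    masks: dict[str, StructureMask],
    rng: np.random.Generator | None = None,
    fields: dict[str, np.ndarray] | None = None,
) -> SpotSet:
    """Place DTC spots according to the configured placement mix.

    ``near_X`` spots are drawn uniformly over admissible voxels whose centre
    lies within ``shell_um`` of the target structure; ``uniform`` spots are
    drawn over all admissible voxels.  Centres get sub-voxel jitter (falling
    back to the voxel centre if jitter would leave the shell), and each spot
    records its true placement class and true distance to its target.
    """
    from .niche import distance_field, interpolate_field

    dc = cfg.dtc
    spacing = np.asarray(masks["marrow_admissible"].spacing, dtype=float)
    admissible = masks["marrow_admissible"].voxels
    if not admissible.any():
        raise GenerationError("marrow_admissible mask is empty")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)

    target_of = {
        "perivascular_any": "vessel_any",
        "near_bone": "bone_surface",
        "near_type_h": "type_h",
    }
    fields = dict(fields or {})
    counts = _allocate_counts(dc.placement_mix, dc.n_spots)
    candidates: dict[str, np.ndarray] = {}
    for cls, n in counts.items():
        if n == 0 or cls == "uniform":
            continue
        target = target_of[cls]
        if target not in masks or masks[target].is_empty():
            raise GenerationError(f"placement class {cls!r}: target mask {target!r} empty or missing")
        if target not in fields:
            fields[target] = distance_field(masks[target]).distances
        shell = admissible & (fields[target] <= dc.shell_um)
        if not shell.any():
            raise GenerationError(
                f"placement class {cls!r}: no admissible voxel within {dc.shell_um} µm of {target}"
            )
        candidates[cls] = np.flatnonzero(shell.ravel())
    candidates["uniform"] = np.flatnonzero(admissible.ravel())

    # sorted so results do not depend on the mix dict's key order
    classes = [cls for cls in sorted(counts) for _ in range(counts[cls])]
    rng.shuffle(classes)
    shape = admissible.shape
    accepted: list[np.ndarray] = []
    accepted_cls: list[str] = []
    true_dist: list[float] = []
    for cls in classes:
        pool = candidates[cls]
        target = target_of.get(cls)
        placed = None
        for _ in range(500):
            flat = pool[rng.integers(len(pool))]
            centre_vox = np.asarray(np.unravel_index(flat, shape), dtype=float)
            pos = centre_vox * spacing + rng.uniform(-0.5, 0.5, size=3) * spacing
            pos = np.clip(pos, 0, (np.asarray(shape) - 1) * spacing)
            if target is not None:
                d = float(interpolate_field(fields[target], spacing, pos[None])[0])
                if d > dc.shell_um:  # jitter pushed it out; keep the voxel centre
                    pos = centre_vox * spacing
                    d = float(fields[target][tuple(centre_vox.astype(int))])
            else:
                d = np.nan
            if dc.min_separation_um > 0 and accepted:
                sep = np.linalg.norm(np.asarray(accepted) - pos, axis=1).min()
                if sep < dc.min_separation_um:
                    continue
            placed = (pos, d)
            break
        if placed is None:  # crowded volume: accept the last candidate anyway
            placed = (pos, d)
        accepted.append(placed[0])
        accepted_cls.append(cls)
        true_dist.append(placed[1])

    coords = np.asarray(accepted) if accepted else np.zeros((0, 3))
    return SpotSet.from_coords_zyx(
        coords,
        radius_um=dc.radius_um,
        kind="dtc",
        source="synthetic",
        placement_class=accepted_cls,
        true_target_distance_um=true_dist,
    )


def generate_dataset(cfg: SyntheticConfig) -> tuple[ImageVolume, GroundTruth]:
    """Run the full generator: tree, sprouts, masks, spots, rendered channels.

    Deterministic given ``cfg.seed``: each stage draws from an independent
    child stream of one seed sequence.
    """
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    rng_tree, rng_sprout, rng_bone, rng_dtc, rng_render = (
        np.random.default_rng(c) for c in ss.spawn(5)
    )
    tree = build_vessel_tree(cfg, rng_tree)
    add_sprouts(tree, cfg, rng_sprout)
    masks = voxelize(tree, cfg, rng_bone)
    spots = place_dtcs(cfg, masks, rng_dtc)
    vol = render_channels(masks, cfg, rng_render, spots=spots)

    sprouts = pd.DataFrame(
        [
            {
                "parent_segment": s.parent_segment,
                "anchor_z_um": s.anchor[0],
                "anchor_y_um": s.anchor[1],
                "anchor_x_um": s.anchor[2],
                "length_um": s.length_um,
                "radius_um": s.radius_um,
            }
            for s in tree.sprouts
        ],
        columns=[
            "parent_segment", "anchor_z_um", "anchor_y_um", "anchor_x_um",
            "length_um", "radius_um",
        ],
    )
    vessels = pd.DataFrame(
        [
            {
                "segment_id": s.id,
                "subtype": s.subtype,
                "parent": -1 if s.parent is None else s.parent,
                "radius_um": s.radius_um,
                "length_um": s.length_um(),
                "lateral_area_um2": 2 * np.pi * s.radius_um * s.length_um(),
            }
            for s in tree.segments
        ]
    )
    truth = GroundTruth(
        masks=masks, spots=spots, sprouts=sprouts, vessels=vessels, tree=tree, seed=cfg.seed
    )
    return vol, truth
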