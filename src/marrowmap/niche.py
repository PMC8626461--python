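"""Spatial niche statistics: distance transforms, proximity fractions,
the random-spot null model, and the two-sample comparisons.

The central quantity is the per-spot 3D Euclidean distance (µm, honouring
anisotropic voxel spacing) from a spot centre to the nearest voxel of a
structure mask, summarized as the fraction of spots within a threshold
(10 µm by default) of each structure, and compared between observed DTCs
and simulated random spots placed uniformly in admissible marrow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, special, stats

from .errors import GenerationError, ValidationError
from .grid import SpotSet, StructureMask

STRUCTURE_ORDER = ("bone_surface", "vessel_any", "arterial", "type_h", "type_l")


@dataclass
class DistanceField:
    """Euclidean distance (µm) from every voxel centre to the nearest mask voxel."""

    structure: str
    distances: np.ndarray
    spacing: tuple[float, float, float]


def distance_field(mask: StructureMask) -> DistanceField:
    """Exact anisotropic Euclidean distance transform of a structure mask.

    Zero on mask voxels, the physical distance to the nearest mask voxel
    centre elsewhere.
    """
    if mask.is_empty():
        raise ValidationError(f"structure {mask.name!r}: mask is empty, no distances defined")
    dist = ndimage.distance_transform_edt(~mask.voxels, sampling=mask.spacing)
    return DistanceField(mask.name, dist.astype(float), mask.spacing)


def interpolate_field(
    distances: np.ndarray, spacing, points_zyx_um: np.ndarray
) -> np.ndarray:
    """Trilinear interpolation of a voxel field at physical (z, y, x) µm points."""
    coords = np.asarray(points_zyx_um, dtype=float) / np.asarray(spacing, dtype=float)
    return ndimage.map_coordinates(distances, coords.T, order=1, mode="nearest")


def measure_spot_distances(
    spots: SpotSet,
    fields: dict[str, DistanceField],
    subtract_radius: bool = False,
    volume_id: str | None = None,
) -> pd.DataFrame:
    """Per-spot distance (µm) to each structure, trilinearly interpolated.

    Distances are centre-of-spot to nearest structure voxel by default;
    ``subtract_radius`` converts them to surface-referenced distances
    (clipped at 0).  Raises if any centroid is outside the grid bounds.
    """
    if not fields:
        raise ValidationError("no distance fields supplied")
    first = next(iter(fields.values()))
    spacing = np.asarray(first.spacing, dtype=float)
    bounds = (np.asarray(first.distances.shape) - 1) * spacing
    coords = spots.coords_zyx()
    if len(coords):
        bad = np.flatnonzero(np.any((coords < -1e-9) | (coords > bounds + 1e-9), axis=1))
        if bad.size:
            ids = spots.table["id"].iloc[bad].tolist()
            raise ValidationError(f"spot centroids outside grid bounds: ids {ids}")
    out = spots.table[["id", "kind"]].copy()
    if volume_id is not None:
        out["volume_id"] = volume_id
    for name, fld in fields.items():
        d = interpolate_field(fld.distances, fld.spacing, coords) if len(coords) else np.zeros(0)
        if subtract_radius:
            d = np.clip(d - spots.table["radius_um"].to_numpy(dtype=float), 0, None)
        out[f"dist_{name}_um"] = d
    return out


@dataclass
class ProximityResult:
    structure: str
    threshold_um: float
    per_volume: pd.DataFrame  # columns volume_id, kind, n, fraction
    mean: dict = field(default_factory=dict)  # kind -> mean fraction across volumes
    sem: dict = field(default_factory=dict)  # kind -> s.e.m. across volumes
    n_spots: dict = field(default_factory=dict)


def proximity_fraction(
    table: pd.DataFrame, structure: str, threshold_um: float = 10.0
) -> ProximityResult:
    """Fraction of spots within ``threshold_um`` of a structure, per volume and group.

    Expects a distance table from :func:`measure_spot_distances`; the group
    unit for the mean ± s.e.m. is the volume (one imaged stack / mouse), so a
    table without ``volume_id`` is treated as one volume.
    """
    col = f"dist_{structure}_um"
    if col not in table.columns:
        raise ValidationError(f"distance table has no column {col!r}")
    if len(table) == 0:
        raise ValidationError("distance table is empty")
    tab = table.copy()
    if "volume_id" not in tab.columns:
        tab["volume_id"] = "volume0"
    grouped = (
        tab.assign(within=tab[col] <= threshold_um)
        .groupby(["kind", "volume_id"], sort=True)
        .agg(n=("within", "size"), fraction=("within", "mean"))
        .reset_index()
    )
    result = ProximityResult(structure=structure, threshold_um=threshold_um, per_volume=grouped)
    for kind, sub in grouped.groupby("kind"):
        fr = sub["fraction"].to_numpy(dtype=float)
        result.mean[kind] = float(fr.mean())
        result.sem[kind] = float(fr.std(ddof=1) / np.sqrt(len(fr))) if len(fr) > 1 else 0.0
        result.n_spots[kind] = int(sub["n"].sum())
    return result


@dataclass
class NullModelConfig:
    """Random-spot null model: DTC-sized spots uniform over admissible marrow."""

    n_random: int = 1000
    diameter_um: float = 10.0
    seed: int = 0
    required_structures: tuple = ("arterial", "type_h", "type_l", "bone_surface")

    def validate(self) -> None:
        if self.n_random < 100:
            raise ValidationError("n_random must be >= 100 for a stable null model")
        if self.diameter_um <= 0:
            raise ValidationError("spot diameter must be > 0")


def default_n_random(n_dtcs: int) -> int:
    """Default null-model size: max(10 x n DTCs, 1000)."""
    return max(10 * n_dtcs, 1000)


def generate_random_spots(
    masks: dict[str, StructureMask], cfg: NullModelConfig
) -> SpotSet:
    """Draw null-model spots uniformly over the admissible marrow region.

    Refuses to run unless every required structure (all vessel subtypes and
    bone by default) is present and non-empty in the volume, so chance
    proximity is neither over- nor under-estimated on unrepresentative
    stacks.  Admissible = marrow minus vessels (incl. lumens) minus bone.
    """
    cfg.validate()
    for name in cfg.required_structures:
        if name not in masks or masks[name].is_empty():
            raise GenerationError(
                f"volume lacks required structure {name!r}; random spots not generated"
            )
    if "marrow_admissible" not in masks or masks["marrow_admissible"].is_empty():
        raise GenerationError("admissible mask empty: nowhere to place random spots")
    admissible = masks["marrow_admissible"].voxels
    spacing = np.asarray(masks["marrow_admissible"].spacing, dtype=float)
    rng = np.random.default_rng(cfg.seed)
    flat = np.flatnonzero(admissible.ravel())
    picks = flat[rng.integers(0, len(flat), size=cfg.n_random)]
    vox = np.column_stack(np.unravel_index(picks, admissible.shape)).astype(float)
    pos = vox * spacing + rng.uniform(-0.5, 0.5, size=(cfg.n_random, 3)) * spacing
    bounds = (np.asarray(admissible.shape) - 1) * spacing
    pos = np.clip(pos, 0, bounds)
    return SpotSet.from_coords_zyx(
        pos, radius_um=cfg.diameter_um / 2.0, kind="random", source="null_model"
    )


def null_convergence_check(
    masks: dict[str, StructureMask],
    cfg: NullModelConfig,
    structure: str,
    threshold_um: float = 10.0,
    n_seeds: int = 5,
    tolerance_pp: float = 0.5,
    multipliers: tuple = (0.25, 0.5, 1.0, 2.0),
) -> dict:
    """Empirical stability of the null-model proximity fraction versus n.

    Re-draws the null model at ``multipliers x n_random`` across seeds and
    reports the across-seed s.d. of the proximity fraction per n, plus the
    smallest n whose s.d. falls below ``tolerance_pp`` percentage points.
    """
    fld = {structure: distance_field(masks[structure])}
    rows = []
    for mult in multipliers:
        n = max(100, int(round(cfg.n_random * mult)))
        fracs = []
        for k in range(n_seeds):
            sub = NullModelConfig(
                n_random=n,
                diameter_um=cfg.diameter_um,
                seed=cfg.seed + 1000 * k + int(mult * 16),
                required_structures=cfg.required_structures,
            )
            spots = generate_random_spots(masks, sub)
            tab = measure_spot_distances(spots, fld)
            fracs.append(float((tab[f"dist_{structure}_um"] <= threshold_um).mean()))
        rows.append({"n": n, "mean_fraction": float(np.mean(fracs)), "sd": float(np.std(fracs, ddof=1))})
    accepted = [r["n"] for r in rows if r["sd"] * 100 < tolerance_pp]
    return {
        "structure": structure,
        "threshold_um": threshold_um,
        "tolerance_pp": tolerance_pp,
        "levels": rows,
        "recommended_n": min(accepted) if accepted else None,
    }


def distance_histogram(
    table: pd.DataFrame,
    structure: str,
    bin_width_um: float = 10.0,
    max_um: float = 30.0,
    kind: str | None = None,
) -> pd.DataFrame:
    """Right-open distance bins [0,w), [w,2w), ... with an overflow bin [max, inf)."""
    if bin_width_um <= 0:
        raise ValidationError("bin width must be > 0")
    col = f"dist_{structure}_um"
    tab = table if kind is None else table[table["kind"] == kind]
    d = tab[col].to_numpy(dtype=float)
    edges = np.arange(0.0, max_um + bin_width_um / 2, bin_width_um)
    idx = np.minimum(np.floor(d / bin_width_um).astype(int), len(edges) - 1)
    counts = np.bincount(idx, minlength=len(edges))
    labels = [f"[{edges[i]:g},{edges[i] + bin_width_um:g})" for i in range(len(edges) - 1)]
    labels.append(f"[{edges[-1]:g},inf)")
    return pd.DataFrame(
        {
            "bin": labels,
            "lower_um": edges,
            "count": counts,
            "fraction": counts / max(len(d), 1),
        }
    )


@dataclass
class KSResult:
    statistic: float
    pvalue: float
    n1: int
    n2: int


def ks_two_sample(a, b) -> KSResult:
    """Two-sided two-sample Kolmogorov–Smirnov test.

    D is the exact supremum of |ECDF_a - ECDF_b| over the pooled sample; the
    p-value uses the asymptotic Kolmogorov distribution at effective sample
    size n1*n2/(n1+n2).
    """
    a = np.sort(np.asarray(a, dtype=float))
    b = np.sort(np.asarray(b, dtype=float))
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("KS test needs at least 2 observations per sample")
    pooled = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, pooled, side="right") / len(a)
    cdf_b = np.searchsorted(b, pooled, side="right") / len(b)
    d = float(np.abs(cdf_a - cdf_b).max())
    en = len(a) * len(b) / (len(a) + len(b))
    p = float(np.clip(special.kolmogorov(np.sqrt(en) * d), 0.0, 1.0))
    return KSResult(statistic=d, pvalue=max(p, np.finfo(float).tiny), n1=len(a), n2=len(b))


@dataclass
class TTestResult:
    statistic: float
    df: float
    pvalue: float
    variant: str
    degenerate: bool = False


def t_test_unpaired(a, b, variant: str = "student") -> TTestResult:
    """Two-tailed unpaired t test on per-volume group means.

    ``student`` pools the variance (default); ``welch`` uses the
    Welch–Satterthwaite correction.  Zero variance in both groups yields
    p = 1 for equal means and p -> 0 for different means, flagged degenerate.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 < 2 or n2 < 2:
        raise ValidationError("t test needs at least 2 observations per group")
    if variant not in ("student", "welch"):
        raise ValidationError(f"unknown t-test variant {variant!r}")
    m1, m2 = a.mean(), b.mean()
    v1, v2 = a.var(ddof=1), b.var(ddof=1)
    if v1 == 0 and v2 == 0:
        if m1 == m2:
            return TTestResult(0.0, n1 + n2 - 2, 1.0, variant, degenerate=True)
        return TTestResult(np.inf if m1 > m2 else -np.inf, n1 + n2 - 2, 0.0, variant, degenerate=True)
    if variant == "student":
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
    else:
        se = np.sqrt(v1 / n1 + v2 / n2)
        df = (v1 / n1 + v2 / n2) ** 2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
        )
    t = (m1 - m2) / se
    p = 2 * stats.t.sf(abs(t), df)
    return TTestResult(float(t), float(df), float(p), variant)


def tumour_volume(width_mm: float, length_mm: float) -> float:
    """Caliper tumour volume in mm³: width² x length / 2."""
    if width_mm <= 0 or length_mm <= 0:
        raise ValidationError("width and length must be > 0")
    return width_mm**2 * length_mm / 2.0
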