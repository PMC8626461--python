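"""DTC spot detection in the tumour-reporter channel.

Single disseminated tumour cells (and small clusters, which count as one
spot) appear as bright ~10 µm spheres.  Detection is single-scale
Laplacian-of-Gaussian blob detection with the scale fixed by the expected
diameter and per-axis sigmas corrected for anisotropic voxel spacing,
followed by rule-based curation (spots inside bone or vessel lumens, or of
low quality, are removed with a logged reason) standing in for manual
review of optical sections.  Detection is deterministic — no RNG.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ValidationError
from .grid import ImageVolume, SpotSet, StructureMask


def detect_spots(
    vol: ImageVolume,
    expected_diameter_um: float = 10.0,
    intensity_threshold: float = 60.0,
    cluster_radius_factor: float = 1.5,
) -> SpotSet:
    """Detect DTC-sized blobs in the tumour channel.

    The LoG scale is ``sigma = d / (2 sqrt(3))`` (the response optimum for a
    solid sphere of diameter d), divided by the per-axis spacing.  Candidate
    maxima whose raw intensity falls below ``intensity_threshold`` are
    discarded; quality is the LoG response normalized to the strongest
    detection.  Overlapping cells merge into one detection, flagged
    ``is_cluster`` when the fitted radius exceeds
    ``cluster_radius_factor x expected``.
    """
    tumour = vol.channel("tumour").astype(np.float32)
    spacing = np.asarray(vol.spacing, dtype=float)
    if expected_diameter_um < 2 * spacing.max():
        raise ValidationError(
            f"expected diameter {expected_diameter_um} µm below resolvability at "
            f"spacing {tuple(spacing)} (need >= {2 * spacing.max()} µm)"
        )
    sigma_um = expected_diameter_um / (2 * np.sqrt(3))
    sigma_vox = sigma_um / spacing
    response = -ndimage.gaussian_laplace(tumour, sigma=sigma_vox) * sigma_um**2

    # non-maximum suppression over a neighbourhood somewhat below one spot
    # diameter, so near-touching spots keep separate peaks
    size = np.maximum((0.7 * expected_diameter_um / spacing).astype(int) | 1, 3)
    local_max = ndimage.maximum_filter(response, size=tuple(size), mode="nearest")
    peaks = (response >= local_max) & (response > 0) & (tumour >= intensity_threshold)
    coords_vox = np.argwhere(peaks)

    if len(coords_vox) == 0:
        return SpotSet.from_coords_zyx(
            np.zeros((0, 3)), radius_um=expected_diameter_um / 2, kind="dtc",
            source="log_detection",
        )

    # plateau peaks (saturated cores) yield several voxels; merge within a radius
    order = np.argsort(-response[tuple(coords_vox.T)])
    coords_um = coords_vox[order] * spacing
    keep: list[int] = []
    for i, c in enumerate(coords_um):
        if all(np.linalg.norm(c - coords_um[j]) >= expected_diameter_um / 2 for j in keep):
            keep.append(i)
    coords_um = coords_um[keep]
    resp = response[tuple(coords_vox[order][keep].T)]

    # equivalent radius from the above-half-max volume in a local window
    radii = []
    half = expected_diameter_um * 1.2
    shape = np.asarray(tumour.shape)
    for c in coords_um:
        lo = np.maximum(((c - half) / spacing).astype(int), 0)
        hi = np.minimum(((c + half) / spacing).astype(int) + 1, shape)
        win = tumour[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        peak = win.max()
        bg = np.percentile(win, 10)
        n_above = int((win > (peak + bg) / 2).sum())
        vol_um3 = n_above * float(np.prod(spacing))
        radii.append((3 * vol_um3 / (4 * np.pi)) ** (1 / 3))
    radii = np.asarray(radii)

    quality = resp / resp.max() if resp.max() > 0 else resp
    return SpotSet.from_coords_zyx(
        coords_um,
        radius_um=np.maximum(radii, 0.5),
        kind="dtc",
        source="log_detection",
        quality=quality,
        is_cluster=radii > cluster_radius_factor * (expected_diameter_um / 2),
    )


def curate_spots(
    spots: SpotSet,
    masks: dict[str, StructureMask] | None = None,
    quality_cutoff: float = 0.0,
    marrow_mask_name: str = "marrow_region",
) -> SpotSet:
    """Rule-based surrogate for manual curation.

    Removes spots whose centroid lies inside bone (``in_bone``) or a vessel
    lumen (``in_lumen``), outside the marrow region when such a mask is
    supplied (``outside_marrow``), or whose quality falls below the cutoff
    (``low_quality``).  Removal reasons are recorded on the returned set's
    ``params['removed']``.
    """
    masks = masks or {}
    tab = spots.table
    n = len(tab)
    reasons = np.full(n, "", dtype=object)
    if n:
        coords = spots.coords_zyx()

        def _inside(mask: StructureMask) -> np.ndarray:
            spacing = np.asarray(mask.spacing, dtype=float)
            vox = np.rint(coords / spacing).astype(int)
            vox = np.clip(vox, 0, np.asarray(mask.voxels.shape) - 1)
            return mask.voxels[tuple(vox.T)]

        if "bone_surface" in masks:
            reasons[_inside(masks["bone_surface"])] = "in_bone"
        if "lumen" in masks:
            hit = _inside(masks["lumen"]) & (reasons == "")
            reasons[hit] = "in_lumen"
        if marrow_mask_name in masks:
            outside = ~_inside(masks[marrow_mask_name]) & (reasons == "")
            reasons[outside] = "outside_marrow"
        if quality_cutoff > 0 and "quality" in tab.columns:
            low = (tab["quality"].to_numpy(dtype=float) < quality_cutoff) & (reasons == "")
            reasons[low] = "low_quality"

    keep = reasons == ""
    removed = pd.DataFrame({"id": tab["id"][~keep], "reason": reasons[~keep]})
    out = SpotSet(table=tab[keep].copy(), source=spots.source, params=dict(spots.params))
    out.params["removed"] = removed.to_dict("records")
    return out
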