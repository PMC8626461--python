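"""Stage orchestration: simulate -> classify -> spots -> distances ->
nullmodel -> stats -> morphometry, with a reproducibility manifest.

Each stage reads its inputs from the output directory of earlier stages (or
in-memory state within one run), writes CSV/JSON outputs, and logs one
structured line with parameters and output checksums.  The manifest records
the config snapshot, seeds, software version and per-stage outputs;
re-running with the same config and seed reproduces deterministic stages
bit-identically.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import synthetic_config_from_dict, synthetic_config_to_dict
from .errors import ConfigurationError, DependencyError
from .grid import ImageVolume, SpotSet, StructureMask
from .io import (
    read_config,
    read_mask,
    read_spot_table,
    read_volume,
    sha256_file,
    write_json,
    write_mask,
    write_spot_table,
    write_volume,
)
from .morphometry import detect_sprouts, lumen_area, skeletonize_component, surface_over_length
from .niche import (
    NullModelConfig,
    default_n_random,
    distance_field,
    distance_histogram,
    ks_two_sample,
    measure_spot_distances,
    proximity_fraction,
)
from .phenotyping import (
    GateConfig,
    LABELS,
    classify_voxels,
    derive_gates,
    extract_components,
    vessel_mean_intensity,
)
from .spots import curate_spots, detect_spots
from .synthetic import generate_dataset

log = logging.getLogger("marrowmap")

STAGES = ("simulate", "classify", "spots", "distances", "nullmodel", "stats", "morphometry")

MASK_FILES = (
    "arterial", "type_h", "type_l", "vessel_any", "lumen", "bone_surface", "marrow_admissible",
)


class PipelineState:
    """In-memory carry-over between stages within one run."""

    def __init__(self, out_dir: Path):
        self.out = out_dir
        self.volume: ImageVolume | None = None
        self.masks: dict[str, StructureMask] = {}
        self.spots: SpotSet | None = None
        self.random_spots: SpotSet | None = None
        self.class_map = None

    def require_volume(self) -> ImageVolume:
        if self.volume is None:
            path = self.out / "volume.ome.tif"
            if not path.exists():
                raise DependencyError("no volume available; run or configure 'simulate' first")
            self.volume = read_volume(path)
        return self.volume

    def require_masks(self) -> dict[str, StructureMask]:
        if not self.masks:
            for name in MASK_FILES:
                path = self.out / f"mask_{name}.ome.tif"
                if path.exists():
                    self.masks[name] = read_mask(path, name)
            if not self.masks:
                raise DependencyError("no structure masks available; run 'simulate' first")
        return self.masks

    def require_spots(self) -> SpotSet:
        if self.spots is None:
            path = self.out / "spots.csv"
            if not path.exists():
                raise DependencyError("no spot table available; run 'spots' first")
            self.spots = read_spot_table(path)
        return self.spots


def _checksum(path: Path) -> str:
    """Content checksum; for OME-TIFF, hash the pixel data (the container
    embeds a fresh UUID per write, so file bytes are not reproducible)."""
    if path.suffix == ".tif":
        import hashlib

        vol = read_volume(path)
        h = hashlib.sha256()
        for name in vol.channels:
            h.update(name.encode())
            h.update(np.ascontiguousarray(vol.channels[name]).tobytes())
        h.update(repr(vol.spacing).encode())
        return h.hexdigest()
    return sha256_file(path)


def _stage_record(manifest: dict, stage: str, params: dict, outputs: list[Path]) -> None:
    checksums = {p.name: _checksum(p) for p in outputs if p.exists()}
    manifest["stages"][stage] = {
        "params": params,
        "outputs": {p.name: str(p) for p in outputs},
        "checksums": checksums,
        "finished_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    log.info("stage=%s params=%s outputs=%s", stage, params, sorted(checksums))


def run_pipeline(config_path: str | Path, out_dir: str | Path, seed: int | None = None) -> dict:
    """Execute the stages requested in the JSON config; return the manifest."""
    cfg = read_config(config_path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stages = cfg.get("stages", ["all"])
    if stages == ["all"] or stages == "all":
        stages = list(STAGES)
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ConfigurationError(f"unknown stage name(s) {unknown}; valid: {STAGES}")

    if seed is None:
        seed = cfg.get("seed")
    auto_seed = seed is None
    if auto_seed:
        seed = int(np.random.SeedSequence().entropy % (2**31))
    seed = int(seed)

    manifest: dict = {
        "version": __version__,
        "config": cfg,
        "config_path": str(config_path),
        "seed": seed,
        "seed_auto_drawn": auto_seed,
        "stages": {},
        "started_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    state = PipelineState(out)
    threshold_um = float(cfg.get("stats", {}).get("threshold_um", 10.0))

    for stage in stages:
        if stage == "simulate":
            syn = synthetic_config_from_dict({**cfg.get("simulate", {}), "seed": seed})
            vol, truth = generate_dataset(syn)
            state.volume, state.masks, state.spots_truth = vol, truth.masks, truth.spots
            outputs = [out / "volume.ome.tif"]
            write_volume(vol, outputs[0])
            for name in MASK_FILES:
                p = out / f"mask_{name}.ome.tif"
                write_mask(truth.masks[name], p)
                outputs.append(p)
            write_spot_table(truth.spots, out / "truth_spots.csv")
            truth.sprouts.to_csv(out / "truth_sprouts.csv", index=False)
            truth.vessels.to_csv(out / "truth_vessels.csv", index=False)
            write_json(synthetic_config_to_dict(syn), out / "resolved_synthetic_config.json")
            outputs += [out / "truth_spots.csv", out / "truth_sprouts.csv",
                        out / "truth_vessels.csv", out / "resolved_synthetic_config.json"]
            _stage_record(manifest, stage, {"seed": seed}, outputs)

        elif stage == "classify":
            vol = state.require_volume()
            params = cfg.get("classify", {})
            if params.get("strategy", "auto") == "manual":
                gates = derive_gates(
                    vol, "manual",
                    GateConfig(**{k: params[k] for k in
                                  ("vessel_presence", "cd31_lo_hi", "emcn_neg_lo", "emcn_lo_hi")},
                               strategy="manual"),
                )
            else:
                gates = derive_gates(vol, "auto")
            class_map = classify_voxels(vol, gates)
            state.class_map = class_map
            comps = extract_components(class_map, float(params.get("min_volume_um3", 500.0)))
            rows = []
            for comp in comps:
                cd31, emcn = vessel_mean_intensity(comp, vol)
                rows.append({"id": comp.id, "subtype": comp.subtype,
                             "volume_um3": comp.volume_um3,
                             "mean_cd31": cd31, "mean_emcn": emcn})
            pd.DataFrame(rows, columns=["id", "subtype", "volume_um3", "mean_cd31", "mean_emcn"]
                         ).to_csv(out / "vessel_components.csv", index=False)
            class_vol = ImageVolume({"class_map": class_map.labels.astype(np.uint8)}, vol.spacing)
            write_volume(class_vol, out / "class_map.ome.tif")
            state.components = comps
            _stage_record(
                manifest, stage,
                {"gates": dataclasses.asdict(gates)},
                [out / "vessel_components.csv", out / "class_map.ome.tif"],
            )

        elif stage == "spots":
            vol = state.require_volume()
            params = cfg.get("spots", {})
            detected = detect_spots(
                vol,
                expected_diameter_um=float(params.get("expected_diameter_um", 10.0)),
                intensity_threshold=float(params.get("intensity_threshold", 60.0)),
            )
            curated = curate_spots(detected, state.require_masks(),
                                   quality_cutoff=float(params.get("quality_cutoff", 0.0)))
            state.spots = curated
            write_spot_table(curated, out / "spots.csv")
            write_json({"detection": params, "n_detected": len(detected),
                        "n_curated": len(curated), "removed": curated.params.get("removed", [])},
                       out / "spot_detection.json")
            _stage_record(manifest, stage, params, [out / "spots.csv", out / "spot_detection.json"])

        elif stage == "distances":
            masks = state.require_masks()
            spots = state.require_spots()
            structures = cfg.get("distances", {}).get(
                "structures", ["bone_surface", "vessel_any", "arterial", "type_h", "type_l"])
            fields = {s: distance_field(masks[s]) for s in structures if s in masks}
            table = measure_spot_distances(spots, fields, volume_id=cfg.get("volume_id", "volume0"))
            table.to_csv(out / "distances.csv", index=False)
            state.distances = table
            _stage_record(manifest, stage, {"structures": structures}, [out / "distances.csv"])

        elif stage == "nullmodel":
            masks = state.require_masks()
            params = cfg.get("nullmodel", {})
            n_dtc = len(state.spots) if state.spots is not None else 0
            null_cfg = NullModelConfig(
                n_random=int(params.get("n_random", default_n_random(n_dtc))),
                diameter_um=float(params.get("diameter_um", 10.0)),
                seed=seed + 1,
                required_structures=tuple(params.get(
                    "required_structures", ("arterial", "type_h", "type_l", "bone_surface"))),
            )
            from .niche import generate_random_spots

            random_spots = generate_random_spots(masks, null_cfg)
            state.random_spots = random_spots
            structures = cfg.get("distances", {}).get(
                "structures", ["bone_surface", "vessel_any", "arterial", "type_h", "type_l"])
            fields = {s: distance_field(masks[s]) for s in structures if s in masks}
            table = measure_spot_distances(random_spots, fields,
                                           volume_id=cfg.get("volume_id", "volume0"))
            write_spot_table(random_spots, out / "random_spots.csv")
            table.to_csv(out / "random_distances.csv", index=False)
            state.random_distances = table
            _stage_record(manifest, stage, dataclasses.asdict(null_cfg),
                          [out / "random_spots.csv", out / "random_distances.csv"])

        elif stage == "stats":
            dist_path, rand_path = out / "distances.csv", out / "random_distances.csv"
            dtc = getattr(state, "distances", None)
            rnd = getattr(state, "random_distances", None)
            if dtc is None:
                if not dist_path.exists():
                    raise DependencyError("stats needs the 'distances' stage output")
                dtc = pd.read_csv(dist_path)
            if rnd is None and rand_path.exists():
                rnd = pd.read_csv(rand_path)
            combined = pd.concat([dtc, rnd], ignore_index=True) if rnd is not None else dtc
            summary, hist_rows = {}, []
            structures = [c[len("dist_"):-len("_um")] for c in dtc.columns if c.startswith("dist_")]
            for s in structures:
                prox = proximity_fraction(combined, s, threshold_um)
                entry = {
                    "threshold_um": threshold_um,
                    "fraction_mean": prox.mean,
                    "fraction_sem": prox.sem,
                    "n_spots": prox.n_spots,
                }
                if rnd is not None:
                    ks = ks_two_sample(dtc[f"dist_{s}_um"], rnd[f"dist_{s}_um"])
                    entry["ks"] = dataclasses.asdict(ks)
                summary[s] = entry
                for kind, tab in (("dtc", dtc), ("random", rnd)):
                    if tab is None:
                        continue
                    h = distance_histogram(tab, s)
                    h.insert(0, "structure", s)
                    h.insert(1, "kind", kind)
                    hist_rows.append(h)
            summary["multiple_testing"] = "none (per-comparison p values reported)"
            write_json(summary, out / "stats.json")
            pd.concat(hist_rows, ignore_index=True).to_csv(out / "histograms.csv", index=False)
            _stage_record(manifest, stage, {"threshold_um": threshold_um},
                          [out / "stats.json", out / "histograms.csv"])

        elif stage == "morphometry":
            masks = state.require_masks()
            params = cfg.get("morphometry", {})
            if state.class_map is not None:
                comps = getattr(state, "components", [])
            else:
                from .phenotyping import VesselClassMap

                labels = np.zeros(masks["vessel_any"].voxels.shape, dtype=np.uint8)
                for name in ("arterial", "type_h", "type_l"):
                    labels[masks[name].voxels] = LABELS[name]
                gates = GateConfig(0, 0, 0, 0, strategy="manual")
                comps = extract_components(
                    VesselClassMap(labels, gates, masks["vessel_any"].spacing),
                    float(params.get("min_volume_um3", 500.0)),
                )
            rows, sprout_rows = [], []
            for comp in comps:
                skel = skeletonize_component(comp)
                sa_over_l = surface_over_length(comp, skel)
                sprouts, density = detect_sprouts(
                    comp, skel,
                    radius_threshold_um=float(params.get("sprout_radius_threshold_um", 2.0)),
                    min_length_um=float(params.get("sprout_min_length_um", 2.0)),
                )
                areas = lumen_area(comp, masks["lumen"], skel,
                                   n_planes=int(params.get("n_lumen_planes", 10)))
                rows.append({
                    "id": comp.id, "subtype": comp.subtype,
                    "volume_um3": comp.volume_um3,
                    "main_path_length_um": skel.main_path_length_um,
                    "surface_over_length_um": sa_over_l,
                    "sprout_count": len(sprouts),
                    "sprouts_per_100um": density,
                    "mean_lumen_area_um2": float(np.mean(areas)) if areas else np.nan,
                })
                for s in sprouts:
                    sprout_rows.append({"component": comp.id, "length_um": s.length_um,
                                        "mean_radius_um": s.mean_radius_um})
            pd.DataFrame(rows).to_csv(out / "morphometry.csv", index=False)
            pd.DataFrame(sprout_rows, columns=["component", "length_um", "mean_radius_um"]
                         ).to_csv(out / "sprouts.csv", index=False)
            density_json = {}
            if "tumour_region" in masks and not masks["tumour_region"].is_empty():
                from .morphometry import vessel_volume_fraction

                density_json["intralesional_vessel_fraction"] = vessel_volume_fraction(
                    masks["vessel_any"], masks["tumour_region"])
            write_json(density_json, out / "region_density.json")
            _stage_record(manifest, stage, params,
                          [out / "morphometry.csv", out / "sprouts.csv",
                           out / "region_density.json"])

    manifest["finished_at"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    write_json(manifest, out / "manifest.json")
    return manifest
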