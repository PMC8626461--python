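# marrowmap

Quantitative 3D mapping of the bone-marrow vascular niche.

Breast-cancer cells that disseminate to the skeleton lodge in specific
microenvironments of the marrow. Deep confocal imaging of cleared bone
shows the marrow vasculature as a hierarchy of subtypes separable by two
endothelial markers — arterioles (CD31-high, Endomucin-negative), type H
capillaries (CD31-high, EMCN-high) and type L sinusoids (low in both) —
and disseminated tumour cells (DTCs) as ~10 µm reporter-positive spots.
`marrowmap` implements the analysis such studies need, as a tested,
scriptable pipeline:

- **Vessel phenotyping** — joint CD31–EMCN intensity gating (3-class Otsu
  per channel, or manual thresholds) into arterial / type H / type L voxel
  maps and per-vessel connected components with mean marker intensities.
- **DTC localization** — anisotropy-corrected Laplacian-of-Gaussian spot
  detection, rule-based curation, exact anisotropic Euclidean distance
  transforms, and the proximity statistic: the fraction of spots within
  10 µm of bone or each vessel subtype.
- **Random-spot null model** — DTC-sized spots placed uniformly in
  admissible marrow (excluding vessel lumens and bone, and requiring all
  vessel subtypes present), giving the chance level the observed fractions
  are compared against; distance histograms, two-sample Kolmogorov–Smirnov
  tests on distance distributions, and unpaired t tests on per-volume
  means.
- **Vessel morphometry** — skeleton-based vessel length, surface area over
  length (2πr for an ideal cylinder), endothelial sprout count per 100 µm
  and sprout lengths, lumen cross-sectional areas, and intralesional
  vessel volume fraction.
- **Synthetic marrow generator** — a phantom with a branching vessel
  hierarchy, bone surfaces, sprouts, and DTCs placed with configurable
  spatial preference, plus exhaustive ground truth; every measurement
  stage is validated as parameter recovery against it.

For a spot set with distances `d_i` to a structure, the core statistic is
simply `P̂ = #{d_i ≤ 10 µm} / n`, reported per volume as mean ± s.e.m.
across volumes, against the null model's `P̂` on the same volume. The KS
statistic is the exact `D = sup_x |F̂_DTC(x) − F̂_random(x)|` with the
asymptotic p-value at effective sample size `n₁n₂/(n₁+n₂)`.

## Worked example

Generate a small synthetic marrow volume and run the full pipeline. Save
this as `example_config.json` — a 128×128×32 stack at (2, 1, 1) µm with 80
DTCs placed 50% perivascular / 20% near type H, and a 2000-spot null model:

```json
{
  "simulate": {
    "shape": [32, 128, 128], "spacing": [2, 1, 1],
    "vessels": {"n_arterioles": 2,
                "radius_um": {"arterial": [5, 0.5], "type_h": [3.5, 0.4], "type_l": [6, 0.8]},
                "segment_length_um": {"arterial": [60, 8], "type_h": [45, 6], "type_l": [50, 8]}},
    "bone": {"cortical_thickness_um": 8, "n_trabecular_plates": 1,
             "trabecular_extent_um": [25, 35]},
    "dtc": {"n_spots": 80, "placement_mix": {"perivascular_any": 0.5, "near_type_h": 0.2}},
    "sprouts": {"density_per_100um": 2.0}
  },
  "nullmodel": {"n_random": 2000}
}
```

```bash
marrowmap all --config example_config.json --out example_out --seed 7
```

Inspecting `stats.json` and `morphometry.csv` from that run prints:

```
vessel_any    dtc 0.762  random 0.329  ks D=0.444 p=1.35e-13
type_h        dtc 0.300  random 0.087  ks D=0.228 p=6.73e-04
bone_surface  dtc 0.075  random 0.121  ks D=0.123 p=1.91e-01

  subtype  main_path_length_um  surface_over_length_um  sprouts_per_100um  mean_lumen_area_um2
 arterial                74.42                   30.53               1.34                20.44
 arterial                96.81                   22.44               2.07                20.41
   type_h               112.89                   18.08               0.89                 8.21
   type_h                92.08                   21.81               2.17                12.04
   type_l               238.41                   57.70               3.36                17.00
```

Reading: 76% of detected DTCs lie within 10 µm of a vessel versus 33% of
random spots — the perivascular enrichment that was configured into the
generator — and the KS test rejects equality of the distance
distributions; bone proximity shows no enrichment (p = 0.19), as none was
configured. The morphometry table lists per-vessel skeleton length,
surface-over-length, sprout density and lumen area. Every stage writes
CSV/JSON plus a `manifest.json` recording parameters, seeds and content
checksums; re-running with the same seed reproduces the outputs exactly.

The same operations are available as a library
(`marrowmap.generate_dataset`, `classify_voxels`, `detect_spots`,
`distance_field`, `proximity_fraction`, `generate_random_spots`,
`ks_two_sample`, …) for use on real OME-TIFF stacks.

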