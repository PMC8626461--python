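"""Distance transforms, proximity statistics, null model and the two-sample
tests, each against an independent oracle."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import cdist

from marrowmap.errors import GenerationError, ValidationError
from marrowmap.grid import SpotSet, StructureMask
from marrowmap.niche import (
    NullModelConfig,
    default_n_random,
    distance_field,
    distance_histogram,
    generate_random_spots,
    interpolate_field,
    ks_two_sample,
    measure_spot_distances,
    null_convergence_check,
    proximity_fraction,
    t_test_unpaired,
    tumour_volume,
)


def brute_force_distances(mask: StructureMask) -> np.ndarray:
    """All-pairs oracle: per-voxel distance to the nearest mask voxel."""
    spacing = np.asarray(mask.spacing)
    targets = np.argwhere(mask.voxels) * spacing
    grid = np.indices(mask.voxels.shape).reshape(3, -1).T * spacing
    return cdist(grid, targets).min(axis=1).reshape(mask.voxels.shape)


class TestDistanceField:
    def test_exact_vs_brute_force_random_masks(self):
        rng = np.random.default_rng(0)
        for _ in range(15):
            shape = tuple(rng.integers(4, 13, size=3))
            vox = rng.random(shape) > 0.9
            if not vox.any():
                vox[tuple(rng.integers(0, shape))] = True
            spacing = tuple(rng.uniform(0.5, 3.0, size=3).round(2))
            mask = StructureMask("m", vox, spacing)
            got = distance_field(mask).distances
            np.testing.assert_allclose(got, brute_force_distances(mask), atol=1e-9)

    def test_single_voxel_anisotropic(self):
        vox = np.zeros((3, 2, 5), dtype=bool)
        vox[0, 0, 0] = True
        fld = distance_field(StructureMask("m", vox, (2.0, 1.0, 1.0)))
        assert fld.distances[1, 0, 3] == pytest.approx(np.sqrt(13))
        assert fld.distances[0, 0, 0] == 0.0

    def test_full_mask_all_zero(self):
        fld = distance_field(StructureMask("m", np.ones((3, 3, 3), bool), (2, 1, 1)))
        assert fld.distances.max() == 0.0

    def test_empty_mask_names_structure(self):
        with pytest.raises(ValidationError, match="bone"):
            distance_field(StructureMask("bone_surface", np.zeros((3, 3, 3), bool), (1, 1, 1)))

    def test_lipschitz_in_physical_steps(self):
        rng = np.random.default_rng(1)
        vox = rng.random((8, 10, 12)) > 0.95
        vox[0, 0, 0] = True
        d = distance_field(StructureMask("m", vox, (2.0, 1.0, 1.0))).distances
        assert np.abs(np.diff(d, axis=0)).max() <= 2.0 + 1e-9
        assert np.abs(np.diff(d, axis=1)).max() <= 1.0 + 1e-9
        assert np.abs(np.diff(d, axis=2)).max() <= 1.0 + 1e-9


class TestSpotDistances:
    def test_spot_on_mask_voxel_is_zero(self):
        vox = np.zeros((4, 4, 4), bool)
        vox[2, 2, 2] = True
        fld = distance_field(StructureMask("vessel_any", vox, (2.0, 1.0, 1.0)))
        spots = SpotSet.from_coords_zyx(np.array([[4.0, 2.0, 2.0]]), 5.0, "dtc")
        tab = measure_spot_distances(spots, {"vessel_any": fld})
        assert tab["dist_vessel_any_um"].iloc[0] == 0.0

    def test_linear_interpolation_midpoint(self):
        from marrowmap.niche import DistanceField

        d = np.zeros((1, 1, 2))
        d[0, 0, 0], d[0, 0, 1] = 4.0, 6.0
        fld = DistanceField("x", d, (1.0, 1.0, 1.0))
        spots = SpotSet.from_coords_zyx(np.array([[0.0, 0.0, 0.5]]), 1.0, "dtc")
        tab = measure_spot_distances(spots, {"x": fld})
        assert tab["dist_x_um"].iloc[0] == pytest.approx(5.0)

    def test_interpolated_close_to_brute_force(self, small_dataset):
        _, truth = small_dataset
        mask = truth.masks["vessel_any"]
        fld = distance_field(mask)
        rng = np.random.default_rng(2)
        extent = (np.asarray(mask.voxels.shape) - 1) * np.asarray(mask.spacing)
        pts = rng.uniform(0, 1, size=(300, 3)) * extent
        spots = SpotSet.from_coords_zyx(pts, 5.0, "dtc")
        tab = measure_spot_distances(spots, {"vessel_any": fld})
        targets = np.argwhere(mask.voxels) * np.asarray(mask.spacing)
        exact = cdist(pts, targets).min(axis=1)
        diag = np.linalg.norm(mask.spacing)
        assert np.max(np.abs(tab["dist_vessel_any_um"].to_numpy() - exact)) <= diag

    def test_out_of_bounds_lists_ids(self):
        vox = np.ones((4, 4, 4), bool)
        fld = distance_field(StructureMask("m", vox, (1.0, 1.0, 1.0)))
        spots = SpotSet.from_coords_zyx(np.array([[1.0, 1.0, 1.0], [99.0, 1.0, 1.0]]), 1.0, "dtc")
        with pytest.raises(ValidationError, match=r"\[1\]"):
            measure_spot_distances(spots, {"m": fld})


class TestProximity:
    def _table(self, distances, kind="dtc", volume_id=None):
        tab = pd.DataFrame(
            {"id": np.arange(len(distances)), "kind": kind,
             "dist_vessel_any_um": distances}
        )
        if volume_id is not None:
            tab["volume_id"] = volume_id
        return tab

    def test_saturating(self):
        res = proximity_fraction(self._table([0.0] * 5), "vessel_any", 10.0)
        assert res.mean["dtc"] == 1.0

    def test_counting(self):
        res = proximity_fraction(self._table([5.0, 9.0, 11.0, 30.0]), "vessel_any", 10.0)
        assert res.mean["dtc"] == pytest.approx(0.5)

    def test_sem_across_volumes(self):
        tab = pd.concat(
            [self._table([0.0, 0.0, 20.0, 20.0], volume_id="a"),
             self._table([0.0, 20.0, 20.0, 20.0], volume_id="b")],
            ignore_index=True,
        )
        res = proximity_fraction(tab, "vessel_any", 10.0)
        fr = np.array([0.5, 0.25])
        assert res.mean["dtc"] == pytest.approx(fr.mean())
        assert res.sem["dtc"] == pytest.approx(fr.std(ddof=1) / np.sqrt(2))

    def test_empty_table_rejected(self):
        with pytest.raises(ValidationError):
            proximity_fraction(self._table([]), "vessel_any", 10.0)

    def test_recovers_configured_placement_fraction(self, small_dataset):
        """Recovered in-shell fraction is unbiased for the generator's mix."""
        from marrowmap.synthetic import place_dtcs

        from .conftest import small_config

        _, truth = small_dataset
        fld = distance_field(truth.masks["vessel_any"])
        hits = n = 0
        for seed in range(6):
            cfg = small_config(n_spots=120)
            cfg.dtc.placement_mix = {"perivascular_any": 0.5}
            cfg.dtc.min_separation_um = 0.0
            spots = place_dtcs(cfg, truth.masks, np.random.default_rng(seed))
            tab = measure_spot_distances(spots, {"vessel_any": fld})
            hits += int((tab["dist_vessel_any_um"] <= 10.0).sum())
            n += len(tab)
        adm = truth.masks["marrow_admissible"].voxels
        p_chance = (fld.distances[adm] <= 10.0).mean()
        expected = 0.5 + 0.5 * p_chance
        half = 2.576 * np.sqrt(expected * (1 - expected) / n)
        assert abs(hits / n - expected) <= half + 0.01


class TestNullModel:
    def test_missing_structure_refused(self, small_dataset):
        _, truth = small_dataset
        masks = dict(truth.masks)
        masks.pop("arterial")
        with pytest.raises(GenerationError, match="arterial"):
            generate_random_spots(masks, NullModelConfig(n_random=200, seed=0))

    def test_seeded_determinism(self, small_dataset):
        _, truth = small_dataset
        cfg = NullModelConfig(n_random=300, seed=9)
        a = generate_random_spots(truth.masks, cfg)
        b = generate_random_spots(truth.masks, cfg)
        np.testing.assert_array_equal(a.coords_zyx(), b.coords_zyx())

    def test_spots_avoid_vessels_and_bone(self, small_dataset):
        _, truth = small_dataset
        spots = generate_random_spots(truth.masks, NullModelConfig(n_random=2000, seed=1))
        spacing = np.asarray(truth.masks["vessel_any"].spacing)
        vox = np.rint(spots.coords_zyx() / spacing).astype(int)
        vox = np.clip(vox, 0, np.asarray(truth.masks["vessel_any"].voxels.shape) - 1)
        forbidden = truth.masks["vessel_any"].voxels | truth.masks["bone_surface"].voxels
        assert not forbidden[tuple(vox.T)].any()

    def test_uniformity_between_halves(self, small_dataset):
        """Counts in two labelled halves of the admissible region follow the
        volume split within the multinomial 99% CI (chi-square)."""
        _, truth = small_dataset
        adm = truth.masks["marrow_admissible"].voxels
        ny = adm.shape[1]
        split = ny // 3
        frac_a = adm[:, :split].sum() / adm.sum()
        spots = generate_random_spots(truth.masks, NullModelConfig(n_random=20000, seed=2))
        # voxel iy occupies [(iy-0.5) sy, (iy+0.5) sy): half "a" ends at (split-0.5) sy
        sy = truth.masks["marrow_admissible"].spacing[1]
        in_a = spots.coords_zyx()[:, 1] < (split - 0.5) * sy
        n_a = int(in_a.sum())
        chi2 = (n_a - 20000 * frac_a) ** 2 / (20000 * frac_a * (1 - frac_a))
        assert chi2 <= stats.chi2.ppf(0.99, df=1)

    def test_default_n_random(self):
        assert default_n_random(200) == 2000
        assert default_n_random(5) == 1000

    def test_convergence_report_schema_and_vacuous_tolerance(self, small_dataset):
        _, truth = small_dataset
        cfg = NullModelConfig(n_random=400, seed=0)
        report = null_convergence_check(
            truth.masks, cfg, "vessel_any", tolerance_pp=100.0, n_seeds=3,
            multipliers=(0.5, 1.0),
        )
        assert [lvl["n"] for lvl in report["levels"]] == [200, 400]
        assert all({"n", "mean_fraction", "sd"} <= set(lvl) for lvl in report["levels"])
        assert report["recommended_n"] == 200  # vacuous tolerance accepts smallest n

    def test_convergence_sd_shrinks_with_n(self, small_dataset):
        _, truth = small_dataset
        cfg = NullModelConfig(n_random=800, seed=3)
        report = null_convergence_check(
            truth.masks, cfg, "vessel_any", n_seeds=10, multipliers=(0.25, 4.0)
        )
        sds = [lvl["sd"] for lvl in report["levels"]]
        assert sds[0] > sds[-1]  # sqrt(n) law, within Monte-Carlo error


class TestHistogramBins:
    def test_boundary_convention(self):
        tab = pd.DataFrame(
            {"id": [0, 1, 2], "kind": "dtc", "dist_type_h_um": [1.0, 9.0, 10.0]}
        )
        hist = distance_histogram(tab, "type_h", bin_width_um=10.0, max_um=30.0)
        assert hist["count"].tolist() == [2, 1, 0, 0]
        assert hist["count"].sum() == 3

    def test_overflow_bin(self):
        tab = pd.DataFrame({"id": [0, 1], "kind": "dtc", "dist_type_h_um": [35.0, 99.0]})
        hist = distance_histogram(tab, "type_h", 10.0, 30.0)
        assert hist["count"].iloc[-1] == 2
        assert hist["bin"].iloc[-1] == "[30,inf)"

    def test_typeh_biased_dtcs_concentrate_in_first_bin(self, small_dataset):
        from marrowmap.synthetic import place_dtcs

        from .conftest import small_config

        _, truth = small_dataset
        fld = distance_field(truth.masks["type_h"])
        cfg = small_config(n_spots=150)
        cfg.dtc.placement_mix = {"near_type_h": 0.8}
        spots = place_dtcs(cfg, truth.masks, np.random.default_rng(0))
        dtc_tab = measure_spot_distances(spots, {"type_h": fld})
        rand = generate_random_spots(truth.masks, NullModelConfig(n_random=2000, seed=1))
        rand_tab = measure_spot_distances(rand, {"type_h": fld})
        h_dtc = distance_histogram(dtc_tab, "type_h")
        h_rand = distance_histogram(rand_tab, "type_h")
        assert h_dtc["fraction"].iloc[0] > 2 * h_rand["fraction"].iloc[0]


def brute_force_ks(a, b):
    pooled = np.concatenate([a, b])
    best = 0.0
    for t in pooled:
        best = max(best, abs((a <= t).mean() - (b <= t).mean()))
    return best


class TestKS:
    def test_identical_samples(self):
        r = ks_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.statistic == 0.0
        assert r.pvalue == pytest.approx(1.0)

    def test_disjoint_supports(self):
        r = ks_two_sample([1.0, 2.0, 3.0], [10.0, 20.0, 30.0])
        assert r.statistic == 1.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        for _ in range(60):
            a = rng.normal(0, 1, rng.integers(3, 40))
            b = rng.normal(rng.uniform(-1, 1), 1, rng.integers(3, 40))
            r = ks_two_sample(a, b)
            assert r.statistic == pytest.approx(brute_force_ks(a, b), abs=1e-12)

    def test_invariant_to_monotone_relabelling(self):
        rng = np.random.default_rng(1)
        a, b = rng.exponential(5, 30), rng.exponential(8, 25)
        r1 = ks_two_sample(a, b)
        r2 = ks_two_sample(np.log1p(a), np.log1p(b))
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-12)

    def test_too_small_sample(self):
        with pytest.raises(ValidationError):
            ks_two_sample([1.0], [2.0, 3.0])


class TestTTest:
    def test_identical_groups(self):
        r = t_test_unpaired([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.statistic == 0.0
        assert r.pvalue == pytest.approx(1.0)

    def test_zero_variance_guard(self):
        r = t_test_unpaired([0.0, 0.0, 0.0, 0.0], [1.0, 1.0, 1.0, 1.0])
        assert r.degenerate
        assert r.pvalue == 0.0
        same = t_test_unpaired([2.0, 2.0], [2.0, 2.0])
        assert same.degenerate and same.pvalue == 1.0

    @pytest.mark.parametrize("variant", ["student", "welch"])
    def test_matches_scipy_closed_form(self, variant):
        rng = np.random.default_rng(2)
        for _ in range(30):
            a = rng.normal(0, 1, rng.integers(3, 20))
            b = rng.normal(0.5, 2, rng.integers(3, 20))
            r = t_test_unpaired(a, b, variant=variant)
            ref = stats.ttest_ind(a, b, equal_var=(variant == "student"))
            assert r.statistic == pytest.approx(ref.statistic, abs=1e-10)
            assert r.pvalue == pytest.approx(ref.pvalue, abs=1e-10)


class TestTumourVolume:
    def test_direct_formula(self):
        assert tumour_volume(5.0, 8.0) == pytest.approx(100.0)

    def test_small_width_no_underflow(self):
        assert tumour_volume(0.001, 8.0) == pytest.approx(4e-6)

    def test_cubic_symmetry(self):
        w = 2.37
        assert tumour_volume(w, w) == pytest.approx(w**3 / 2)

    def test_non_positive_rejected(self):
        with pytest.raises(ValidationError):
            tumour_volume(0.0, 5.0)
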