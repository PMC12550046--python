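"""Voxelwise t-maps, cluster extraction, risk scores and leave-one-out."""

import numpy as np
import pytest
import scipy.stats

from pallidomap.data_model import GridMismatchError, SpotMap, StatMap, make_grid
from pallidomap.mapping import (
    MappingConfig,
    dice,
    extract_spot,
    loo_fit,
    loo_predict,
    score_patient,
    stratify,
    voxelwise_tmap,
)
from pallidomap.vta import voxelize_vta


def _random_vta_cohort(n=14, seed=0):
    """Small cohort of spherical VTAs on a coarse grid for oracle checks."""
    rng = np.random.default_rng(seed)
    grid = make_grid((-5, -5, -5), (21, 21, 21), 0.5)
    vta_sets = [
        [voxelize_vta(rng.uniform(-2, 2, 3), rng.uniform(1.0, 3.0), grid,
                      patient_id=f"p{i}")]
        for i in range(n)
    ]
    severity = rng.normal(0, 1, n)
    return grid, vta_sets, severity


def _statmap_with_cube(side, t_value=3.0, shape=(20, 20, 20)):
    grid = make_grid((0, 0, 0), shape, 0.5)
    t = np.zeros(shape)
    p = np.ones(shape)
    t[:side, :side, :side] = t_value
    p[:side, :side, :side] = 0.01
    ones = np.ones(shape)
    return StatMap(
        t=grid.like(t), p=grid.like(p),
        n_in=grid.like(ones * 7), n_out=grid.like(ones * 7),
        tested=grid.like(ones),
    )


class TestVoxelwiseTMap:
    def test_matches_scipy_ttest_everywhere(self):
        grid, vta_sets, severity = _random_vta_cohort(n=14, seed=2)
        config = MappingConfig(min_group=2)
        sm = voxelwise_tmap(vta_sets, severity, config=config, grid=grid)
        coverage = np.stack([
            vs[0].mask.values.ravel().astype(bool) for vs in vta_sets
        ])
        tested = sm.tested.values.ravel().astype(bool)
        idx = np.flatnonzero(tested)
        assert idx.size > 100
        t_flat = sm.t.values.ravel()
        p_flat = sm.p.values.ravel()
        for v in idx[:: max(1, idx.size // 200)]:
            s_in = severity[coverage[:, v]]
            s_out = severity[~coverage[:, v]]
            ref = scipy.stats.ttest_ind(s_in, s_out, equal_var=True)
            assert t_flat[v] == pytest.approx(ref.statistic, abs=1e-10)
            assert p_flat[v] == pytest.approx(ref.pvalue, abs=1e-10)

    def test_group_counts_partition_cohort(self):
        grid, vta_sets, severity = _random_vta_cohort(n=12, seed=3)
        sm = voxelwise_tmap(vta_sets, severity, MappingConfig(min_group=2), grid)
        tested = sm.tested.values.astype(bool)
        total = sm.n_in.values[tested] + sm.n_out.values[tested]
        assert np.all(total == 12)

    def test_identical_severities_give_t0_p1(self):
        grid, vta_sets, _ = _random_vta_cohort(n=10, seed=4)
        sm = voxelwise_tmap(vta_sets, np.ones(10), MappingConfig(min_group=2), grid)
        tested = sm.tested.values.astype(bool)
        assert np.all(sm.t.values[tested] == 0)
        assert np.all(sm.p.values[tested] == 1)

    def test_direction_convention_stimulated_worse_positive(self):
        # patients covering the center have higher severity -> t > 0 there
        grid = make_grid((-3, -3, -3), (13, 13, 13), 0.5)
        vta_sets, severity = [], []
        for i in range(6):
            vta_sets.append([voxelize_vta((0, 0, 0), 1.5, grid)])
            severity.append(2.0 + 0.01 * i)
        for i in range(6):
            vta_sets.append([voxelize_vta((2.4, 0, 0), 0.6, grid)])
            severity.append(0.0 + 0.01 * i)
        sm = voxelwise_tmap(vta_sets, np.array(severity),
                            MappingConfig(min_group=3), grid)
        center = tuple(np.round(sm.t.world_to_voxel((0, 0, 0))[0]).astype(int))
        assert sm.t.values[center] > 10


class TestExtractSpot:
    def test_512_voxel_cube_retained(self):
        spot = extract_spot(_statmap_with_cube(8), "sour")
        assert len(spot.cluster_table) == 1
        assert spot.cluster_table[0]["voxel_count"] == 512
        assert spot.n_voxels == 512

    def test_343_voxel_cube_dropped(self):
        spot = extract_spot(_statmap_with_cube(7), "sour")
        assert spot.cluster_table == []
        assert spot.n_voxels == 0

    def test_corner_touching_cubes_form_one_cluster(self):
        grid = make_grid((0, 0, 0), (20, 20, 20), 0.5)
        t = np.zeros((20, 20, 20))
        p = np.ones((20, 20, 20))
        t[:7, :7, :7] = 3.0
        t[7:14, 7:14, 7:14] = 3.0  # touches the first cube only at a corner
        p[t > 0] = 0.01
        ones = np.ones((20, 20, 20))
        sm = StatMap(grid.like(t), grid.like(p), grid.like(ones * 7),
                     grid.like(ones * 7), grid.like(ones))
        spot = extract_spot(sm, "sour", MappingConfig(min_cluster_voxels=500))
        assert len(spot.cluster_table) == 1
        assert spot.cluster_table[0]["voxel_count"] == 686

    def test_polarity_sign_filter(self):
        sm = _statmap_with_cube(8, t_value=-3.0)
        assert extract_spot(sm, "sour").n_voxels == 0
        sweet = extract_spot(sm, "sweet")
        assert sweet.n_voxels == 512
        assert np.all(sweet.weight.values[sweet.mask.values.astype(bool)] > 0)

    def test_retained_sizes_bounded_by_suprathreshold(self):
        sm = _statmap_with_cube(9)
        spot = extract_spot(sm, "sour")
        with np.errstate(invalid="ignore"):
            supra = int(((sm.p.values < 0.05) & (sm.t.values > 0)).sum())
        assert sum(c["voxel_count"] for c in spot.cluster_table) <= supra
        assert spot.n_voxels == supra  # single cluster, all pass


class TestScorePatient:
    def _spot(self, grid, w=2.0):
        mask = np.zeros(grid.shape)
        mask[:10, :10, :10] = 1
        return SpotMap(grid.like(mask), grid.like(mask * w), "sour")

    def test_fully_inside_uniform_cluster(self):
        grid = make_grid((0, 0, 0), (20, 20, 20), 0.5)
        spot = self._spot(grid, w=2.0)
        vta = voxelize_vta((2, 2, 2), 1.0, grid)
        assert score_patient(spot, [vta]) == pytest.approx(2.0)

    def test_disjoint_vta_scores_zero(self):
        grid = make_grid((0, 0, 0), (20, 20, 20), 0.5)
        spot = self._spot(grid)
        vta = voxelize_vta((8, 8, 8), 1.0, grid)
        assert score_patient(spot, [vta]) == 0.0

    def test_half_overlap_halves_weight(self):
        grid = make_grid((0, 0, 0), (20, 20, 20), 0.5)
        spot = self._spot(grid, w=3.0)
        # hand-made VTA: 4 voxels inside the cluster, 4 outside
        mask = np.zeros(grid.shape)
        mask[0, 0, :4] = 1
        mask[15, 15, :4] = 1
        from pallidomap.data_model import VTA

        vta = VTA("p", "right", (0, 0, 0), 1.0, grid.like(mask))
        assert score_patient(spot, [vta]) == pytest.approx(1.5)

    def test_linear_in_weight_scale(self):
        grid = make_grid((0, 0, 0), (20, 20, 20), 0.5)
        vta = voxelize_vta((3, 3, 3), 1.5, grid)
        s1 = score_patient(self._spot(grid, 1.0), [vta])
        s4 = score_patient(self._spot(grid, 4.0), [vta])
        assert s4 == pytest.approx(4 * s1)


class TestLeaveOneOut:
    def test_planted_recovery_voxel_level(self, loo_results):
        assert loo_results["fit"]["r2"] > 0.05
        assert loo_results["fit"]["p"] < 0.05

    def test_strong_effect_fit(self):
        from dataclasses import replace

        from pallidomap.mapping import MappingCohort
        from pallidomap.synthetic_data import SyntheticConfig, generate_cohort

        cfg = replace(SyntheticConfig(), effect_beta=4.0, noise_sd=0.2)
        cohort = generate_cohort(cfg, seed=1)
        mc = MappingCohort.from_vtas(
            [r.patient_id for r in cohort.records],
            cohort.vta_sets, cohort.severity, cohort.grid,
        )
        assert loo_fit(mc)["r2"] > 0.3

    def test_planted_recovery_patient_level(self, loo_results):
        pred = loo_results["predict"]
        assert 0.05 < pred["r2"] < 0.6
        assert pred["r"] > 0

    def test_small_cohort_rejected(self):
        grid, vta_sets, severity = _random_vta_cohort(n=3, seed=5)
        from pallidomap.mapping import MappingCohort

        mc = MappingCohort.from_vtas(["a", "b", "c"], vta_sets, severity, grid)
        with pytest.raises(ValueError, match="n >= 10"):
            loo_fit(mc)
        with pytest.raises(ValueError, match="n >= 10"):
            loo_predict(mc)

    def test_null_cohorts_calibrated(self, null_calibration):
        # with no planted effect the LOOCV correlation should almost never
        # be significantly positive, and voxel-level R^2 should collapse
        assert null_calibration["pred_sig_pos"].mean() <= 0.10
        assert np.percentile(null_calibration["fit_r2"], 95) < 0.15

    def test_null_map_cluster_rate_reported(self, null_calibration):
        # uncorrected-p + size rule is not FWER-controlled; measure the
        # empirical map-wise cluster rate and keep it under the design bound
        assert null_calibration["any_cluster"].mean() <= 0.20


class TestStratify:
    def test_even_tertiles(self):
        res = stratify(np.arange(1, 10), np.arange(1, 10))
        assert res["strata_sizes"] == {"low": 3, "medium": 3, "high": 3}

    def test_planted_cohort_low_vs_high_significant(self, std_cohort, loo_results):
        pred = loo_results["predict"]["predicted"]
        res = stratify(pred, std_cohort.severity)
        by_pair = {c["pair"]: c for c in res["comparisons"]}
        assert by_pair["low_vs_high"]["p_fdr"] < 0.05

    def test_identical_observations_give_p1(self):
        res = stratify(np.arange(9), np.ones(9))
        assert all(c["p"] == 1.0 for c in res["comparisons"])

    def test_too_few_patients_rejected(self):
        with pytest.raises(ValueError):
            stratify(np.array([1.0, 2.0]), np.array([1.0, 2.0]))


class TestDice:
    def test_identical_masks(self):
        grid = make_grid((0, 0, 0), (10, 10, 10), 0.5)
        grid.values[:5] = 1
        assert dice(grid, grid) == 1.0

    def test_disjoint_masks(self):
        a = make_grid((0, 0, 0), (10, 10, 10), 0.5)
        b = make_grid((0, 0, 0), (10, 10, 10), 0.5)
        a.values[:3] = 1
        b.values[7:] = 1
        assert dice(a, b) == 0.0

    def test_counting_example(self):
        a = make_grid((0, 0, 0), (10, 10, 10), 0.5)
        b = make_grid((0, 0, 0), (10, 10, 10), 0.5)
        a.values.ravel()[:100] = 1
        b.values.ravel()[50:150] = 1
        assert dice(a, b) == pytest.approx(0.5)

    def test_grid_mismatch_rejected(self):
        a = make_grid((0, 0, 0), (10, 10, 10), 0.5)
        b = make_grid((1, 0, 0), (10, 10, 10), 0.5)
        with pytest.raises(GridMismatchError):
            dice(a, b)

    def test_both_empty_warns_zero(self):
        a = make_grid((0, 0, 0), (5, 5, 5), 0.5)
        with pytest.warns(UserWarning):
            assert dice(a, a) == 0.0
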