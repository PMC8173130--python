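import numpy as np
import pytest

from hypoximap import (
    PatientObservation,
    ThresholdGrid,
    clinical_spec,
    km_estimator,
    logrank_test,
    simulate_clinical_cohort,
    split_cohort,
    stratify_cohort,
    survival_sweep_1d,
    survival_sweep_2d,
)

from oracles import logrank_chi2, logrank_permutation_distribution, product_limit


def _patients(hfs, key="true"):
    return [
        PatientObservation(patient_id=f"P{i:03d}", hf_mri={key: h})
        for i, h in enumerate(hfs)
    ]


class TestSplit:
    def test_eighty_patients_split_26_54(self, rng):
        patients = _patients(rng.random(80))
        high, low = split_cohort(patients, "true")
        assert (len(high), len(low)) == (26, 54)

    @pytest.mark.parametrize("n", [3, 4, 5, 7, 9, 10, 33, 80])
    def test_group_sizes_floor_n_over_three(self, n, rng):
        high, low = split_cohort(_patients(rng.random(n)), "true")
        assert len(high) == n // 3
        assert len(high) + len(low) == n

    def test_highest_hf_patients_in_high_group(self):
        high, low = split_cohort(_patients(np.arange(1, 10) / 10), "true")
        assert sorted(p.hf_mri["true"] for p in high) == [0.7, 0.8, 0.9]

    def test_three_patients_distinct_hf(self):
        high, low = split_cohort(_patients([0.2, 0.9, 0.5]), "true")
        assert len(high) == 1
        assert high[0].hf_mri["true"] == 0.9

    def test_boundary_ties_warned_and_deterministic(self):
        patients = _patients([0.5, 0.5, 0.5, 0.1, 0.1, 0.1])
        with pytest.warns(UserWarning, match="ties"):
            high, low = split_cohort(patients, "true")
        assert [p.patient_id for p in high] == ["P000", "P001"]

    def test_missing_hf_excluded_with_warning(self):
        patients = _patients([0.1, 0.5, 0.9, 0.3])
        patients[1].hf_mri.clear()
        with pytest.warns(UserWarning, match="excluded"):
            high, low = split_cohort(patients, "true")
        assert len(high) + len(low) == 3


class TestKaplanMeier:
    def test_no_events_survival_stays_one(self):
        c = km_estimator([5, 8, 12, 20, 30], [False] * 5)
        assert c.survival_at(100.0) == 1.0

    def test_single_event_among_four(self):
        c = km_estimator([10, 12, 15, 20], [True, False, False, False])
        assert c.survival_at(10) == pytest.approx(0.75)

    def test_hand_product_limit_with_censoring(self):
        # events at 6 and 10 and 15; censored at 7:
        # S(10) = (3/4) * (1/2) = 0.375
        c = km_estimator([6, 7, 10, 15], [True, False, True, True])
        assert c.survival_at(10) == pytest.approx(0.375)

    def test_matches_empirical_survival_without_censoring(self, rng):
        times = rng.exponential(10, 40).round(2)
        c = km_estimator(times, np.ones(40, bool))
        for t in np.quantile(times, [0.1, 0.5, 0.9]):
            assert c.survival_at(t) == pytest.approx(np.mean(times > t))

    def test_matches_product_limit_oracle(self, rng):
        times = rng.exponential(10, 30).round(1)
        events = rng.random(30) < 0.7
        if not events.any():
            events[0] = True
        ot, os_ = product_limit(times, events)
        c = km_estimator(times, events)
        assert np.allclose(c.survival_at(ot), os_)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            km_estimator([], [])


class TestLogrank:
    def test_identical_groups_give_zero_statistic(self):
        t, e = [3, 6, 9, 12], [1, 0, 1, 1]
        res = logrank_test((t, e), (t, e))
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_label_swap_symmetry(self, rng):
        t1, t2 = rng.exponential(10, 8), rng.exponential(20, 8)
        e1, e2 = np.ones(8, bool), rng.random(8) < 0.7
        a = logrank_test((t1, e1), (t2, e2))
        b = logrank_test((t2, e2), (t1, e1))
        assert a.chi_square == pytest.approx(b.chi_square)
        assert a.p_value == pytest.approx(b.p_value)

    def test_zero_events_degenerate(self):
        res = logrank_test(([1, 2], [0, 0]), ([3, 4], [0, 0]))
        assert res.degenerate
        assert res.p_value == 1.0

    def test_statistic_matches_hypergeometric_oracle(self, rng):
        for _ in range(10):
            t = rng.exponential(10, 10).round(1)
            e = rng.random(10) < 0.8
            if not e.any():
                continue
            g = np.zeros(10, bool)
            g[:5] = True
            res = logrank_test((t[g], e[g]), (t[~g], e[~g]))
            assert res.chi_square == pytest.approx(logrank_chi2(t, e, g), rel=1e-9)

    def test_separated_groups_against_exhaustive_permutations(self):
        """The spec's fully separated 3-vs-3 cohort: the chi-square p-value
        must fall inside the exact permutation bracket [P(S>s0), P(S>=s0)]
        (the exact test only resolves p to its atom, here 1/20)."""
        t = np.array([1, 2, 3, 10, 20, 30], float)
        e = np.ones(6, bool)
        g = np.array([1, 1, 1, 0, 0, 0], bool)
        s0 = logrank_chi2(t, e, g)
        stats = logrank_permutation_distribution(t, e, 3)
        res = logrank_test((t[g], e[g]), (t[~g], e[~g]))
        assert np.mean(stats > s0 + 1e-9) <= res.p_value <= np.mean(stats >= s0 - 1e-9)

    def test_permutation_oracle_agreement_on_small_cohorts(self, rng):
        """On 8-patient cohorts the asymptotic p agrees with the exhaustive
        permutation mid-p within 0.1 — the resolution of an exact
        distribution whose atoms reach ~0.1 at these sizes."""
        for _ in range(15):
            t = rng.exponential(10, 8).round(1)
            e = rng.random(8) < 0.8
            if e.sum() == 0:
                continue
            g = np.zeros(8, bool)
            g[:4] = True
            s0 = logrank_chi2(t, e, g)
            stats = logrank_permutation_distribution(t, e, 4)
            mid_p = 0.5 * (np.mean(stats >= s0 - 1e-9) + np.mean(stats > s0 + 1e-9))
            res = logrank_test((t[g], e[g]), (t[~g], e[~g]))
            assert abs(res.p_value - mid_p) <= 0.1


class TestStratify:
    def test_full_stratification_result(self, rng):
        patients, _ = simulate_clinical_cohort(clinical_spec(n=30, seed=5))
        res = stratify_cohort(patients, "true")
        assert len(res.high_ids) == 10
        assert len(res.low_ids) == 20
        for ep in ("dfs", "os"):
            assert 0.0 <= res.logrank[ep].p_value <= 1.0
            assert res.km_high[ep].survival_at(0.0) <= 1.0


@pytest.fixture(scope="module")
def mapped_cohort():
    patients, maps = simulate_clinical_cohort(
        clinical_spec(n=45, seed=11), include_maps=True
    )
    return patients, maps


class TestSweeps:
    def test_single_threshold_grid_equals_one_logrank(self, mapped_cohort):
        patients, maps = mapped_cohort
        grid = ThresholdGrid(k0trans_values=np.array([0.015]))
        sw = survival_sweep_1d(patients, "ktrans_only", grid, "dfs", maps=maps)
        from hypoximap.survival import hf_matrix_from_maps

        hf = hf_matrix_from_maps(patients, maps, "ktrans_only", grid.k0trans_values)
        high, low = split_cohort(patients, hf_values=hf[:, 0])
        th, eh = zip(*(p.endpoint("dfs") for p in high))
        tl, el = zip(*(p.endpoint("dfs") for p in low))
        direct = logrank_test((th, eh), (tl, el))
        assert sw.p_values[0] == pytest.approx(direct.p_value)
        assert sw.optimal_k0trans == pytest.approx(0.015)

    def test_degenerate_thresholds_recorded_missing(self, mapped_cohort):
        patients, maps = mapped_cohort
        # far below any voxel value every patient has HF = 0 -> no split
        grid = ThresholdGrid(k0trans_values=np.array([1e-8, 0.015]))
        sw = survival_sweep_1d(patients, "ktrans_only", grid, "dfs", maps=maps)
        assert np.isnan(sw.p_values[0])
        assert np.isfinite(sw.p_values[1])
        assert sw.n_tested == 1

    def test_2d_surface_max_ve0_column_equals_1d_sweep(self, mapped_cohort):
        patients, maps = mapped_cohort
        k0s = np.round(np.arange(0.005, 0.051, 0.005), 10)
        grid2 = ThresholdGrid(k0trans_values=k0s, ve0_values=np.array([0.3, 2.0]))
        grid1 = ThresholdGrid(k0trans_values=k0s)
        sw2 = survival_sweep_2d(patients, "conjunction", grid2, "dfs", maps=maps)
        sw1 = survival_sweep_1d(patients, "ktrans_only", grid1, "dfs", maps=maps)
        assert np.allclose(sw2.p_values[:, 1], sw1.p_values, equal_nan=True)

    def test_2d_optimum_not_worse_than_shared_axis_1d(self, mapped_cohort):
        patients, maps = mapped_cohort
        k0s = np.round(np.arange(0.005, 0.051, 0.005), 10)
        grid2 = ThresholdGrid(k0trans_values=k0s, ve0_values=np.array([0.3, 2.0]))
        sw2 = survival_sweep_2d(patients, "conjunction", grid2, "dfs", maps=maps)
        col = sw2.p_values[:, 1]
        assert sw2.optimal_p <= np.nanmin(col) + 1e-12

    def test_hazard_dependent_cohort_yields_significant_range(self):
        patients, maps = simulate_clinical_cohort(
            clinical_spec(seed=2), include_maps=True
        )
        grid = ThresholdGrid(k0trans_values=np.round(np.arange(0.005, 0.101, 0.005), 10))
        sw = survival_sweep_1d(patients, "ktrans_only", grid, "dfs", maps=maps)
        sig = sw.significant_mask
        assert sig.any()
        assert sw.optimal_p < 0.05
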