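"""Regional ΔR statistics: primitives and the DeltaRModel procedure."""

import numpy as np
import pandas as pd
import pytest

from intracort.cohort import make_longitudinal_cohort
from intracort.longitudinal import (
    DeltaRModel,
    adjust_for_confounds,
    age_overlap_subset,
    compute_delta_r,
    delta_z,
    fwe_correct,
    group_delta_difference,
    interpolate_reference_delta,
    isi_deviations,
    paired_t,
    region_zscores,
    rescale_delta_linear,
    vulnerability,
    welch_t,
)

from conftest import small_cohort_config


class TestIsiDeviations:
    def test_two_point_centering(self):
        assert isi_deviations([2.0, 4.0]).tolist() == [1.0, -1.0]

    def test_equal_isis_center_to_zero(self):
        assert np.allclose(isi_deviations([1.7] * 5), 0.0)

    def test_grand_mean_not_group_mean(self):
        hc = np.full(8, 3.3)
        tbi = np.full(4, 0.5)
        dev = isi_deviations(np.concatenate([hc, tbi]))
        grand = (8 * 3.3 + 4 * 0.5) / 12
        assert np.allclose(dev[:8], grand - 3.3)
        assert np.allclose(dev[8:], grand - 0.5)
        # group-wise centering would put both groups at zero instead
        assert not np.allclose(dev, 0.0)

    def test_rejects_empty_and_nonpositive(self):
        with pytest.raises(ValueError):
            isi_deviations([])
        with pytest.raises(ValueError):
            isi_deviations([1.0, 0.0])


class TestConfoundAdjustment:
    def test_pure_age_effect_removed_exactly(self):
        age = np.array([60.0, 65, 70, 75, 80, 85])
        sex = np.array([0, 1, 0, 1, 0, 1])
        values = 2.0 + 0.01 * age
        adj = adjust_for_confounds(values, age, sex)
        assert np.allclose(adj, values.mean(), atol=1e-10)

    def test_orthogonal_values_unchanged(self, rng):
        age = rng.uniform(60, 90, 200)
        sex = rng.integers(0, 2, 200)
        values = rng.normal(1.1, 0.05, 200)
        adj = adjust_for_confounds(values, age, sex)
        assert np.allclose(adj.mean(), values.mean(), atol=1e-12)
        assert abs(np.corrcoef(adj, age)[0, 1]) < 0.05  # only chance correlation
        # residual orthogonality to the design is exact
        assert abs(np.dot(adj - adj.mean(), age - age.mean())) < 1e-7 * np.abs(age).sum()

    def test_mean_preserved(self, rng):
        age = rng.uniform(20, 80, 50)
        sex = rng.integers(0, 2, 50)
        values = rng.normal(1.0, 0.1, 50) + 0.002 * age
        adj = adjust_for_confounds(values, age, sex)
        assert adj.mean() == pytest.approx(values.mean(), abs=1e-12)

    def test_rank_deficient_rejected(self):
        with pytest.raises(ValueError, match="rank"):
            adjust_for_confounds([1.0, 2, 3, 4], [70, 70, 70, 70], [0, 0, 0, 0])


class TestDeltaR:
    def test_headline_magnitude_convention(self):
        assert compute_delta_r(1.0, 0.8) == pytest.approx(-0.200, abs=1e-15)

    def test_no_change(self):
        assert compute_delta_r(1.1, 1.1) == 0.0

    def test_temporal_pole_scale_loss(self):
        assert compute_delta_r(0.96, 0.96 * 0.737) == pytest.approx(-0.263, abs=1e-12)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError):
            compute_delta_r(0.0, 1.0)


class TestRescaling:
    def test_linear_scaling_between_study_intervals(self):
        assert rescale_delta_linear(-0.066, 3.3, 0.5) == pytest.approx(-0.01, abs=1e-15)

    def test_identity_at_source_interval(self):
        assert rescale_delta_linear(-0.2, 0.5, 0.5) == -0.2

    def test_zero_delta(self):
        assert rescale_delta_linear(0.0, 1.0, 7.3) == 0.0

    def test_nonpositive_interval_rejected(self):
        with pytest.raises(ValueError):
            rescale_delta_linear(-0.1, 0.0, 0.5)


def _hc_table(deltas_by_subject, isis, n_regions=2):
    rows = []
    for (sid, dr), isi in zip(deltas_by_subject.items(), isis):
        for rid in range(n_regions):
            rows.append(dict(subject_id=sid, region_id=rid, visit="baseline",
                             R=1.0, isi_years=isi))
            rows.append(dict(subject_id=sid, region_id=rid, visit="followup",
                             R=1.0 + dr, isi_years=isi))
    return pd.DataFrame(rows)


class TestReferenceInterpolation:
    def test_equal_isis_reduce_to_plain_mean(self):
        table = _hc_table({"a": -0.01, "b": -0.03}, [0.5, 0.5])
        out = interpolate_reference_delta(table, 0.5)
        assert np.allclose(out, -0.02, atol=1e-12)

    def test_constant_rate_recovery(self):
        # both subjects decline at 2 %/yr over different intervals
        table = _hc_table({"a": -0.02 * 3.0, "b": -0.02 * 4.0}, [3.0, 4.0])
        out = interpolate_reference_delta(table, 0.5)
        assert np.allclose(out, -0.01, atol=1e-12)

    def test_single_subject(self):
        table = _hc_table({"a": -0.04}, [2.0])
        assert np.allclose(interpolate_reference_delta(table, 1.0), -0.02, atol=1e-12)


class TestTTests:
    def test_identical_paired_samples(self):
        res = paired_t([1.0, 1.1, 1.2], [1.0, 1.1, 1.2])
        assert res.statistic == 0.0 and res.pvalue == 1.0

    def test_paired_matches_textbook_formula(self):
        before = np.array([1.00, 1.05, 0.98, 1.10, 1.02])
        after = np.array([0.97, 1.01, 0.96, 1.08, 0.99])
        d = after - before
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        from scipy.stats import t as tdist

        p_hand = 2 * tdist.sf(abs(t_hand), len(d) - 1)
        res = paired_t(before, after)
        assert res.statistic == pytest.approx(t_hand, rel=1e-12)
        assert res.pvalue == pytest.approx(p_hand, rel=1e-12)

    def test_welch_matches_satterthwaite_formula(self):
        x = np.array([0.1, 0.2, 0.15, 0.3, 0.25])
        y = np.array([0.4, 0.5, 0.45, 0.55])
        vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
        t_hand = (x.mean() - y.mean()) / np.sqrt(vx + vy)
        df_hand = (vx + vy) ** 2 / (vx**2 / (len(x) - 1) + vy**2 / (len(y) - 1))
        res = welch_t(x, y)
        assert res.statistic == pytest.approx(t_hand, rel=1e-12)
        assert res.df == pytest.approx(df_hand, rel=1e-12)

    def test_welch_type_one_error_calibration(self, rng):
        hits = 0
        reps = 2000
        for _ in range(reps):
            x = rng.normal(0, 1.0, 12)
            y = rng.normal(0, 3.0, 30)
            if welch_t(x, y).pvalue < 0.05:
                hits += 1
        assert 0.035 < hits / reps < 0.065


class TestFamilywiseCorrection:
    def test_single_p_unchanged(self):
        _, p_adj = fwe_correct([0.03])
        assert p_adj[0] == pytest.approx(0.03)

    def test_holm_by_hand(self):
        reject, p_adj = fwe_correct([0.01, 0.04])
        assert np.allclose(p_adj, [0.02, 0.04])
        assert reject.all()

    def test_all_ones_never_rejected(self):
        reject, p_adj = fwe_correct([1.0] * 5)
        assert not reject.any()

    def test_bonferroni_option(self):
        _, p_adj = fwe_correct([0.01, 0.04], method="bonferroni")
        assert np.allclose(p_adj, [0.02, 0.08])


class TestMapScores:
    def test_zscores_standardize_across_regions(self, rng):
        x = rng.uniform(0.9, 1.3, 40)
        z = region_zscores(x)
        assert abs(z.mean()) < 1e-12
        assert abs(z.std(ddof=0) - 1.0) < 1e-12

    def test_identical_groups_give_zero_delta_z(self, rng):
        x = rng.uniform(0.9, 1.3, 20)
        assert np.allclose(delta_z(x, x), 0.0, atol=1e-12)

    def test_affine_rescaling_invariance(self, rng):
        """Scanner-induced affine shifts of one group cancel in Δz."""
        hc = rng.uniform(0.9, 1.3, 20)
        tbi = hc + rng.normal(0, 0.01, 20)
        base = delta_z(tbi, hc)
        rescaled = delta_z(1.7 * tbi + 0.3, hc)
        assert np.allclose(base, rescaled, atol=1e-12)

    def test_injected_deficit_is_extreme_negative(self, rng):
        hc = rng.uniform(1.0, 1.1, 10)
        tbi = hc.copy()
        tbi[3] -= 0.2  # acute occipital-style deficit
        dz = delta_z(tbi, hc)
        assert dz[3] == dz.min() and dz[3] < 0


class TestVulnerability:
    def test_uniform_regions_zero(self):
        assert np.allclose(vulnerability([-0.1, -0.1, -0.1]), 0.0)

    def test_leave_one_out_by_hand(self):
        v = vulnerability([-0.10, -0.20, -0.30])
        assert v[0] == pytest.approx((-0.10 - (-0.25)) / (-0.25), abs=1e-15)
        assert v[0] == pytest.approx(-0.60, abs=1e-15)

    def test_zero_loo_mean_flagged_nan(self):
        # exactly representable values so the leave-one-out mean is exactly 0
        v = vulnerability([0.25, 0.125, -0.125])
        assert np.isnan(v[0])


class TestGroupDifference:
    def test_identical_groups_zero_map(self):
        x = np.array([-0.2, -0.1])
        assert np.allclose(group_delta_difference(x, x), 0.0)

    def test_injected_difference(self):
        d = group_delta_difference(np.full(3, -0.20), np.full(3, -0.01))
        assert np.allclose(d, -0.19, atol=1e-15)

    def test_antisymmetry(self, rng):
        a, b = rng.normal(size=(2, 6))
        assert np.allclose(group_delta_difference(a, b), -group_delta_difference(b, a))


class TestAgeOverlap:
    @staticmethod
    def _cohort(hc_ages, tbi_ages):
        rows = []
        for i, a in enumerate(hc_ages):
            rows.append(dict(subject_id=f"h{i}", group="HC", age_years=a))
        for i, a in enumerate(tbi_ages):
            rows.append(dict(subject_id=f"t{i}", group="mTBI", age_years=a))
        return pd.DataFrame(rows)

    def test_direct_rule_application(self):
        sub = age_overlap_subset(self._cohort([60.0, 80.0], [40.0, 79.0]))
        kept = sub.groupby("group")["age_years"].apply(list).to_dict()
        assert kept == {"HC": [60.0], "mTBI": [79.0]}

    def test_full_overlap_is_identity(self):
        df = self._cohort([50.0, 55.0], [52.0, 58.0])
        assert len(age_overlap_subset(df)) == len(df)

    def test_disjoint_ages_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            age_overlap_subset(self._cohort([80.0, 90.0], [20.0, 30.0]))


class TestDeltaRModel:
    def test_recovers_injected_effects_noiseless(self, profile4):
        cfg = small_cohort_config(
            n=10, subject_random_sd=0.0, trajectory_sd=0.0, measurement_sd=0.0,
            age_log_slope=0.0, sex_log_effect=0.0, scanner_log_effect=0.0,
        )
        cfg.hc.isi_sd = 0.0
        cfg.tbi.isi_sd = 0.0
        cohort, _ = make_longitudinal_cohort(cfg, profile4)
        res = DeltaRModel(cohort, adjust="none").fit()
        t = res.region_table
        assert np.allclose(t.delta_r_tbi, -0.20, atol=1e-12)
        assert np.allclose(t.delta_r_hc, -0.01, atol=1e-12)
        assert np.allclose(t["diff"], -0.19, atol=1e-12)

    def test_pure_age_effect_leaves_group_difference(self, profile4):
        """Adding an age confound to the generator does not move the adjusted
        group ΔR difference."""
        base = small_cohort_config(n=30, seed=3, age_log_slope=0.0)
        with_age = small_cohort_config(n=30, seed=3, age_log_slope=-0.01)
        d = {}
        for key, cfg in (("none", base), ("age", with_age)):
            cohort, _ = make_longitudinal_cohort(cfg, profile4)
            d[key] = DeltaRModel(cohort).fit().region_table["diff"].to_numpy()
        assert np.allclose(d["none"], d["age"], atol=5e-3)

    def test_subject_missing_visit_rejected(self, profile4):
        cohort, _ = make_longitudinal_cohort(small_cohort_config(n=5), profile4)
        broken = cohort[~((cohort.subject_id == "hc000") & (cohort.visit == "followup"))]
        with pytest.raises(ValueError, match="baseline and one follow-up"):
            DeltaRModel(broken)
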