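"""Method-comparison regression, group statistics, and cluster inference."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage, stats

from echopipe import firstlevel as fl
from echopipe.compare import (
    MethodComparison,
    behavior_stats,
    bold_behavior_correlation,
    chi_square_counts,
    cluster_inference,
    find_clusters,
    group_contrast,
    slope_test_battery,
    summarize_behavior,
    wilcoxon_rank_sum,
    zmap_regression,
)
from echopipe.relaxometry import extract_single_echo
from echopipe.simulate import (
    GROUP_PROFILES,
    AcquisitionSpec,
    TaskDesign,
    build_trial_schedule,
    default_truth,
    render_echoes,
    simulate_behavior,
)


class TestZmapRegression:
    def test_identity_maps(self, rng):
        z = rng.standard_normal((6, 6, 4))
        mask = np.ones(z.shape, bool)
        slope, icept, r2, n = zmap_regression(z, z, mask)
        assert slope == pytest.approx(1.0)
        assert icept == pytest.approx(0.0, abs=1e-12)
        assert r2 == pytest.approx(1.0)
        assert n == z.size

    def test_halved_map(self, rng):
        z = rng.standard_normal((5, 5, 3))
        mask = np.ones(z.shape, bool)
        slope, _, r2, _ = zmap_regression(0.5 * z, z, mask)
        assert slope == pytest.approx(0.5)
        assert r2 == pytest.approx(1.0)

    def test_matches_normal_equation_oracle(self, rng):
        x = rng.standard_normal((4, 4, 4))
        y = 0.8 * x + rng.normal(0, 0.5, x.shape)
        mask = rng.random(x.shape) > 0.3
        slope, icept, r2, _ = zmap_regression(y, x, mask)

        xv, yv = x[mask], y[mask]
        sxx = ((xv - xv.mean()) ** 2).sum()
        sxy = ((xv - xv.mean()) * (yv - yv.mean())).sum()
        syy = ((yv - yv.mean()) ** 2).sum()
        assert slope == pytest.approx(sxy / sxx, rel=1e-10)
        assert icept == pytest.approx(yv.mean() - sxy / sxx * xv.mean(), rel=1e-10)
        assert r2 == pytest.approx(sxy**2 / (sxx * syy), rel=1e-10)

    def test_no_intercept_variant(self, rng):
        x = rng.standard_normal((4, 4, 2))
        y = 1.3 * x
        mask = np.ones(x.shape, bool)
        slope, icept, r2, _ = zmap_regression(y, x, mask, intercept=False)
        assert slope == pytest.approx(1.3)
        assert icept == 0.0 and r2 == pytest.approx(1.0)

    def test_zero_variance_reference_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            zmap_regression(np.ones((2, 2, 2)), np.ones((2, 2, 2)),
                            np.ones((2, 2, 2), bool))


def make_rows(slopes, method="weighted", group="HOA", r2=None):
    r2 = r2 if r2 is not None else np.full(len(slopes), 0.5)
    return [
        MethodComparison(subject=f"s{i}", method=method, group=group,
                         slope=float(s), intercept=0.0, r2=float(r),
                         n_voxels=100)
        for i, (s, r) in enumerate(zip(slopes, r2))
    ]


class TestSlopeBattery:
    def test_unit_slopes_give_zero_t(self):
        rows = make_rows(np.ones(10))
        out = slope_test_battery(rows)
        assert out["per_method"]["weighted"]["t_vs_1"] == pytest.approx(0.0)

    def test_identical_methods_zero_welch_t(self, rng):
        s = rng.normal(0.8, 0.1, 12)
        rows = make_rows(s, "weighted") + make_rows(s, "retroicor")
        out = slope_test_battery(rows)
        assert out["between_methods"]["slope"]["t"] == pytest.approx(0.0)

    def test_one_sample_t_matches_textbook_formula(self, rng):
        s = rng.normal(0.8, 0.1, 48)
        out = slope_test_battery(make_rows(s))
        m, sd = s.mean(), s.std(ddof=1)
        expected = (m - 1.0) / (sd / np.sqrt(48))
        entry = out["per_method"]["weighted"]
        assert entry["t_vs_1"] == pytest.approx(expected, rel=1e-10)
        assert entry["df"] == 47

    def test_group_anova_and_tukey_present(self, rng):
        rows = []
        for g, mean in [("HYA", 0.9), ("HOA", 0.8), ("WMH", 0.7)]:
            rows += make_rows(rng.normal(mean, 0.05, 8), group=g)
        out = slope_test_battery(rows)
        anova = out["group_anova"]["weighted"]["slope"]
        assert anova["F"] > 10
        assert len(anova["tukey"]) == 3

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            slope_test_battery(make_rows([0.8]))


class TestGroupContrast:
    def test_constant_covariate_is_noop(self, rng):
        maps = rng.standard_normal((8, 4, 4, 3))
        groups = ["A"] * 4 + ["B"] * 4
        plain = group_contrast(maps, groups)
        with_cov = group_contrast(maps, groups, covariates=np.ones(8))
        for key in plain.difference_z:
            assert np.allclose(plain.difference_z[key], with_cov.difference_z[key])

    def test_group_difference_recovered(self, rng):
        maps = rng.normal(0, 0.1, (20, 5, 5, 3))
        maps[:10, 2, 2, 1] += 2.0  # strong effect in group A only
        groups = ["A"] * 10 + ["B"] * 10
        res = group_contrast(maps, groups)
        assert res.difference_z["A>B"][2, 2, 1] > 5
        assert res.omnibus_p[2, 2, 1] < 1e-4

    def test_omnibus_f_matches_anova_for_two_groups(self, rng):
        maps = rng.standard_normal((12, 2, 2, 2))
        groups = ["A"] * 6 + ["B"] * 6
        res = group_contrast(maps, groups)
        v = maps[:, 0, 0, 0]
        f, p = stats.f_oneway(v[:6], v[6:])
        assert res.omnibus_f[0, 0, 0] == pytest.approx(f, rel=1e-9)
        assert res.omnibus_p[0, 0, 0] == pytest.approx(p, rel=1e-9)

    def test_small_groups_rejected(self, rng):
        maps = rng.standard_normal((3, 2, 2, 2))
        with pytest.raises(ValueError):
            group_contrast(maps, ["A", "A", "B"])

    def test_power_on_simulated_activation_difference(self):
        """A 1% vs 0% signal-change difference with n=10 per group is
        detected above the voxel threshold in the truth region."""
        acq = AcquisitionSpec(n_volumes=90, grid_shape=(8, 8, 5))
        task = TaskDesign(n_trials=30)
        detected = 0
        n_runs = 10
        for run in range(n_runs):
            maps, groups = [], []
            for subj in range(20):
                active = subj < 10
                seed = run * 100 + subj
                events = build_trial_schedule(task, seed=seed,
                                              run_duration_s=acq.duration_s)
                events = simulate_behavior(events, GROUP_PROFILES["HOA"],
                                           accuracy=1.0, seed=seed)
                truth = default_truth(
                    acq, seed=seed, activation=0.01 if active else 0.0,
                    physio_amplitude=0.0, structured_sd=0.0, thermal_sd=4.0,
                    t2star_ms=35.35,
                )
                sess = render_echoes(truth, acq, events)
                series = fl.highpass_temporal(
                    extract_single_echo(sess.echoes, 35.35), 50.0)
                dm = fl.build_design(events, tr_ms=acq.tr,
                                     n_volumes=acq.n_volumes)
                dm = fl.highpass_design(dm, acq.tr, 50.0)
                st = fl.fit_glm(series, dm)
                maps.append(st.cope["all_vs_baseline"])
                groups.append("active" if active else "control")
                if active:
                    truth_region = truth.activation_map["congruent"] > 0
            res = group_contrast(np.stack(maps), groups)
            if res.difference_z["active>control"][truth_region].max() > 2.32:
                detected += 1
        assert detected >= 0.9 * n_runs


class TestClusterInference:
    def test_empty_map_empty_result(self):
        assert find_clusters(np.zeros((5, 5, 5))) == []

    def test_cubic_block_single_cluster(self):
        z = np.zeros((7, 7, 7))
        z[2:5, 2:5, 2:5] = 3.0
        clusters = find_clusters(z, 2.32)
        assert len(clusters) == 1
        assert clusters[0].size == 27
        assert clusters[0].peak_z == pytest.approx(3.0)

    def test_diagonal_voxels_connected_26(self):
        z = np.zeros((4, 4, 4))
        z[0, 0, 0] = z[1, 1, 1] = 3.0
        assert len(find_clusters(z, 2.32)) == 1

    def test_no_suprathreshold_returns_empty_not_error(self, rng):
        maps = rng.normal(0, 1e-3, (6, 4, 4, 3))
        res = cluster_inference(maps, voxel_z=10.0, n_permutations=100, seed=0)
        assert res.clusters == []

    def test_strong_effect_flagged_significant(self, rng):
        maps = rng.normal(0, 0.5, (12, 8, 8, 6))
        maps[:, 2:5, 2:5, 2:4] += 3.0
        res = cluster_inference(maps, n_permutations=300, seed=1)
        assert res.significant
        assert res.significant[0].size >= 18

    def test_minimum_permutations_enforced(self, rng):
        with pytest.raises(ValueError):
            cluster_inference(rng.standard_normal((6, 4, 4, 3)),
                              n_permutations=50, seed=0)


class TestBehavior:
    def _subjects(self, rng, rt_shift=None):
        subjects, groups = {}, {}
        shift = rt_shift or {"HYA": -150.0, "HOA": 0.0, "WMH": 60.0}
        i = 0
        for group, n in [("HYA", 5), ("HOA", 6), ("WMH", 5)]:
            for _ in range(n):
                events = build_trial_schedule(TaskDesign(n_trials=40),
                                              seed=i)
                profile = {
                    "congruent": (600.0 + shift[group], 40.0),
                    "incongruent": (660.0 + shift[group], 40.0),
                }
                events = simulate_behavior(events, profile, accuracy=0.95,
                                           seed=i)
                sid = f"s{i:02d}"
                subjects[sid] = events
                groups[sid] = group
                i += 1
        return subjects, groups

    def test_identical_rts_give_zero_f(self):
        subjects, groups = {}, {}
        for i in range(6):
            events = build_trial_schedule(TaskDesign(n_trials=20), seed=0)
            profile = {"congruent": (600.0, 0.0), "incongruent": (600.0, 0.0)}
            subjects[f"s{i}"] = simulate_behavior(events, profile,
                                                  accuracy=1.0, seed=0)
            groups[f"s{i}"] = "A" if i < 3 else "B"
        out = behavior_stats(subjects, groups)
        assert out["anova"]["rt_correct"]["F"] == 0.0

    def test_group_effect_detected(self, rng):
        subjects, groups = self._subjects(rng)
        out = behavior_stats(subjects, groups)
        assert out["anova"]["rt_correct"]["p"] < 1e-4
        tukey = out["anova"]["rt_correct"]["tukey"]
        hya_wmh = tukey[(tukey.group_a == "HOA") & (tukey.group_b == "HYA")]
        assert hya_wmh["p_adj"].iloc[0] < 0.01

    def test_anova_matches_sums_of_squares_oracle(self, rng):
        subjects, groups = self._subjects(rng)
        out = behavior_stats(subjects, groups)
        df = out["summary"]
        vals = df["rt_correct"].to_numpy()
        labels = df["group"].to_numpy()
        grand = vals.mean()
        names = sorted(set(labels))
        ssb = sum(
            (labels == g).sum() * (vals[labels == g].mean() - grand) ** 2
            for g in names
        )
        ssw = sum(
            ((vals[labels == g] - vals[labels == g].mean()) ** 2).sum()
            for g in names
        )
        f_oracle = (ssb / (len(names) - 1)) / (ssw / (len(vals) - len(names)))
        assert out["anova"]["rt_correct"]["F"] == pytest.approx(f_oracle,
                                                                rel=1e-10)

    def test_executive_rt_is_condition_difference(self):
        events = build_trial_schedule(TaskDesign(n_trials=40), seed=2)
        events = simulate_behavior(
            events, {"congruent": (600.0, 0.0), "incongruent": (661.3, 0.0)},
            accuracy=1.0, seed=2,
        )
        summ = summarize_behavior(events)
        assert summ["rt_executive"] == pytest.approx(61.3)

    def test_wilcoxon_complete_separation(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = a + 100.0
        res = wilcoxon_rank_sum(a, b)
        assert res["W"] in (0.0, 25.0)
        assert res["method"] == "exact"

    def test_chi_square_counts(self):
        res = chi_square_counts([[10, 9], [17, 11], [10, 8]])
        table = np.array([[10, 9], [17, 11], [10, 8]])
        expected = stats.chi2_contingency(table)
        assert res["chi2"] == pytest.approx(expected.statistic)
        assert res["df"] == 2

    def test_missing_condition_cell_names_subject(self):
        events = build_trial_schedule(TaskDesign(n_trials=10), seed=3)
        events = simulate_behavior(events, GROUP_PROFILES["HOA"],
                                   accuracy=0.0, seed=3)
        with pytest.raises(ValueError, match="badsub"):
            behavior_stats({"badsub": events, "ok": events},
                           {"badsub": "A", "ok": "B"})


class TestCorrelation:
    def test_perfect_correlation(self):
        x = np.arange(10, dtype=float)
        r, r2, p = bold_behavior_correlation(x, x)
        assert r == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)

    def test_r_squared_algebraic_identity(self, rng):
        x = rng.standard_normal(30)
        y = 0.3 * x + rng.standard_normal(30)
        r, r2, _ = bold_behavior_correlation(x, y)
        cov = np.cov(x, y, ddof=1)
        expected = cov[0, 1] ** 2 / (cov[0, 0] * cov[1, 1])
        assert r2 == pytest.approx(expected, rel=1e-10)

    def test_null_p_values_roughly_uniform(self):
        ps = []
        for seed in range(200):
            g = np.random.default_rng(seed)
            _, _, p = bold_behavior_correlation(g.standard_normal(50),
                                                g.standard_normal(50))
            ps.append(p)
        assert 0.4 < np.mean(ps) < 0.6
        assert (np.array(ps) < 0.05).mean() < 0.12

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            bold_behavior_correlation(np.ones(5), np.arange(5.0))
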