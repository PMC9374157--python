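"""Pointwise statistics, cluster formation, and the sign-flip null."""

import itertools

import numpy as np
import pytest
from scipy import stats as sstats

from thetalink.cluster_stats import (
    pointwise_paired_stat,
    pointwise_rm_anova,
    rm_anova_contrasts,
    form_clusters,
    permutation_cluster_test,
    paired_cluster_test,
    rm_anova_cluster_tests,
    cohens_d_window,
)


class TestPointwiseStats:
    def test_matches_scipy_paired_t(self, rng):
        a = rng.standard_normal((10, 40)) + 0.5
        b = rng.standard_normal((10, 40))
        t = pointwise_paired_stat(a, b)
        ref = sstats.ttest_rel(a, b, axis=0).statistic
        assert np.allclose(t, ref)

    def test_identical_conditions_give_zero(self, rng):
        a = rng.standard_normal((8, 20))
        with pytest.warns(RuntimeWarning):
            t = pointwise_paired_stat(a, a)
        assert np.all(t == 0)

    def test_pure_main_effect_yields_null_interaction(self, rng):
        """2x2 cells built with only a factor-1 shift: the interaction
        contrast is exactly zero for every subject and timepoint."""
        base = rng.standard_normal((12, 30))
        shift = 1.0
        cells = {
            ("a1", "b1"): base + shift, ("a1", "b2"): base + shift,
            ("a2", "b1"): base, ("a2", "b2"): base,
        }
        F = pointwise_rm_anova(cells)
        assert np.allclose(F["interaction"], 0.0)
        assert F["factor1"].max() > 10  # the real effect is visible
        # and the F is the square of the paired t on the contrast
        contrast = rm_anova_contrasts(cells)["factor1"]
        t = pointwise_paired_stat(contrast, np.zeros_like(contrast))
        assert np.allclose(F["factor1"], t**2)


class TestFormClusters:
    def test_subthreshold_trace_gives_empty_list(self):
        assert form_clusters(np.zeros(50), threshold=2.0) == []

    def test_uniform_run_mass(self):
        trace = np.zeros(30)
        trace[5:15] = 3.0
        clusters = form_clusters(trace, threshold=2.0)
        assert clusters == [(5, 14, pytest.approx(30.0))]

    def test_interrupted_run_splits(self):
        trace = np.full(20, 3.0)
        trace[10] = 0.5
        clusters = form_clusters(trace, threshold=2.0)
        assert len(clusters) == 2

    def test_sign_change_splits_two_sided(self):
        trace = np.concatenate([np.full(5, 3.0), np.full(5, -3.0)])
        clusters = form_clusters(trace, threshold=2.0, tail="two-sided")
        assert len(clusters) == 2
        assert clusters[0][2] > 0 > clusters[1][2]

    def test_matches_bruteforce_scan(self, rng):
        trace = rng.standard_normal(200) * 2
        thr = 1.5
        ours = form_clusters(trace, thr, "two-sided")
        runs, cur = [], None
        for i, v in enumerate(trace):
            lab = np.sign(v) if abs(v) > thr else 0
            if cur is not None and (lab == 0 or lab != cur[2]):
                runs.append((cur[0], i - 1, float(trace[cur[0]:i].sum())))
                cur = None
            if lab != 0 and cur is None:
                cur = (i, None, lab)
        if cur is not None:
            runs.append((cur[0], len(trace) - 1, float(trace[cur[0]:].sum())))
        assert [(s, e) for s, e, _ in ours] == [(s, e) for s, e, _ in runs]
        assert np.allclose([m for *_, m in ours], [m for *_, m in runs])


class TestPermutationTest:
    def test_deterministic_under_seed(self, rng):
        diffs = rng.standard_normal((10, 60)) + 0.4
        times = np.arange(60) / 60.0
        r1 = permutation_cluster_test(diffs, times, 500, seed=42)
        r2 = permutation_cluster_test(diffs, times, 500, seed=42)
        assert [c.p_value for c in r1.clusters] == [c.p_value
                                                    for c in r2.clusters]

    def test_p_values_match_exhaustive_enumeration(self, rng):
        """Independent oracle: enumerate all 2^S sign assignments and count
        permutation maxima at least as large as the observed cluster mass."""
        S, T = 9, 40
        diffs = rng.standard_normal((S, T))
        diffs[:, 10:20] += 0.9
        times = np.arange(T, dtype=float)
        res = permutation_cluster_test(diffs, times, n_permutations=4000,
                                       seed=0, tail="two-sided")
        t_crit = sstats.t.ppf(0.975, S - 1)

        null_max = []
        for signs in itertools.product([1.0, -1.0], repeat=S):
            d = diffs * np.asarray(signs)[:, None]
            t = d.mean(0) / (d.std(0, ddof=1) / np.sqrt(S))
            masses = [abs(m) for *_, m in form_clusters(t, t_crit)]
            null_max.append(max(masses, default=0.0))
        null_max = np.asarray(null_max)
        for c in res.clusters:
            exact = max((null_max >= abs(c.mass)).mean(), 1 / 4000)
            assert c.p_value == pytest.approx(exact, abs=0.03)

    def test_observed_clusters_match_mne(self, rng):
        """Cross-check cluster formation and masses against the established
        implementation on the same threshold."""
        from mne.stats import permutation_cluster_1samp_test
        S, T = 12, 50
        diffs = rng.standard_normal((S, T))
        diffs[:, 20:30] += 1.0
        times = np.arange(T, dtype=float)
        t_crit = sstats.t.ppf(0.975, S - 1)
        ours = permutation_cluster_test(diffs, times, 1000, seed=1)
        _, clusters, p_mne, _ = permutation_cluster_1samp_test(
            diffs, threshold=t_crit, n_permutations=1024, tail=0, seed=0,
            verbose="error")
        def span(cl):
            idx = cl[0] if isinstance(cl, tuple) else cl
            if hasattr(idx, "start"):  # slice
                return int(idx.start), int(idx.stop) - 1
            idx = np.flatnonzero(idx) if idx.dtype == bool else idx
            return int(idx.min()), int(idx.max())
        mne_spans = sorted(span(cl) for cl in clusters)
        our_spans = sorted((c.start_idx, c.end_idx) for c in ours.clusters)
        assert our_spans == mne_spans
        # the dominant cluster p agrees within Monte-Carlo slack
        assert min(c.p_value for c in ours.clusters) == pytest.approx(
            float(p_mne.min()), abs=0.03)

    def test_one_sided_tail_only_forms_matching_sign(self, rng):
        diffs = rng.standard_normal((10, 50))
        diffs[:, 5:15] -= 1.2
        times = np.arange(50, dtype=float)
        res = permutation_cluster_test(diffs, times, 500, seed=3, tail="less")
        assert res.clusters and all(c.mass < 0 for c in res.clusters)

    def test_null_false_positive_rate_not_inflated(self, rng):
        hits = 0
        times = np.arange(50, dtype=float)
        n_sims = 150
        for _ in range(n_sims):
            diffs = rng.standard_normal((12, 50))
            res = permutation_cluster_test(diffs, times, 300, seed=rng)
            hits += any(c.p_value < 0.05 for c in res.clusters)
        assert hits / n_sims < 0.10

    def test_rm_anova_wrapper_uses_F_masses(self, rng):
        base = rng.standard_normal((10, 30))
        cells = {("x", "u"): base + 1.0, ("x", "v"): base + 1.0,
                 ("y", "u"): base, ("y", "v"): base}
        out = rm_anova_cluster_tests(cells, np.arange(30, dtype=float),
                                     n_permutations=300, seed=5)
        assert set(out) == {"factor1", "factor2", "interaction"}
        assert out["factor1"].stat_kind == "F"
        assert out["factor1"].significant()
        assert not out["interaction"].clusters

    def test_boundary_caveat_travels_with_results(self, rng):
        diffs = rng.standard_normal((8, 20))
        res = permutation_cluster_test(diffs, np.arange(20.0), 200, seed=0)
        assert "cautiously" in res.to_dict()["boundary_caveat"]


class TestCohensD:
    def test_textbook_window_differences(self):
        # per-subject window differences 1, 2, 3 -> mean 2, SD 1 -> d = 2
        a = np.array([[1.0] * 4, [2.0] * 4, [3.0] * 4])
        b = np.zeros_like(a)
        assert cohens_d_window(a, b, np.arange(4.0), (0, 3)) == pytest.approx(2.0)

    def test_degenerate_zero_spread_flagged(self):
        a = np.ones((3, 4))
        with pytest.warns(RuntimeWarning):
            d = cohens_d_window(a, a, np.arange(4.0), (0, 3))
        assert np.isnan(d)

    def test_recovers_simulated_effect(self, rng):
        d_true = 0.6
        ds = []
        for _ in range(300):
            diffs = rng.standard_normal((30, 8)) * 0.1
            per = d_true + rng.standard_normal(30)
            a = per[:, None] + diffs
            ds.append(cohens_d_window(a, np.zeros_like(a),
                                      np.arange(8.0), (0, 7)))
        assert np.mean(ds) == pytest.approx(d_true, abs=0.15)
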