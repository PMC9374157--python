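"""Mixed models, the fast REML path, mediation, and behavioral tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from thetalink.inference import (
    RandomSlopeREML,
    fit_lmm,
    mediation_analysis,
    behavioral_tests,
)


def _lmm_table(seed, S=18, n=60, task_eff=-250.0, theta_eff=-35.0,
               sd_int=80.0, sd_slope=40.0, resid=120.0):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(S):
        b0 = rng.normal(0, sd_int)
        b1 = rng.normal(0, sd_slope)
        for t in range(n):
            task = float(t % 2)
            theta = 1 + 0.15 * task + rng.normal(0, 0.25)
            rt = (900 + b0 + (task_eff + b1) * task + theta_eff * theta
                  + rng.normal(0, resid))
            rows.append((s, task, theta, rt))
    return pd.DataFrame(rows,
                        columns=["subject_id", "task_mem", "theta", "rt_ms"])


class TestFastREML:
    """The sufficient-statistics fitter must agree with statsmodels MixedLM."""

    @pytest.mark.parametrize("seed", [1, 2])
    def test_matches_statsmodels(self, seed):
        import statsmodels.regression.mixed_linear_model as mlm
        df = _lmm_table(seed)
        X = np.column_stack([np.ones(len(df)), df["theta"], df["task_mem"]])
        Z = np.column_stack([np.ones(len(df)), df["task_mem"]])
        ref = mlm.MixedLM(df["rt_ms"].to_numpy(), X,
                          groups=df["subject_id"].to_numpy(),
                          exog_re=Z).fit(reml=True, method="lbfgs")
        ours = RandomSlopeREML(df["rt_ms"].to_numpy(), X,
                               df["task_mem"].to_numpy(),
                               df["subject_id"].to_numpy()).fit()
        assert np.allclose(ours["beta"], np.asarray(ref.fe_params), rtol=1e-4)
        assert np.allclose(ours["se"], np.asarray(ref.bse_fe), rtol=1e-3)
        assert ours["sigma2"] == pytest.approx(ref.scale, rel=1e-3)
        assert np.allclose(np.diag(ours["psi"]),
                           np.diag(np.asarray(ref.cov_re)), rtol=0.02)

    def test_batch_agrees_with_scalar_fits(self):
        df = _lmm_table(3)
        X = np.column_stack([np.ones(len(df)), df["theta"], df["task_mem"]])
        f = RandomSlopeREML(df["rt_ms"].to_numpy(), X,
                            df["task_mem"].to_numpy(),
                            df["subject_id"].to_numpy())
        warm = f.fit()["theta"]
        idx = np.random.default_rng(0).integers(0, f.n_subjects, (6, f.n_subjects))
        betas, ok = f.fit_batch(idx, start=warm)
        assert ok.all()
        for i in range(6):
            ref = f.fit(idx[i], start=warm)
            assert np.allclose(betas[i], ref["beta"], atol=1e-3)


class TestFitLMM:
    def test_recovers_task_effect_within_ci(self):
        df = _lmm_table(11, task_eff=-250.0)
        res = fit_lmm(df, "rt_ms ~ theta + task_mem")
        c = res.coef("task_mem")
        assert c["ci_lo"] < -250.0 < c["ci_hi"]
        assert res.converged

    def test_single_subject_rejected(self):
        df = _lmm_table(1, S=1)
        with pytest.raises(ValueError):
            fit_lmm(df, "rt_ms ~ task_mem")

    def test_result_surface(self):
        df = _lmm_table(12)
        res = fit_lmm(df, "rt_ms ~ task_mem")
        assert "residual" in res.random_sd
        assert "beta" in res.summary()
        d = res.to_dict()
        assert d["n_groups"] == 18


class TestMediation:
    @staticmethod
    def _table(seed, a=0.15, b=-40.0, S=14, n=50):
        rng = np.random.default_rng(seed)
        rows = []
        for s in range(S):
            b0, b1 = rng.normal(0, 80), rng.normal(0, 40)
            for t in range(n):
                task = float(t % 2)
                med = 1 + a * task + rng.normal(0, 0.25)
                rt = 700 + b0 + (450 + b1) * task + b * med + rng.normal(0, 120)
                rows.append((s, task, med, rt))
        return pd.DataFrame(
            rows, columns=["subject_id", "task_mem", "med", "rt_ms"])

    def test_no_mediator_path_covers_zero(self):
        res = mediation_analysis(self._table(5, b=0.0), "med", B=250, seed=1)
        lo, hi = res.acme["ci95"]
        assert lo <= 0.0 <= hi

    def test_known_product_recovered(self):
        res = mediation_analysis(self._table(6, a=0.2, b=-50.0), "med",
                                 B=250, seed=2)
        lo, hi = res.acme["ci95"]
        assert lo <= 0.2 * -50.0 <= hi
        assert res.acme["p_value"] < 0.05 or (lo <= -10.0 <= hi)

    def test_total_decomposes_into_acme_plus_ade(self):
        res = mediation_analysis(self._table(7), "med", B=250, seed=3)
        draws = res.draws
        assert np.allclose(draws["total"].mean(),
                           (draws["acme"] + draws["ade"]).mean(),
                           atol=3 * draws["total"].std())
        tot = res.total["estimate"]
        assert res.acme["estimate"] + res.ade["estimate"] == pytest.approx(
            tot, abs=0.1 * abs(tot))

    def test_bootstrap_reproducible(self):
        t = self._table(8)
        r1 = mediation_analysis(t, "med", B=200, seed=9)
        r2 = mediation_analysis(t, "med", B=200, seed=9)
        pd.testing.assert_frame_equal(r1.draws, r2.draws)

    def test_chain_models_reported(self):
        res = mediation_analysis(self._table(9), "med", B=200, seed=4)
        assert set(res.chain) == {"total", "mediator_model", "outcome_model"}
        assert "ACME" in res.summary()


class TestBehavioral:
    @staticmethod
    def _trials(impl_rt, mem_rt, subject_ids=None):
        rows = []
        n = len(impl_rt)
        ids = subject_ids or [f"s{i}" for i in range(n)]
        for i in range(n):
            for task, rt in (("implementation", impl_rt[i]),
                             ("memorization", mem_rt[i])):
                for j in range(3):
                    rows.append(dict(subject_id=ids[i], task=task,
                                     correct=True, catch=False,
                                     rt_ms=rt, trial_id=j))
        return pd.DataFrame(rows)

    def test_paired_t_matches_closed_form(self, rng):
        """Differences with mean 100 and SD 10 over 30 subjects give
        t = 100 / (10 / sqrt(30))."""
        n = 30
        u = rng.standard_normal(n)
        u = (u - u.mean()) / u.std(ddof=1)
        base = 700 + rng.uniform(-50, 50, n)
        mem = base + 100 + 10 * u
        rep = behavioral_tests(self._trials(base, mem))
        blk = rep["rt_regular"]
        expect = -100.0 / (10.0 / np.sqrt(30))
        if blk["test"] == "paired_t":
            assert blk["statistic"] == pytest.approx(expect, rel=1e-6)
        else:  # normality gate may fire on constructed data
            assert blk["p_value"] < 0.001

    def test_identical_distributions_give_null(self, rng):
        base = 700 + rng.standard_normal(12) * 30
        rep = behavioral_tests(self._trials(base, base + rng.standard_normal(12)))
        assert rep["rt_regular"]["p_value"] > 0.2

    def test_skewed_differences_trigger_wilcoxon(self, rng):
        base = 700 + rng.standard_normal(25) * 10
        skew = np.concatenate([np.full(20, 5.0), [300, 400, 500, 600, 700]])
        rep = behavioral_tests(self._trials(base, base + skew))
        assert rep["rt_regular"]["shapiro_p"] < 0.05
        assert rep["rt_regular"]["test"] == "wilcoxon"

    def test_error_rates_and_catch_split(self, tiny_sim):
        from thetalink import simulate_subject
        frames = []
        for i in range(6):
            _, tr = simulate_subject(tiny_sim, i, signals=False)
            frames.append(tr.assign(subject_id=f"sub-{i:02d}"))
        rep = behavioral_tests(pd.concat(frames, ignore_index=True))
        for key in ("rt_regular", "rt_catch", "error_regular", "error_catch"):
            assert "p_value" in rep[key] or "error" in rep[key]
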