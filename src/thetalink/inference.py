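"""Trial-level mixed models, the mediation chain, and behavioral group tests.

The four fixed-effect structures used by the pipeline are fixed a priori
(no model selection):

* ``rt_ms ~ task_mem``                    (total effect of task on RT)
* ``mediator ~ task_mem``                 (task -> theta path)
* ``rt_ms ~ mediator + task_mem``         (theta -> RT given task, direct path)
* ``plv ~ task_mem * contra``             (connectivity models)

all with a random intercept and a random task slope per subject,
REML-fitted.  Public fits go through statsmodels MixedLM; p-values use the
normal approximation on the Wald z (Satterthwaite degrees of freedom are
not available in this stack — the inferential behavior of the pipeline is
calibrated by simulation instead).

The causal mediation analysis estimates the average causal mediation effect
(ACME, the a*b path product), the average direct effect (ADE) and the total
effect, with uncertainty from a nonparametric bootstrap that resamples
subjects with replacement and refits the mediator and outcome models on
every draw.  The bootstrap inner loop uses an in-package profiled-REML
fitter specialized to the random-intercept + random-slope family; it
operates on per-subject sufficient statistics, so a draw costs a 3-parameter
optimization over tiny matrices regardless of trial counts.  Its estimates
agree with statsmodels MixedLM (tested), which remains the reporting path.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats as sstats
import statsmodels.formula.api as smf

logger = logging.getLogger(__name__)

__all__ = [
    "LMMResult",
    "MediationResult",
    "fit_lmm",
    "RandomSlopeREML",
    "mediation_analysis",
    "behavioral_tests",
]


# ---------------------------------------------------------------------------
# statsmodels-backed LMM
# ---------------------------------------------------------------------------


@dataclass
class LMMResult:
    """Fixed-effect estimates with normal-approximation inference."""

    formula: str
    fixed_effects: pd.DataFrame  # name, estimate, se, ci_lo, ci_hi, p_value
    random_sd: dict
    converged: bool
    intercept_only_fallback: bool = False
    n_obs: int = 0
    n_groups: int = 0

    def coef(self, name: str) -> dict:
        row = self.fixed_effects.loc[self.fixed_effects["name"] == name]
        if row.empty:
            raise KeyError(name)
        return row.iloc[0].to_dict()

    def summary(self) -> str:
        lines = [f"LMM (REML): {self.formula}",
                 f"  {self.n_obs} obs, {self.n_groups} subjects, "
                 f"converged={self.converged}"
                 + (" [intercept-only fallback]" if self.intercept_only_fallback else "")]
        for _, r in self.fixed_effects.iterrows():
            lines.append(
                f"  {r['name']:<22} beta={r['estimate']: .4g} "
                f"CI95=[{r['ci_lo']: .4g}, {r['ci_hi']: .4g}] p={r['p_value']:.4g}"
            )
        lines.append("  random SDs: "
                     + ", ".join(f"{k}={v:.4g}" for k, v in self.random_sd.items()))
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "formula": self.formula,
            "fixed_effects": self.fixed_effects.to_dict(orient="records"),
            "random_sd": self.random_sd,
            "converged": self.converged,
            "intercept_only_fallback": self.intercept_only_fallback,
            "n_obs": self.n_obs,
            "n_groups": self.n_groups,
        }


def fit_lmm(table: pd.DataFrame, formula: str, group: str = "subject_id",
            re_formula: str = "~task_mem") -> LMMResult:
    """REML fit of a fixed formula with random intercept + slope per subject.

    Singular random-effect fits fall back to a random-intercept-only
    structure, flagged in the result.
    """
    groups = table[group]
    n_groups = groups.nunique()
    if n_groups < 2:
        raise ValueError("mixed model needs at least 2 subjects")
    if n_groups < 10:
        warnings.warn(f"only {n_groups} subjects; fewer than recommended (>=10)",
                      RuntimeWarning, stacklevel=2)
    per = table.groupby(group).size().min()
    if per < 20:
        warnings.warn(f"as few as {per} trials/subject; fewer than recommended (>=20)",
                      RuntimeWarning, stacklevel=2)

    def _fit(re_f):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(formula, table, groups=groups, re_formula=re_f)
            return model.fit(reml=True, method="lbfgs")

    fallback = False
    res = _fit(re_formula)
    singular = (not res.converged) or (
        np.linalg.eigvalsh(np.atleast_2d(res.cov_re)).min() < 1e-8
    )
    if singular and re_formula not in ("1", "~1"):
        logger.info("singular random-effect fit for %s; falling back to "
                    "random intercept only", formula)
        fallback = True
        res = _fit("1")

    names = list(res.fe_params.index)
    est = res.fe_params.to_numpy()
    se = res.bse_fe.to_numpy()
    z = est / se
    p = 2 * sstats.norm.sf(np.abs(z))
    fe = pd.DataFrame({
        "name": names, "estimate": est, "se": se,
        "ci_lo": est - 1.959963984540054 * se,
        "ci_hi": est + 1.959963984540054 * se,
        "p_value": p,
        "df_approx": np.inf,  # normal approximation
    })
    cov_re = np.atleast_2d(res.cov_re.to_numpy())
    rnames = list(res.cov_re.index)
    random_sd = {rn: float(np.sqrt(max(cov_re[i, i], 0.0)))
                 for i, rn in enumerate(rnames)}
    random_sd["residual"] = float(np.sqrt(res.scale))
    return LMMResult(
        formula=formula, fixed_effects=fe, random_sd=random_sd,
        converged=bool(res.converged), intercept_only_fallback=fallback,
        n_obs=len(table), n_groups=n_groups,
    )


# ---------------------------------------------------------------------------
# fast profiled-REML fitter (random intercept + one random slope)
# ---------------------------------------------------------------------------


class RandomSlopeREML:
    """Profiled REML for y = X b + Z_i u_i + e with Z = [1, slope_var].

    Built once from trial-level data; per-subject sufficient statistics
    (X'X, X'y, Z'X, Z'Z, Z'y, y'y, n) make refits on subject-resampled
    index vectors (cluster bootstrap draws) nearly free.  The scaled
    random-effect covariance is parametrized by its log-Cholesky factor and
    optimized with Nelder-Mead; beta and the residual variance are profiled
    out in closed form.
    """

    def __init__(self, y: np.ndarray, X: np.ndarray, slope: np.ndarray,
                 groups: np.ndarray):
        y = np.asarray(y, float)
        X = np.asarray(X, float)
        Z = np.column_stack([np.ones_like(y), np.asarray(slope, float)])
        self.p = X.shape[1]
        uniq, inv = np.unique(groups, return_inverse=True)
        S = uniq.size
        self.n_subjects = S
        self.XtX = np.zeros((S, self.p, self.p))
        self.Xty = np.zeros((S, self.p))
        self.ZtX = np.zeros((S, 2, self.p))
        self.ZtZ = np.zeros((S, 2, 2))
        self.Zty = np.zeros((S, 2))
        self.yty = np.zeros(S)
        self.n = np.zeros(S)
        for s in range(S):
            m = inv == s
            Xs, Zs, ys = X[m], Z[m], y[m]
            self.XtX[s] = Xs.T @ Xs
            self.Xty[s] = Xs.T @ ys
            self.ZtX[s] = Zs.T @ Xs
            self.ZtZ[s] = Zs.T @ Zs
            self.Zty[s] = Zs.T @ ys
            self.yty[s] = ys @ ys
            self.n[s] = m.sum()

    # -- objective over theta = (log l00, l10, log l11) of Psi* = L L' --

    def _psi(self, theta):
        l00, l10, l11 = np.exp(theta[0]), theta[1], np.exp(theta[2])
        return np.array([[l00**2, l00 * l10],
                         [l00 * l10, l10**2 + l11**2]])

    def _profile(self, theta, idx):
        psi = self._psi(theta)
        ZtZ = self.ZtZ[idx]
        # M = I + (Z'Z) Psi ; C = Psi M^{-1} (symmetric by push-through)
        M = np.eye(2)[None] + ZtZ @ psi
        det = M[:, 0, 0] * M[:, 1, 1] - M[:, 0, 1] * M[:, 1, 0]
        if np.any(det <= 0) or not np.all(np.isfinite(det)):
            return None
        Minv = np.empty_like(M)
        Minv[:, 0, 0] = M[:, 1, 1]
        Minv[:, 1, 1] = M[:, 0, 0]
        Minv[:, 0, 1] = -M[:, 0, 1]
        Minv[:, 1, 0] = -M[:, 1, 0]
        Minv /= det[:, None, None]
        C = psi[None] @ Minv
        ZtX = self.ZtX[idx]
        Zty = self.Zty[idx]
        CZX = C @ ZtX
        CZy = (C @ Zty[:, :, None])[:, :, 0]
        XtWX = self.XtX[idx].sum(0) - np.einsum("naj,nak->jk", ZtX, CZX)
        XtWy = self.Xty[idx].sum(0) - np.einsum("na,naj->j", Zty, CZX)
        ytWy = self.yty[idx].sum() - np.einsum("na,na->", Zty, CZy)
        try:
            beta = np.linalg.solve(XtWX, XtWy)
        except np.linalg.LinAlgError:
            return None
        rss = ytWy - beta @ XtWy
        if not np.isfinite(rss) or rss <= 0:
            return None
        N = self.n[idx].sum()
        logdet_v = np.log(det).sum()
        sign, logdet_xwx = np.linalg.slogdet(XtWX)
        if sign <= 0:
            return None
        obj = (N - self.p) * np.log(rss) + logdet_v + logdet_xwx
        return obj, beta, rss, XtWX, N

    # -- batched evaluation over many bootstrap draws at once --

    def _gather(self, idx_mat: np.ndarray) -> dict:
        return dict(
            XtX=self.XtX[idx_mat], Xty=self.Xty[idx_mat],
            ZtX=self.ZtX[idx_mat], ZtZ=self.ZtZ[idx_mat],
            Zty=self.Zty[idx_mat], yty=self.yty[idx_mat],
            N=self.n[idx_mat].sum(axis=1),
        )

    def _profile_batch(self, theta: np.ndarray, sel: dict):
        """Profiled REML objective for a [B x 3] parameter batch, each row
        paired with its own subject resample (gathered in ``sel``)."""
        B = theta.shape[0]
        l00, l10, l11 = np.exp(theta[:, 0]), theta[:, 1], np.exp(theta[:, 2])
        psi = np.empty((B, 2, 2))
        psi[:, 0, 0] = l00**2
        psi[:, 0, 1] = psi[:, 1, 0] = l00 * l10
        psi[:, 1, 1] = l10**2 + l11**2
        M = np.eye(2)[None, None] + sel["ZtZ"] @ psi[:, None]
        det = M[..., 0, 0] * M[..., 1, 1] - M[..., 0, 1] * M[..., 1, 0]
        bad = (det <= 1e-12).any(axis=1) | ~np.isfinite(det).all(axis=1)
        det = np.where(det <= 1e-12, 1.0, det)
        Minv = np.empty_like(M)
        Minv[..., 0, 0] = M[..., 1, 1]
        Minv[..., 1, 1] = M[..., 0, 0]
        Minv[..., 0, 1] = -M[..., 0, 1]
        Minv[..., 1, 0] = -M[..., 1, 0]
        Minv /= det[..., None, None]
        C = psi[:, None] @ Minv
        CZX = C @ sel["ZtX"]
        XtWX = sel["XtX"].sum(1) - np.einsum("bnaj,bnak->bjk", sel["ZtX"], CZX)
        XtWy = sel["Xty"].sum(1) - np.einsum("bna,bnaj->bj", sel["Zty"], CZX)
        CZy = np.einsum("bnij,bnj->bni", C, sel["Zty"])
        ytWy = sel["yty"].sum(1) - np.einsum("bna,bna->b", sel["Zty"], CZy)
        sign, logdet_x = np.linalg.slogdet(XtWX)
        bad |= sign <= 0
        safe = np.where(bad[:, None, None], np.eye(self.p)[None], XtWX)
        beta = np.linalg.solve(safe, XtWy[..., None])[..., 0]
        rss = ytWy - np.einsum("bj,bj->b", beta, XtWy)
        bad |= ~np.isfinite(rss) | (rss <= 0)
        rss = np.where(bad, 1.0, rss)
        obj = ((sel["N"] - self.p) * np.log(rss)
               + np.log(det).sum(axis=1) + logdet_x)
        return np.where(bad, np.inf, obj), beta

    def fit_batch(self, idx_mat: np.ndarray, start=None, n_iter: int = 64,
                  step: float = 0.2):
        """REML fits for every row of a [B x S] subject-resample matrix via a
        vectorized Nelder-Mead over the 3 covariance parameters (all draws
        advance in lockstep).  Returns (beta [B x p], converged [B])."""
        idx_mat = np.asarray(idx_mat)
        sel = self._gather(idx_mat)
        B = idx_mat.shape[0]
        x0 = np.asarray(start if start is not None else [-0.5, 0.0, -0.5],
                        float)
        d = 3
        simplex = np.tile(x0, (B, d + 1, 1))
        for i in range(d):
            simplex[:, i + 1, i] += step
        fv = np.stack([self._profile_batch(simplex[:, i], sel)[0]
                       for i in range(d + 1)], axis=1)
        for _ in range(n_iter):
            order = np.argsort(fv, axis=1)
            simplex = np.take_along_axis(simplex, order[:, :, None], axis=1)
            fv = np.take_along_axis(fv, order, axis=1)
            centroid = simplex[:, :d].mean(axis=1)
            xr = centroid + (centroid - simplex[:, d])
            fr, _ = self._profile_batch(xr, sel)
            # expansion where the reflection is the new best
            expand = fr < fv[:, 0]
            if expand.any():
                xe = centroid + 2.0 * (centroid - simplex[:, d])
                fe, _ = self._profile_batch(xe, sel)
            else:
                xe, fe = xr, fr
            use_e = expand & (fe < fr)
            # contraction where the reflection is still the worst
            contract = fr >= fv[:, d - 1]
            if contract.any():
                xc = centroid + 0.5 * (simplex[:, d] - centroid)
                fc, _ = self._profile_batch(xc, sel)
            else:
                xc, fc = xr, np.full_like(fr, np.inf)
            use_c = contract & (fc < np.minimum(fr, fv[:, d]))
            shrink = contract & ~use_c
            new_x = np.where(use_e[:, None], xe,
                             np.where(use_c[:, None], xc, xr))
            new_f = np.where(use_e, fe, np.where(use_c, fc, fr))
            accept = ~shrink
            simplex[:, d] = np.where(accept[:, None], new_x, simplex[:, d])
            fv[:, d] = np.where(accept, new_f, fv[:, d])
            if shrink.any():
                sl = np.flatnonzero(shrink)
                simplex[sl, 1:] = (simplex[sl, :1]
                                   + 0.5 * (simplex[sl, 1:] - simplex[sl, :1]))
                for i in range(1, d + 1):
                    fv[sl, i], _ = self._profile_batch(simplex[sl, i],
                                                       self._gather(idx_mat[sl]))
        best = np.argmin(fv, axis=1)
        theta = np.take_along_axis(simplex, best[:, None, None], axis=1)[:, 0]
        obj, beta = self._profile_batch(theta, sel)
        return beta, np.isfinite(obj)

    def fit(self, idx=None, start=None, maxfev=200):
        """REML fit on the subjects in ``idx`` (with multiplicity).

        Returns dict with beta, se, sigma2, psi (unscaled covariance),
        converged flag.
        """
        if idx is None:
            idx = np.arange(self.n_subjects)
        idx = np.asarray(idx)
        theta0 = np.asarray(start if start is not None else [-0.5, 0.0, -0.5],
                            float)

        def f(theta):
            out = self._profile(theta, idx)
            return np.inf if out is None else out[0]

        res = optimize.minimize(f, theta0, method="Nelder-Mead",
                                options=dict(maxfev=maxfev, xatol=1e-4,
                                             fatol=1e-6))
        out = self._profile(res.x, idx)
        if out is None:
            return dict(beta=np.full(self.p, np.nan), se=None, sigma2=np.nan,
                        psi=None, theta=res.x, converged=False)
        _, beta, rss, XtWX, N = out
        sigma2 = rss / (N - self.p)
        cov_beta = sigma2 * np.linalg.inv(XtWX)
        return dict(beta=beta, se=np.sqrt(np.diag(cov_beta)), sigma2=sigma2,
                    psi=sigma2 * self._psi(res.x), theta=res.x,
                    converged=bool(np.isfinite(beta).all()))


# ---------------------------------------------------------------------------
# mediation
# ---------------------------------------------------------------------------


def _effect_dict(draws: np.ndarray, point: float) -> dict:
    lo, hi = np.percentile(draws, [2.5, 97.5])
    frac_le = np.mean(draws <= 0)
    frac_ge = np.mean(draws >= 0)
    p = min(1.0, max(2.0 * min(frac_le, frac_ge), 2.0 / max(draws.size, 1)))
    return {"estimate": float(point), "ci95": [float(lo), float(hi)],
            "p_value": float(p)}


@dataclass
class MediationResult:
    """ACME / ADE / total effect with subject-bootstrap uncertainty."""

    acme: dict
    ade: dict
    total: dict
    proportion_mediated: float
    B: int
    n_failed_draws: int
    seed: int
    chain: dict = field(default_factory=dict)  # Baron-Kenny LMMs
    draws: pd.DataFrame | None = None

    def summary(self) -> str:
        def fmt(name, e):
            return (f"  {name:<6} {e['estimate']: .4g} "
                    f"CI95=[{e['ci95'][0]: .4g}, {e['ci95'][1]: .4g}] "
                    f"p={e['p_value']:.4g}")
        return "\n".join([
            f"Causal mediation (subject bootstrap, B={self.B}, "
            f"{self.n_failed_draws} failed draws):",
            fmt("ACME", self.acme), fmt("ADE", self.ade),
            fmt("total", self.total),
            f"  proportion mediated: {self.proportion_mediated:.3f}",
        ])

    def to_dict(self) -> dict:
        return {
            "acme": self.acme, "ade": self.ade, "total": self.total,
            "proportion_mediated": self.proportion_mediated,
            "B": self.B, "n_failed_draws": self.n_failed_draws,
            "seed": self.seed,
            "chain": {k: v.to_dict() for k, v in self.chain.items()},
        }


def mediation_analysis(table: pd.DataFrame, mediator: str,
                       outcome: str = "rt_ms", treatment: str = "task_mem",
                       group: str = "subject_id", B: int = 1000,
                       seed: int = 0) -> MediationResult:
    """Mediation of the treatment effect on the outcome via the mediator.

    Evaluates the Baron-Kenny criterion chain first (treatment -> outcome,
    treatment -> mediator, mediator -> outcome given treatment), each as a
    random-intercept + treatment-slope LMM; then estimates ACME = a*b and
    ADE from the coefficient products, with percentile CIs from B
    nonparametric bootstrap draws resampling subjects with replacement and
    refitting all three models per draw.
    """
    if B < 200:
        warnings.warn("B < 200 bootstrap draws gives unstable CIs",
                      RuntimeWarning, stacklevel=2)
    cols = [outcome, mediator, treatment, group]
    data = table.loc[:, cols].dropna()

    chain = {
        "total": fit_lmm(data, f"{outcome} ~ {treatment}", group,
                         re_formula=f"~{treatment}"),
        "mediator_model": fit_lmm(data, f"{mediator} ~ {treatment}", group,
                                  re_formula=f"~{treatment}"),
        "outcome_model": fit_lmm(data, f"{outcome} ~ {mediator} + {treatment}",
                                 group, re_formula=f"~{treatment}"),
    }
    a = chain["mediator_model"].coef(treatment)["estimate"]
    b = chain["outcome_model"].coef(mediator)["estimate"]
    c_prime = chain["outcome_model"].coef(treatment)["estimate"]
    c_total = chain["total"].coef(treatment)["estimate"]

    # --- bootstrap with the sufficient-statistics REML fitter ---
    y = data[outcome].to_numpy()
    med = data[mediator].to_numpy()
    tr = data[treatment].to_numpy()
    g = data[group].to_numpy()
    ones = np.ones_like(y)
    fit_med = RandomSlopeREML(med, np.column_stack([ones, tr]), tr, g)
    fit_out = RandomSlopeREML(y, np.column_stack([ones, med, tr]), tr, g)
    fit_tot = RandomSlopeREML(y, np.column_stack([ones, tr]), tr, g)
    warm_med = fit_med.fit()["theta"]
    warm_out = fit_out.fit()["theta"]
    warm_tot = fit_tot.fit()["theta"]

    S = fit_med.n_subjects
    rng = np.random.default_rng(seed)
    idx_mat = rng.integers(0, S, size=(B, S))
    beta_med, ok_m = fit_med.fit_batch(idx_mat, start=warm_med)
    beta_out, ok_o = fit_out.fit_batch(idx_mat, start=warm_out)
    beta_tot, ok_t = fit_tot.fit_batch(idx_mat, start=warm_tot)
    ok = ok_m & ok_o & ok_t
    failed = int((~ok).sum())
    if not ok.any():
        raise RuntimeError("all bootstrap draws failed to converge")
    draws = pd.DataFrame({
        "acme": beta_med[ok, 1] * beta_out[ok, 1],
        "ade": beta_out[ok, 2],
        "total": beta_tot[ok, 1],
    })

    return MediationResult(
        acme=_effect_dict(draws["acme"].to_numpy(), a * b),
        ade=_effect_dict(draws["ade"].to_numpy(), c_prime),
        total=_effect_dict(draws["total"].to_numpy(), c_total),
        proportion_mediated=float((a * b) / c_total) if c_total != 0 else np.nan,
        B=B, n_failed_draws=failed, seed=seed, chain=chain, draws=draws,
    )


# ---------------------------------------------------------------------------
# behavioral group tests
# ---------------------------------------------------------------------------


def _paired_gate_test(impl: np.ndarray, mem: np.ndarray) -> dict:
    """Paired comparison with a Shapiro-Wilk normality gate on the
    differences: t test if normality holds, Wilcoxon signed-rank otherwise
    (exact null below 5 subjects)."""
    diffs = impl - mem
    n = diffs.size
    sw_p = float(sstats.shapiro(diffs).pvalue) if n >= 3 else np.nan
    use_wilcoxon = np.isfinite(sw_p) and sw_p < 0.05
    out = {
        "n": int(n),
        "mean_implementation": float(np.mean(impl)),
        "mean_memorization": float(np.mean(mem)),
        "shapiro_p": sw_p,
    }
    if use_wilcoxon:
        method = "exact" if n < 5 else "auto"
        res = sstats.wilcoxon(impl, mem, method=method)
        n_pairs = n * (n + 1) / 2
        out.update(test="wilcoxon", statistic=float(res.statistic),
                   p_value=float(res.pvalue),
                   effect_size=float(1.0 - 2.0 * res.statistic / n_pairs))
        logger.info("normality violated (Shapiro-Wilk p=%.3g); Wilcoxon used", sw_p)
    else:
        res = sstats.ttest_rel(impl, mem)
        sd = diffs.std(ddof=1)
        out.update(test="paired_t", statistic=float(res.statistic),
                   p_value=float(res.pvalue),
                   effect_size=float(diffs.mean() / sd) if sd > 0 else np.nan)
    return out


def behavioral_tests(group_trials: pd.DataFrame) -> dict:
    """Task comparisons of RT and error rate, regular and catch trials
    separately, from per-subject means (computed first)."""
    df = group_trials
    need = {"subject_id", "task", "correct", "catch", "rt_ms"}
    if not need <= set(df.columns):
        raise ValueError(f"missing columns {need - set(df.columns)}")

    def per_subject(value_fn, subset_fn):
        agg = {}
        for (sid, task), sub in df.groupby(["subject_id", "task"]):
            sub = subset_fn(sub)
            if len(sub):
                agg.setdefault(sid, {})[task] = value_fn(sub)
        keep = [s for s, v in agg.items()
                if "implementation" in v and "memorization" in v]
        impl = np.array([agg[s]["implementation"] for s in keep])
        mem = np.array([agg[s]["memorization"] for s in keep])
        return impl, mem

    report = {}
    specs = {
        "rt_regular": (lambda s: s["rt_ms"].mean(),
                       lambda s: s[~s["catch"] & s["correct"]
                                   & s["rt_ms"].notna()]),
        "rt_catch": (lambda s: s["rt_ms"].mean(),
                     lambda s: s[s["catch"] & s["correct"]
                                 & s["rt_ms"].notna()]),
        "error_regular": (lambda s: 1.0 - s["correct"].mean(),
                          lambda s: s[~s["catch"]]),
        "error_catch": (lambda s: 1.0 - s["correct"].mean(),
                        lambda s: s[s["catch"]]),
    }
    for name, (value_fn, subset_fn) in specs.items():
        impl, mem = per_subject(value_fn, subset_fn)
        if impl.size < 3:
            report[name] = {"error": "fewer than 3 complete subjects"}
            continue
        report[name] = _paired_gate_test(impl, mem)
    return report
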