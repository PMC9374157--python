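"""Cluster-based sign-flip permutation statistics on time courses.

Pointwise paired t (or, for 2 x 2 within-subject designs, F = t^2 on the
effect contrast) with an alpha-level critical value forms candidate
clusters: maximal runs of contiguous suprathreshold samples sharing a sign.
Cluster mass is the sum of the pointwise statistic over the run.  The null
is built by randomly flipping the sign of each subject's condition
difference and recording the largest cluster mass per permutation; the
cluster p-value is the fraction of permutation maxima at least as large as
the observed mass (ties count against the observed; the denominator is the
permutation count, so the smallest reportable p is 1/n_permutations).

Cluster boundaries inherit only cluster-level inference: the first and last
samples of a cluster are not individually significant and must be
interpreted cautiously.  Every result carries this caveat.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

logger = logging.getLogger(__name__)

__all__ = [
    "BOUNDARY_CAVEAT",
    "Cluster",
    "ClusterResult",
    "pointwise_paired_stat",
    "pointwise_rm_anova",
    "form_clusters",
    "permutation_cluster_test",
    "paired_cluster_test",
    "rm_anova_cluster_tests",
    "cohens_d_window",
]

BOUNDARY_CAVEAT = (
    "Cluster boundaries reflect cluster-level inference only; the first and "
    "last time points of a cluster are not individually significant and must "
    "be interpreted cautiously."
)

TAILS = ("two-sided", "greater", "less")


@dataclass
class Cluster:
    start_s: float
    end_s: float
    start_idx: int
    end_idx: int  # inclusive
    mass: float
    p_value: float = np.nan
    effect_size_d: float | None = None

    def to_dict(self) -> dict:
        return {
            "start_s": self.start_s, "end_s": self.end_s,
            "mass": self.mass, "p_value": self.p_value,
            "effect_size_d": self.effect_size_d,
        }


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    stat_trace: np.ndarray
    times: np.ndarray
    threshold: float
    n_permutations: int
    tail: str
    alpha: float
    stat_kind: str = "t"  # 't' or 'F'
    boundary_caveat: str = BOUNDARY_CAVEAT

    def significant(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p_value < self.alpha]

    @property
    def min_p(self) -> float:
        return min((c.p_value for c in self.clusters), default=1.0)

    def to_dict(self) -> dict:
        return {
            "stat_kind": self.stat_kind,
            "tail": self.tail,
            "threshold": self.threshold,
            "n_permutations": self.n_permutations,
            "alpha": self.alpha,
            "clusters": [c.to_dict() for c in self.clusters],
            "n_significant": len(self.significant()),
            "boundary_caveat": self.boundary_caveat,
        }


# ---------------------------------------------------------------------------
# pointwise statistics
# ---------------------------------------------------------------------------


def _t_from_diffs(diffs: np.ndarray) -> np.ndarray:
    """Paired t trace from per-subject difference time courses [S x T].
    Zero-variance timepoints get t = 0 (cannot exceed any threshold)."""
    S = diffs.shape[0]
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    zero = sd == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} timepoints with zero variance; t set to 0",
                      RuntimeWarning, stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(zero, 0.0, mean / (sd / np.sqrt(S)))
    return t


def pointwise_paired_stat(cond_a: np.ndarray, cond_b: np.ndarray) -> np.ndarray:
    """Paired t trace between two [subjects x time] condition arrays."""
    cond_a, cond_b = np.asarray(cond_a, float), np.asarray(cond_b, float)
    if cond_a.shape != cond_b.shape or cond_a.shape[0] < 3:
        raise ValueError("conditions must share shape with >= 3 subjects")
    return _t_from_diffs(cond_a - cond_b)


def rm_anova_contrasts(cells: dict) -> dict[str, np.ndarray]:
    """Per-subject effect contrasts of a 2 x 2 within-subject design.

    ``cells`` maps (level_of_factor1, level_of_factor2) -> [subjects x time].
    Returns per-subject difference traces whose paired t (squared) is the
    rmANOVA F of each effect: main effects are averaged simple differences,
    the interaction is the double difference (A1-A2)-(B1-B2), which is
    exchangeable under the no-interaction null.
    """
    keys = list(cells.keys())
    lv1 = sorted({k[0] for k in keys})
    lv2 = sorted({k[1] for k in keys})
    if len(lv1) != 2 or len(lv2) != 2 or len(keys) != 4:
        raise ValueError("need a complete 2x2 cell dict")
    a11 = np.asarray(cells[(lv1[0], lv2[0])], float)
    a12 = np.asarray(cells[(lv1[0], lv2[1])], float)
    a21 = np.asarray(cells[(lv1[1], lv2[0])], float)
    a22 = np.asarray(cells[(lv1[1], lv2[1])], float)
    return {
        "factor1": ((a11 + a12) - (a21 + a22)) / 2.0,
        "factor2": ((a11 + a21) - (a12 + a22)) / 2.0,
        "interaction": (a11 - a12) - (a21 - a22),
    }


def pointwise_rm_anova(cells: dict) -> dict[str, np.ndarray]:
    """F traces (df = 1, n-1) for both main effects and the interaction of a
    2 x 2 within-subject design, computed from subject cell means."""
    return {name: _t_from_diffs(d) ** 2
            for name, d in rm_anova_contrasts(cells).items()}


# ---------------------------------------------------------------------------
# cluster formation
# ---------------------------------------------------------------------------


def form_clusters(stat_trace: np.ndarray, threshold: float,
                  tail: str = "two-sided") -> list[tuple[int, int, float]]:
    """Maximal contiguous suprathreshold runs with a common sign.

    Returns (start_idx, end_idx_inclusive, mass) triples; mass is the sum
    of the statistic over the run.
    """
    if tail not in TAILS:
        raise ValueError(f"tail must be one of {TAILS}")
    stat = np.asarray(stat_trace, float)
    if tail == "two-sided":
        label = np.sign(stat) * (np.abs(stat) > threshold)
    elif tail == "greater":
        label = (stat > threshold).astype(float)
    else:
        label = -(stat < -threshold).astype(float)
    out = []
    start = None
    for i in range(stat.size + 1):
        cur = label[i] if i < stat.size else 0.0
        prev = label[i - 1] if i > 0 else 0.0
        if cur != prev:
            if prev != 0.0 and start is not None:
                out.append((start, i - 1, float(stat[start:i].sum())))
            start = i if cur != 0.0 else None
    return out


def _perm_max_masses(t_mat: np.ndarray, threshold: float, tail: str
                     ) -> np.ndarray:
    """Largest cluster mass magnitude per row of a [perms x time] statistic
    matrix (vectorized run-length scan across all rows at once)."""
    P, T = t_mat.shape
    if tail == "two-sided":
        label = np.sign(t_mat) * (np.abs(t_mat) > threshold)
    elif tail == "greater":
        label = (t_mat > threshold).astype(float)
    else:
        label = -(t_mat < -threshold).astype(float)
    # pad a guard column of zeros so runs never span rows
    lab = np.concatenate([label, np.zeros((P, 1))], axis=1).ravel()
    st = np.concatenate([t_mat, np.zeros((P, 1))], axis=1).ravel()
    change = np.flatnonzero(np.diff(np.concatenate([[0.0], lab])) != 0)
    if change.size == 0:
        return np.zeros(P)
    bounds = np.concatenate([change, [lab.size]])
    cs = np.concatenate([[0.0], np.cumsum(st)])
    starts = bounds[:-1]
    ends = bounds[1:]
    run_label = lab[starts]
    keep = run_label != 0
    masses = np.abs(cs[ends[keep]] - cs[starts[keep]])
    rows = starts[keep] // (T + 1)
    out = np.zeros(P)
    np.maximum.at(out, rows, masses)
    return out


# ---------------------------------------------------------------------------
# permutation test
# ---------------------------------------------------------------------------


def permutation_cluster_test(
    diffs: np.ndarray,
    times: np.ndarray,
    n_permutations: int = 10_000,
    seed: int | np.random.Generator = 0,
    tail: str = "two-sided",
    alpha: float = 0.05,
    stat_kind: str = "t",
) -> ClusterResult:
    """Sign-flip max-cluster-mass permutation test on per-subject difference
    (or contrast) time courses [subjects x time].

    ``stat_kind='t'`` thresholds the paired t trace at the two-sided (or
    one-sided) alpha critical value; ``stat_kind='F'`` squares the trace and
    thresholds at the F(1, n-1) critical value, with mass summed in F units
    (clusters are then sign-free).  Sign flips are applied to the subject
    contrasts in both cases.
    """
    diffs = np.asarray(diffs, float)
    if diffs.ndim != 2 or diffs.shape[0] < 3:
        raise ValueError("diffs must be [subjects x time] with >= 3 subjects")
    if tail not in TAILS:
        raise ValueError(f"tail must be one of {TAILS}")
    if stat_kind not in ("t", "F"):
        raise ValueError("stat_kind must be 't' or 'F'")
    if stat_kind == "F" and tail != "two-sided":
        raise ValueError("one-sided tails require stat_kind='t'")
    if n_permutations < 100:
        warnings.warn("fewer than 100 permutations gives poor p resolution",
                      RuntimeWarning, stacklevel=2)
    S, T = diffs.shape
    dof = S - 1
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))

    if tail == "two-sided":
        t_crit = sstats.t.ppf(1.0 - alpha / 2.0, dof)
    else:
        t_crit = sstats.t.ppf(1.0 - alpha, dof)

    t_obs = _t_from_diffs(diffs)
    if stat_kind == "F":
        trace, threshold, eff_tail = t_obs**2, t_crit**2, "greater"
    else:
        trace, threshold, eff_tail = t_obs, t_crit, tail
    observed = form_clusters(trace, threshold, eff_tail)

    # vectorized permutation null: only the mean changes under sign flips
    signs = rng.integers(0, 2, size=(n_permutations, S)) * 2.0 - 1.0
    mean_p = (signs @ diffs) / S
    sumsq = (diffs**2).sum(axis=0)
    var_p = (sumsq - S * mean_p**2) / (S - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_p = np.where(var_p <= 0, 0.0, mean_p / np.sqrt(var_p / S))
    if stat_kind == "F":
        t_p = t_p**2
    null_max = _perm_max_masses(t_p, threshold, eff_tail)

    clusters = []
    for start, end, mass in observed:
        count = int(np.sum(null_max >= abs(mass)))
        p = max(count, 1) / n_permutations
        d = _cohens_d_from_diffs(diffs, start, end)
        clusters.append(Cluster(
            start_s=float(times[start]), end_s=float(times[end]),
            start_idx=int(start), end_idx=int(end),
            mass=float(mass), p_value=float(p), effect_size_d=d,
        ))
    clusters.sort(key=lambda c: c.start_idx)
    return ClusterResult(
        clusters=clusters, stat_trace=trace, times=np.asarray(times),
        threshold=float(threshold), n_permutations=n_permutations,
        tail=tail, alpha=alpha, stat_kind=stat_kind,
    )


def paired_cluster_test(cond_a, cond_b, times, **kwargs) -> ClusterResult:
    """Cluster permutation test of A vs B [subjects x time] (paired)."""
    cond_a, cond_b = np.asarray(cond_a, float), np.asarray(cond_b, float)
    if cond_a.shape != cond_b.shape:
        raise ValueError("conditions must share shape")
    return permutation_cluster_test(cond_a - cond_b, times, **kwargs)


def rm_anova_cluster_tests(cells: dict, times, n_permutations: int = 10_000,
                           seed: int = 0, alpha: float = 0.05
                           ) -> dict[str, ClusterResult]:
    """Cluster permutation tests for both main effects and the interaction
    of a 2 x 2 within-subject design, each via sign flips of the per-subject
    effect contrast, with F-unit cluster masses."""
    contrasts = rm_anova_contrasts(cells)
    rng = np.random.default_rng(seed)
    return {
        name: permutation_cluster_test(
            d, times, n_permutations=n_permutations, seed=rng,
            tail="two-sided", alpha=alpha, stat_kind="F",
        )
        for name, d in contrasts.items()
    }


# ---------------------------------------------------------------------------
# effect size
# ---------------------------------------------------------------------------


def _cohens_d_from_diffs(diffs: np.ndarray, start: int, end: int) -> float:
    per_subject = diffs[:, start:end + 1].mean(axis=1)
    sd = per_subject.std(ddof=1)
    if sd == 0:
        warnings.warn("zero SD of window differences; d undefined",
                      RuntimeWarning, stacklevel=2)
        return float(np.inf) if per_subject.mean() != 0 else float(np.nan)
    return float(per_subject.mean() / sd)


def cohens_d_window(cond_a, cond_b, times, window) -> float:
    """Cohen's d of the A-B difference averaged over a time window: mean of
    the per-subject window differences divided by their SD (n-1)."""
    cond_a, cond_b = np.asarray(cond_a, float), np.asarray(cond_b, float)
    times = np.asarray(times)
    mask = (times >= window[0] - 1e-12) & (times <= window[1] + 1e-12)
    if not mask.any():
        raise ValueError("empty window")
    idx = np.flatnonzero(mask)
    return _cohens_d_from_diffs(cond_a - cond_b, idx[0], idx[-1])
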