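"""End-to-end orchestration: simulated or on-disk group data in, structured
report out.

Stage order (all randomness seeded from the analysis config):

1. subject exclusion (low accuracy / catch-trial floor);
2. behavioral group tests;
3. alpha laterality rmANOVA clusters (correct trials, catch included —
   power analyses keep catch trials);
4. beta laterality x task rmANOVA clusters + the one-sided interaction
   (deeper contralateral suppression in implementation);
5. theta task contrast (one-sided: implementation > memorization) and the
   congruency control contrasts;
6. per-trial theta scalar (355-985 ms window on the 128 Hz power grid),
   SD trimming, RT/theta mixed models and causal mediation
   (correct regular trials only);
7. theta-phase connectivity table and PLV/wPLI mixed models, including the
   parahippocampal control pair (correct regular trials only).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dataio import (
    AnalysisConfig,
    EpochSet,
    ROIDefinition,
    DEFAULT_BANDS,
    read_epochs,
    read_trials,
    read_rois,
    subject_exclusion,
    trim_by_sd,
    congruent_mask,
    DataFormatError,
)
from .synthetic import SimConfig, iter_group, default_rois
from .spectral import (
    morlet_band_power,
    roi_timecourse_pca_flip,
    lateralize,
    mean_window_power,
    check_edge_margin,
    window_mask,
)
from .connectivity import build_connectivity_table
from .cluster_stats import (
    paired_cluster_test,
    rm_anova_cluster_tests,
    BOUNDARY_CAVEAT,
)
from .inference import fit_lmm, mediation_analysis, behavioral_tests

logger = logging.getLogger(__name__)

__all__ = ["RunReport", "run_all", "congruency_contrasts",
           "subject_features", "load_group"]

CONGRUENCY_CAVEAT = (
    "Separate significance of within-task or within-congruency contrasts "
    "cannot be taken as evidence for an interaction between the factors."
)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


@dataclass
class RunReport:
    """Structured result of a full pipeline run."""

    provenance: dict
    exclusions: dict
    trial_accounting: dict
    behavioral: dict
    oscillatory: dict
    mediation: object
    connectivity: dict

    def to_dict(self) -> dict:
        def conv(v):
            if hasattr(v, "to_dict"):
                return v.to_dict()
            if isinstance(v, dict):
                return {k: conv(x) for k, x in v.items()}
            return v
        return _jsonable({
            "provenance": self.provenance,
            "exclusions": self.exclusions,
            "trial_accounting": self.trial_accounting,
            "behavioral": self.behavioral,
            "oscillatory": conv(self.oscillatory),
            "mediation": conv(self.mediation),
            "connectivity": conv(self.connectivity),
        })

    def to_json(self, path: str | Path | None = None, indent: int = 1) -> str:
        text = json.dumps(self.to_dict(), indent=indent, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def summary(self) -> str:
        d = self.to_dict()
        lines = [f"thetalink run report (v{d['provenance']['version']})",
                 f"subjects analyzed: {d['provenance']['n_subjects_analyzed']} "
                 f"(excluded: {list(d['exclusions']) or 'none'})", ""]
        rt = d["behavioral"].get("rt_regular", {})
        if "p_value" in rt:
            lines.append(
                f"RT regular: {rt['mean_implementation']:.0f} vs "
                f"{rt['mean_memorization']:.0f} ms ({rt['test']}, "
                f"stat={rt['statistic']:.2f}, p={rt['p_value']:.3g})")
        for name, block in d["oscillatory"].items():
            if name == "theta_congruency":
                continue
            effects = block if "clusters" not in block else {"": block}
            for eff, res in effects.items():
                if not isinstance(res, dict) or "clusters" not in res:
                    continue
                sig = [c for c in res["clusters"] if c["p_value"] < res["alpha"]]
                tag = f"{name}{('/' + eff) if eff else ''}"
                if sig:
                    c = min(sig, key=lambda c: c["p_value"])
                    lines.append(
                        f"{tag}: significant cluster {c['start_s']:.3f}-"
                        f"{c['end_s']:.3f} s, p={c['p_value']:.4g}, "
                        f"d={c['effect_size_d']:.2f}" if c["effect_size_d"]
                        else f"{tag}: significant cluster p={c['p_value']:.4g}")
                else:
                    lines.append(f"{tag}: no significant cluster")
        med = d["mediation"]
        lines.append(
            f"mediation: ACME={med['acme']['estimate']:.3g} "
            f"CI95={med['acme']['ci95']} p={med['acme']['p_value']:.3g}; "
            f"ADE={med['ade']['estimate']:.3g} p={med['ade']['p_value']:.3g}")
        for meas, pairs in d["connectivity"].items():
            for pair, res in pairs.items():
                fe = {r["name"]: r for r in res["fixed_effects"]}
                t = fe.get("task_mem")
                if t:
                    lines.append(f"{meas} {pair}: task beta={t['estimate']:.4g} "
                                 f"p={t['p_value']:.3g}")
        lines += ["", BOUNDARY_CAVEAT]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# per-subject feature extraction
# ---------------------------------------------------------------------------


def subject_features(epochs: EpochSet, trials: pd.DataFrame,
                     rois: list[ROIDefinition], cfg: AnalysisConfig) -> dict:
    """All group-analysis inputs for one subject; the raw epoch array can be
    freed afterwards (streaming)."""
    roi_by_name = {r.name: r for r in rois}
    alpha, beta, theta = (DEFAULT_BANDS[b] for b in ("alpha", "beta", "theta"))
    for band in (alpha, beta, theta):
        check_edge_margin(epochs.tmin, epochs.tmax, band, cfg.analysis_window)

    correct = trials["correct"].to_numpy()
    is_catch = trials["catch"].to_numpy()
    is_impl = (trials["task"] == "implementation").to_numpy()
    power_keep = correct  # power analyses: correct trials, catch included

    def roi_power(name, band):
        tc = roi_timecourse_pca_flip(epochs.data, roi_by_name[name])
        return morlet_band_power(tc, epochs.srate, band, epochs.tmin,
                                 out_srate=cfg.power_srate, roi=name)

    out: dict = {"subject_id": epochs.subject_id}

    # behavioral aggregates for exclusion
    reg = ~is_catch
    out["accuracy"] = float(correct[reg].mean())
    out["catch_accuracy"] = {
        task: float(correct[is_catch & (trials["task"] == task).to_numpy()].mean())
        for task in ("implementation", "memorization")
    }

    # alpha from LatOcc, lateralized by cued side
    p_l = roi_power("LatOcc_L", alpha)
    p_r = roi_power("LatOcc_R", alpha)
    times = p_l.times
    contra, ipsi = lateralize(p_l.values, p_r.values,
                              trials["cued_side"].to_numpy())
    out["power_times"] = times
    out["alpha_cells"] = {
        (task, lat): arr[power_keep & (is_impl == (task == "implementation"))]
        .mean(axis=0)
        for task in ("implementation", "memorization")
        for lat, arr in (("contralateral", contra), ("ipsilateral", ipsi))
    }

    # beta from Hand, lateralized by response side
    p_l = roi_power("Hand_L", beta)
    p_r = roi_power("Hand_R", beta)
    contra, ipsi = lateralize(p_l.values, p_r.values,
                              trials["response_side"].to_numpy())
    out["beta_cells"] = {
        (task, lat): arr[power_keep & (is_impl == (task == "implementation"))]
        .mean(axis=0)
        for task in ("implementation", "memorization")
        for lat, arr in (("contralateral", contra), ("ipsilateral", ipsi))
    }

    # theta from bilateral mPFC: task means, congruency cells, trial scalar
    p_theta = roi_power("mPFC", theta)
    cong = congruent_mask(trials).to_numpy()
    out["theta_task"] = {
        task: p_theta.values[power_keep & (is_impl == (task == "implementation"))]
        .mean(axis=0)
        for task in ("implementation", "memorization")
    }
    out["theta_congruency"] = {}
    for task in ("implementation", "memorization"):
        for cg in (True, False):
            m = power_keep & (is_impl == (task == "implementation")) & (cong == cg)
            key = (task, "congruent" if cg else "incongruent")
            out["theta_congruency"][key] = (
                p_theta.values[m].mean(axis=0) if m.any() else None)

    out["theta_scalar"] = mean_window_power(p_theta.values, p_theta.times,
                                            cfg.plv_window)

    # connectivity rows (correct regular trials only)
    out["connectivity"] = build_connectivity_table(epochs, trials, rois, cfg)

    out["trials"] = trials.assign(subject_id=epochs.subject_id)
    return out


# ---------------------------------------------------------------------------
# group data sources
# ---------------------------------------------------------------------------


def load_group(data_dir: str | Path):
    """Yield (EpochSet, trials, rois) per subject from the on-disk layout:
    <data_dir>/rois.json plus one sub-directory per subject."""
    data_dir = Path(data_dir)
    subdirs = sorted(p for p in data_dir.iterdir()
                     if p.is_dir() and (p / "epochs.h5").exists())
    if not subdirs:
        raise DataFormatError(f"no subject directories under {data_dir}")
    rois = read_rois(data_dir)
    for sub in subdirs:
        epochs = read_epochs(sub)
        trials = read_trials(sub)
        yield epochs, trials, rois


# ---------------------------------------------------------------------------
# group analyses
# ---------------------------------------------------------------------------


def _stack_cells(features: list[dict], key: str) -> dict:
    cells = {}
    for cell in features[0][key]:
        cells[cell] = np.stack([f[key][cell] for f in features])
    return cells


def _window_slice(arr_dict: dict, times: np.ndarray,
                  window: tuple[float, float]):
    mask = window_mask(times, window)
    return ({k: v[:, mask] for k, v in arr_dict.items()}, times[mask])


def congruency_contrasts(theta_cells: dict, times: np.ndarray,
                         n_permutations: int, seed: int, alpha: float
                         ) -> dict:
    """Theta control contrasts: congruent vs incongruent within each task,
    and task within each congruency level.  Two-sided paired cluster tests;
    a caveat records that separate significance is not an interaction."""
    out: dict = {"caveat": CONGRUENCY_CAVEAT}
    tests = {
        "congruency_in_implementation":
            (("implementation", "congruent"), ("implementation", "incongruent")),
        "congruency_in_memorization":
            (("memorization", "congruent"), ("memorization", "incongruent")),
        "task_in_congruent":
            (("implementation", "congruent"), ("memorization", "congruent")),
        "task_in_incongruent":
            (("implementation", "incongruent"), ("memorization", "incongruent")),
    }
    for i, (name, (ka, kb)) in enumerate(tests.items()):
        a, b = theta_cells.get(ka), theta_cells.get(kb)
        if a is None or b is None:
            logger.info("congruency contrast %s skipped: empty cell", name)
            out[name] = {"skipped": "empty congruency cell"}
            continue
        out[name] = paired_cluster_test(
            a, b, times, n_permutations=n_permutations,
            seed=seed + i, tail="two-sided", alpha=alpha)
    return out


def run_all(sim_config: SimConfig | None = None,
            data_dir: str | Path | None = None,
            analysis: AnalysisConfig | None = None) -> RunReport:
    """Execute the full analysis on a simulated or on-disk group dataset."""
    if (sim_config is None) == (data_dir is None):
        raise ValueError("provide exactly one of sim_config or data_dir")
    cfg = (analysis or AnalysisConfig()).validate()
    seed = cfg.rng_seed

    if sim_config is not None:
        sim_config.validate()
        rois = default_rois(sim_config)
        source = ((ep, tr, rois) for ep, tr in iter_group(sim_config))
    else:
        source = load_group(data_dir)

    features = []
    for epochs, trials, rois in source:
        logger.info("stage subject_features: %s", epochs.subject_id)
        features.append(subject_features(epochs, trials, rois, cfg))
        del epochs  # raw tensor no longer needed (streaming)

    # --- subject exclusion ---------------------------------------------------
    group_acc = [f["accuracy"] for f in features]
    exclusions = {}
    kept = []
    for f in features:
        keep, reasons = subject_exclusion(
            f["accuracy"], group_acc, f["catch_accuracy"],
            k=cfg.subject_excl_k, catch_floor=cfg.catch_acc_floor)
        if keep:
            kept.append(f)
        else:
            exclusions[f["subject_id"]] = reasons
    if len(kept) < 3:
        raise RuntimeError("stage subject_exclusion: fewer than 3 subjects survive")
    features = kept

    accounting: dict = {
        "n_subjects_input": len(group_acc),
        "n_subjects_analyzed": len(features),
        "n_subjects_excluded": len(exclusions),
    }

    # --- behavioral ----------------------------------------------------------
    group_trials = pd.concat([f["trials"] for f in features], ignore_index=True)
    behavioral = behavioral_tests(group_trials)

    # --- oscillatory cluster analyses ----------------------------------------
    times = features[0]["power_times"]
    osc: dict = {}

    alpha_cells, win_times = _window_slice(
        _stack_cells(features, "alpha_cells"), times, cfg.analysis_window)
    res = rm_anova_cluster_tests(alpha_cells, win_times,
                                 n_permutations=cfg.n_permutations,
                                 seed=seed + 1, alpha=cfg.alpha_level)
    osc["alpha_laterality"] = {"task": res["factor1"],
                               "laterality": res["factor2"],
                               "interaction": res["interaction"]}

    beta_cells, _ = _window_slice(
        _stack_cells(features, "beta_cells"), times, cfg.analysis_window)
    res = rm_anova_cluster_tests(beta_cells, win_times,
                                 n_permutations=cfg.n_permutations,
                                 seed=seed + 2, alpha=cfg.alpha_level)
    # directional interaction: contralateral suppression deeper in
    # implementation -> (contra - ipsi) smaller for implementation
    inter_diff = ((beta_cells[("implementation", "contralateral")]
                   - beta_cells[("implementation", "ipsilateral")])
                  - (beta_cells[("memorization", "contralateral")]
                     - beta_cells[("memorization", "ipsilateral")]))
    from .cluster_stats import permutation_cluster_test
    one_sided = permutation_cluster_test(
        inter_diff, win_times, n_permutations=cfg.n_permutations,
        seed=seed + 3, tail="less", alpha=cfg.alpha_level)
    osc["beta_laterality"] = {"task": res["factor1"],
                              "laterality": res["factor2"],
                              "interaction": res["interaction"],
                              "interaction_one_sided": one_sided}

    theta_cells, _ = _window_slice(
        _stack_cells(features, "theta_task"), times, cfg.analysis_window)
    osc["theta_task"] = paired_cluster_test(
        theta_cells["implementation"], theta_cells["memorization"], win_times,
        n_permutations=cfg.n_permutations, seed=seed + 4,
        tail="greater", alpha=cfg.alpha_level)

    cong_stacked = {}
    for cell in features[0]["theta_congruency"]:
        arrs = [f["theta_congruency"][cell] for f in features]
        if any(a is None for a in arrs):
            continue
        cong_stacked[cell] = np.stack(arrs)
    cong_sliced, _ = _window_slice(cong_stacked, times, cfg.analysis_window)
    osc["theta_congruency"] = congruency_contrasts(
        cong_sliced, win_times, cfg.n_permutations, seed + 10, cfg.alpha_level)

    # --- mediation ------------------------------------------------------------
    med_rows = []
    n_input = n_theta_trim = n_rt_trim = 0
    for f in features:
        tr = f["trials"].copy()
        tr["theta_scalar"] = f["theta_scalar"]
        tr = tr[~tr["catch"] & tr["correct"] & tr["rt_ms"].notna()]
        n_input += len(tr)
        keep_theta = trim_by_sd(tr["theta_scalar"].to_numpy(), cfg.trim_k)
        n_theta_trim += int((~keep_theta).sum())
        tr = tr[keep_theta]
        keep_rt = np.ones(len(tr), dtype=bool)
        for task, sub in tr.groupby("task"):
            if len(sub) >= 3:
                keep_rt[tr.index.get_indexer(sub.index)] &= trim_by_sd(
                    sub["rt_ms"].to_numpy(), cfg.trim_k)
        n_rt_trim += int((~keep_rt).sum())
        med_rows.append(tr[keep_rt])
    med_table = pd.concat(med_rows, ignore_index=True)
    med_table["task_mem"] = (med_table["task"] == "memorization").astype(float)
    accounting["mediation"] = {
        "n_correct_regular": n_input,
        "n_theta_trimmed": n_theta_trim,
        "n_rt_trimmed": n_rt_trim,
        "n_analyzed": len(med_table),
    }
    assert n_input == len(med_table) + n_theta_trim + n_rt_trim
    mediation = mediation_analysis(
        med_table, mediator="theta_scalar", outcome="rt_ms",
        treatment="task_mem", group="subject_id",
        B=cfg.mediation_B, seed=seed + 20)

    # --- connectivity ----------------------------------------------------------
    conn = pd.concat([f["connectivity"] for f in features], ignore_index=True)
    conn["task_mem"] = (conn["task"] == "memorization").astype(float)
    conn["contra"] = (conn["laterality"] == "contralateral").astype(float)
    connectivity: dict = {}
    for measure in ("plv", "wpli"):
        block = {}
        for pair in ("mPFC-Hand", "mPFC-LatOcc"):
            sub = conn[conn["roi_pair"] == pair]
            block[pair] = fit_lmm(sub, f"{measure} ~ task_mem * contra",
                                  group="subject_id", re_formula="~task_mem")
        sub = conn[conn["roi_pair"] == "mPFC-Control"]
        block["mPFC-Control"] = fit_lmm(sub, f"{measure} ~ task_mem",
                                        group="subject_id",
                                        re_formula="~task_mem")
        connectivity[measure] = block

    n_reg_correct = int((~group_trials["catch"] & group_trials["correct"]).sum())
    accounting["connectivity"] = {
        "n_correct_regular": n_reg_correct,
        "n_rows": len(conn),
        "rows_per_trial_pair_hemi": 1,
    }
    accounting["power_analyses"] = {
        "n_trials_input": len(group_trials),
        "n_correct_incl_catch": int(group_trials["correct"].sum()),
        "n_excluded_incorrect": int((~group_trials["correct"]).sum()),
    }
    assert (accounting["power_analyses"]["n_trials_input"]
            == accounting["power_analyses"]["n_correct_incl_catch"]
            + accounting["power_analyses"]["n_excluded_incorrect"])

    provenance = {
        "version": __version__,
        "seed": seed,
        "n_permutations": cfg.n_permutations,
        "analysis_config": cfg.to_dict(),
        "sim_config": sim_config.to_dict() if sim_config is not None else None,
        "data_dir": str(data_dir) if data_dir is not None else None,
        "n_subjects_analyzed": len(features),
    }
    return RunReport(
        provenance=provenance,
        exclusions=exclusions,
        trial_accounting=accounting,
        behavioral=behavioral,
        oscillatory=osc,
        mediation=mediation,
        connectivity=connectivity,
    )
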