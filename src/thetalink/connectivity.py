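"""Within-trial phase-synchronization estimators between ROI pairs.

PLV is computed within trial over time samples: the magnitude of the
time-averaged unit phasor of the phase difference.  The multivariate
region-pair estimate is the root mean square of the M x N matrix of
pairwise source PLVs.  wPLI weights phase consistency by the imaginary
cross-spectrum and ignores zero-lag coupling; its multivariate aggregation
mirrors the PLV RMS rule.  Connectivity always uses the raw-rate
(512 samples/s) filter-Hilbert theta phases, not the decimated power grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataio import (
    AnalysisConfig,
    EpochSet,
    ROIDefinition,
    ConfigError,
    DEFAULT_BANDS,
)
from .spectral import analytic_signal, bandpass_filter, window_mask

logger = logging.getLogger(__name__)

__all__ = [
    "plv_pair",
    "plv_multivariate",
    "WpliResult",
    "wpli_pair",
    "wpli_multivariate",
    "CONNECTIVITY_COLUMNS",
    "build_connectivity_table",
]

CONNECTIVITY_COLUMNS = [
    "subject_id", "trial_id", "task", "roi_pair", "laterality", "plv", "wpli",
]


def _check_phases(*arrays) -> None:
    for a in arrays:
        if not np.isfinite(a).all():
            raise ValueError("non-finite phases")


def plv_pair(phase1: np.ndarray, phase2: np.ndarray,
             times: np.ndarray | None = None,
             window: tuple[float, float] | None = None) -> float:
    """Phase-locking value between two phase series over the window samples.

    PLV = | mean_t exp(i (phi1 - phi2)) |; 1 for a constant phase
    difference, ~sqrt(pi)/(2 sqrt(T)) for independent uniform phases.
    """
    phase1 = np.asarray(phase1, dtype=float)
    phase2 = np.asarray(phase2, dtype=float)
    _check_phases(phase1, phase2)
    if window is not None:
        mask = window_mask(np.asarray(times), window)
        phase1, phase2 = phase1[..., mask], phase2[..., mask]
    if phase1.shape[-1] < 2:
        raise ValueError("need at least 2 samples")
    return float(np.abs(np.exp(1j * (phase1 - phase2)).mean()))


def plv_multivariate(phases_a: np.ndarray, phases_b: np.ndarray,
                     times: np.ndarray | None = None,
                     window: tuple[float, float] | None = None) -> float:
    """Multivariate PLV between two regions: RMS of all pairwise PLVs.

    ``phases_a`` is [M x time], ``phases_b`` [N x time]; the result is
    sqrt(mean of the M x N pairwise PLV matrix squared).  Equals
    :func:`plv_pair` exactly when M = N = 1.
    """
    pa = np.atleast_2d(np.asarray(phases_a, dtype=float))
    pb = np.atleast_2d(np.asarray(phases_b, dtype=float))
    _check_phases(pa, pb)
    if pa.shape[-1] != pb.shape[-1]:
        raise ValueError("phase series must share the time axis")
    if window is not None:
        mask = window_mask(np.asarray(times), window)
        pa, pb = pa[:, mask], pb[:, mask]
    T = pa.shape[-1]
    if T < 2:
        raise ValueError("need at least 2 samples")
    ea = np.exp(1j * pa)
    eb = np.exp(1j * pb)
    pairwise = np.abs(ea @ eb.conj().T) / T  # [M x N] of pairwise PLVs
    return float(np.sqrt(np.mean(pairwise**2)))


@dataclass
class WpliResult:
    """wPLI value with a degeneracy flag for the pure zero-lag case."""

    value: float
    zero_lag_degenerate: bool = False

    def __float__(self) -> float:
        return self.value


def wpli_pair(analytic1: np.ndarray, analytic2: np.ndarray,
              times: np.ndarray | None = None,
              window: tuple[float, float] | None = None) -> WpliResult:
    """Weighted phase-lag index between two analytic signals.

    wPLI = |sum_t Im X(t)| / sum_t |Im X(t)| with X = s1 conj(s2).  A pure
    zero-lag relation makes every imaginary part vanish; the estimator then
    returns 0 with ``zero_lag_degenerate`` set.
    """
    a1 = np.asarray(analytic1, dtype=complex)
    a2 = np.asarray(analytic2, dtype=complex)
    if not (np.isfinite(a1).all() and np.isfinite(a2).all()):
        raise ValueError("non-finite analytic signals")
    if window is not None:
        mask = window_mask(np.asarray(times), window)
        a1, a2 = a1[..., mask], a2[..., mask]
    if a1.shape[-1] < 2:
        raise ValueError("need at least 2 samples")
    im = np.imag(a1 * np.conj(a2))
    denom = np.abs(im).sum()
    if denom <= 1e-15 * np.abs(a1 * np.conj(a2)).sum():
        return WpliResult(0.0, zero_lag_degenerate=True)
    return WpliResult(float(np.abs(im.sum()) / denom))


def wpli_multivariate(analytic_a: np.ndarray, analytic_b: np.ndarray,
                      times: np.ndarray | None = None,
                      window: tuple[float, float] | None = None) -> float:
    """RMS aggregation of pairwise wPLIs between two regions (mirrors the
    multivariate PLV rule)."""
    aa = np.atleast_2d(np.asarray(analytic_a, dtype=complex))
    ab = np.atleast_2d(np.asarray(analytic_b, dtype=complex))
    if window is not None:
        mask = window_mask(np.asarray(times), window)
        aa, ab = aa[:, mask], ab[:, mask]
    im = np.imag(aa[:, None, :] * ab.conj()[None, :, :])  # [M x N x T]
    denom = np.abs(im).sum(axis=-1)
    num = np.abs(im.sum(axis=-1))
    scale = np.abs(aa[:, None, :] * ab.conj()[None, :, :]).sum(axis=-1)
    vals = np.where(denom <= 1e-15 * scale, 0.0, num / np.maximum(denom, 1e-300))
    return float(np.sqrt(np.mean(vals**2)))


# ---------------------------------------------------------------------------
# trial-level connectivity table
# ---------------------------------------------------------------------------

#: (pair tag, seed ROI, {left target, right target}, laterality reference)
DEFAULT_PAIRS = [
    ("mPFC-Hand", "mPFC", ("Hand_L", "Hand_R"), "response_side"),
    ("mPFC-LatOcc", "mPFC", ("LatOcc_L", "LatOcc_R"), "cued_side"),
    ("mPFC-Control", "mPFC", ("Parahip_L", "Parahip_R"), "cued_side"),
]


def build_connectivity_table(
    epochs: EpochSet,
    trials: pd.DataFrame,
    rois: list[ROIDefinition],
    config: AnalysisConfig | None = None,
    pairs=DEFAULT_PAIRS,
) -> pd.DataFrame:
    """Per-trial theta PLV and wPLI rows for one subject.

    Only correct regular (non-catch) trials contribute.  For each
    seed-target pair the left/right targets are mapped to contralateral /
    ipsilateral per trial from the pair's laterality reference column
    (response side for Hand, cued side for LatOcc; the control pair keeps
    the cued-side convention but its model uses Task only).
    """
    config = config or AnalysisConfig()
    band = DEFAULT_BANDS["theta"]
    roi_by_name = {r.name: r for r in rois}
    for _, seed, targets, _ in pairs:
        for name in (seed, *targets):
            roi = roi_by_name.get(name)
            if roi is None or not roi.source_indices:
                raise ConfigError(f"ROI {name} missing or empty")

    keep = (~trials["catch"]) & trials["correct"]
    keep_idx = np.flatnonzero(keep.to_numpy())
    if keep_idx.size == 0:
        return pd.DataFrame(columns=CONNECTIVITY_COLUMNS)

    filtered = bandpass_filter(
        epochs.data[keep_idx], band.f_lo, band.f_hi, epochs.srate,
        transition_lo=2.0, transition_hi=2.0,
    )
    analytic = analytic_signal(filtered)
    mask = window_mask(epochs.times, config.plv_window)
    logger.debug("connectivity window [%g, %g]: %d samples at %g Hz",
                 *config.plv_window, int(mask.sum()), epochs.srate)
    analytic = analytic[..., mask]
    phases = np.angle(analytic)

    kept = trials.iloc[keep_idx]
    rows = []
    for pair_tag, seed, (tgt_l, tgt_r), ref_col in pairs:
        seed_idx = roi_by_name[seed].source_indices
        tgt_idx = {"left": roi_by_name[tgt_l].source_indices,
                   "right": roi_by_name[tgt_r].source_indices}
        for k, (_, tr) in enumerate(kept.iterrows()):
            ref = tr[ref_col]
            for hemi in ("left", "right"):
                lat = "contralateral" if hemi != ref else "ipsilateral"
                plv = plv_multivariate(phases[k][seed_idx],
                                       phases[k][tgt_idx[hemi]])
                wpli = wpli_multivariate(analytic[k][seed_idx],
                                         analytic[k][tgt_idx[hemi]])
                rows.append(dict(
                    subject_id=epochs.subject_id,
                    trial_id=int(tr["trial_id"]),
                    task=tr["task"],
                    roi_pair=pair_tag,
                    laterality=lat,
                    plv=plv,
                    wpli=wpli,
                ))
    table = pd.DataFrame(rows, columns=CONNECTIVITY_COLUMNS)
    assert ((table["plv"] >= 0) & (table["plv"] <= 1)).all()
    assert ((table["wpli"] >= 0) & (table["wpli"] <= 1)).all()
    return table
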