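"""Data containers, on-disk formats, validation, and trial/subject filtering rules.

On-disk layout for one subject
------------------------------
``epochs.h5``   HDF5 file with a single dataset ``data`` shaped
                [trials x sources x time].
``meta.json``   sidecar: subject_id, srate, tmin, tmax, source_labels.
                Axis order and the time axis are always taken from the
                sidecar, never inferred from the array.
``trials.tsv``  BIDS-events-like tab-separated table, one row per trial,
                header exactly: trial_id, task, cued_side, response_side,
                correct, catch, rt_ms, block.  Missing RT is written "n/a".
``rois.json``   list of {name, source_indices, orientation_signs, hemisphere}.

Conventions used throughout the package: time is in seconds relative to
retro-cue onset (sample 0 at ``tmin``); SD always uses the n-1 denominator;
all time windows are closed intervals with inclusive endpoints.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ConfigError",
    "DataFormatError",
    "IntegrityError",
    "EpochSet",
    "ROIDefinition",
    "BandSpec",
    "AnalysisConfig",
    "DEFAULT_BANDS",
    "TRIAL_COLUMNS",
    "TASKS",
    "SIDES",
    "validate_trials",
    "read_epochs",
    "write_epochs",
    "read_trials",
    "write_trials",
    "read_rois",
    "write_rois",
    "trim_by_sd",
    "subject_exclusion",
]


class ConfigError(ValueError):
    """Invalid configuration (CLI exit code 2)."""


class DataFormatError(ValueError):
    """A file does not follow the documented on-disk format (CLI exit code 3)."""


class IntegrityError(ValueError):
    """Sidecar metadata and array contents disagree (CLI exit code 3)."""


TASKS = ("implementation", "memorization")
SIDES = ("left", "right")

TRIAL_COLUMNS = [
    "trial_id",
    "task",
    "cued_side",
    "response_side",
    "correct",
    "catch",
    "rt_ms",
    "block",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class EpochSet:
    """One subject's epoched source-level data: [trials x sources x time].

    ``tmin`` is the time of the first sample in seconds relative to the
    retro-cue (negative = pre-cue).  The time axis is
    ``tmin + k / srate`` for sample k.
    """

    subject_id: str
    data: np.ndarray
    srate: float
    tmin: float
    source_labels: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_sources(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    @property
    def tmax(self) -> float:
        return self.tmin + (self.n_times - 1) / self.srate

    @property
    def times(self) -> np.ndarray:
        return self.tmin + np.arange(self.n_times) / self.srate

    def validate(self) -> "EpochSet":
        if self.data.ndim != 3:
            raise IntegrityError(
                f"epoch data must be 3-D [trials x sources x time], got {self.data.ndim}-D"
            )
        if len(self.source_labels) != self.n_sources:
            raise IntegrityError(
                f"{len(self.source_labels)} source labels for {self.n_sources} sources"
            )
        if not np.isfinite(self.data).all():
            raise IntegrityError("epoch data contains non-finite values")
        if self.srate <= 0:
            raise IntegrityError("srate must be positive")
        if not (self.tmin <= 0.0 < self.tmax):
            raise IntegrityError(
                f"epoch window [{self.tmin}, {self.tmax}] must bracket cue onset (tmin <= 0 < tmax)"
            )
        return self


@dataclass
class ROIDefinition:
    """Named set of source indices with per-source orientation signs."""

    name: str
    source_indices: list[int]
    orientation_signs: list[int]
    hemisphere: str  # left | right | bilateral

    def validate(self, n_sources: int | None = None) -> "ROIDefinition":
        idx = list(self.source_indices)
        if len(set(idx)) != len(idx):
            raise DataFormatError(f"ROI {self.name}: duplicate source indices")
        if len(self.orientation_signs) != len(idx):
            raise DataFormatError(f"ROI {self.name}: one orientation sign per source required")
        if any(s not in (-1, 1) for s in self.orientation_signs):
            raise DataFormatError(f"ROI {self.name}: orientation signs must be +1/-1")
        if self.hemisphere not in ("left", "right", "bilateral"):
            raise DataFormatError(f"ROI {self.name}: bad hemisphere {self.hemisphere!r}")
        if n_sources is not None and any(i < 0 or i >= n_sources for i in idx):
            raise DataFormatError(f"ROI {self.name}: source index out of range")
        return self


@dataclass
class BandSpec:
    """A frequency band with its Morlet cycle count."""

    name: str
    f_lo: float
    f_hi: float
    n_cycles: float

    def validate(self) -> "BandSpec":
        if not (0 < self.f_lo < self.f_hi):
            raise ConfigError(f"band {self.name}: need 0 < f_lo < f_hi")
        if self.n_cycles < 1:
            raise ConfigError(f"band {self.name}: n_cycles >= 1")
        return self


#: theta 3-7 Hz / 3 cycles, alpha 8-14 Hz / 4 cycles, beta 15-30 Hz / 5 cycles
DEFAULT_BANDS = {
    "theta": BandSpec("theta", 3.0, 7.0, 3),
    "alpha": BandSpec("alpha", 8.0, 14.0, 4),
    "beta": BandSpec("beta", 15.0, 30.0, 5),
}


@dataclass
class AnalysisConfig:
    """Knobs of the group analysis.

    analysis_window : cluster statistics run on 0-1800 ms from cue onset.
    plv_window      : per-trial theta scalar / PLV window, 355-985 ms.
    trim_k          : outlier trimming cut at 3 SD.
    subject_excl_k  : subjects beyond 2.5 SD below group-mean accuracy drop.
    catch_acc_floor : subjects below 60% catch accuracy in either task drop.
    power_srate     : band power grid after decimation, 128 samples/s.
    """

    analysis_window: tuple[float, float] = (0.0, 1.8)
    plv_window: tuple[float, float] = (0.355, 0.985)
    n_permutations: int = 10_000
    alpha_level: float = 0.05
    trim_k: float = 3.0
    subject_excl_k: float = 2.5
    catch_acc_floor: float = 0.60
    power_srate: float = 128.0
    mediation_B: int = 1000
    rng_seed: int = 0

    def validate(self) -> "AnalysisConfig":
        if not (0.0 < self.alpha_level < 1.0):
            raise ConfigError("alpha_level must be in (0, 1)")
        for name in ("analysis_window", "plv_window"):
            t0, t1 = getattr(self, name)
            if not t0 < t1:
                raise ConfigError(f"{name} must satisfy t0 < t1")
        if self.n_permutations < 1 or self.mediation_B < 1:
            raise ConfigError("n_permutations and mediation_B must be positive")
        if self.trim_k <= 0 or self.subject_excl_k <= 0:
            raise ConfigError("trim_k and subject_excl_k must be positive")
        return self

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        kwargs = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        for name in ("analysis_window", "plv_window"):
            if name in kwargs:
                kwargs[name] = tuple(kwargs[name])
        return cls(**kwargs).validate()

    def to_dict(self) -> dict:
        d = asdict(self)
        d["analysis_window"] = list(self.analysis_window)
        d["plv_window"] = list(self.plv_window)
        return d


# ---------------------------------------------------------------------------
# trial table
# ---------------------------------------------------------------------------


def validate_trials(trials: pd.DataFrame, n_trials: int | None = None) -> pd.DataFrame:
    """Validate a trial table against the canonical schema.

    Extra columns (e.g. simulation ground truth) are allowed and preserved;
    the canonical eight must be present and well-formed.  If ``n_trials`` is
    given the row count must match the paired EpochSet.
    """
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise DataFormatError(f"trial table missing columns: {missing}")
    if n_trials is not None and len(trials) != n_trials:
        raise IntegrityError(
            f"trial table has {len(trials)} rows for {n_trials} epochs"
        )
    bad_task = set(trials["task"]) - set(TASKS)
    if bad_task:
        raise DataFormatError(f"unknown task labels: {sorted(bad_task)}")
    for col in ("cued_side", "response_side"):
        bad = set(trials[col]) - set(SIDES)
        if bad:
            raise DataFormatError(f"unknown {col} labels: {sorted(bad)}")
    rt = trials["rt_ms"].to_numpy(dtype=float)
    if np.any(rt[np.isfinite(rt)] < 0):
        raise DataFormatError("negative rt_ms")
    return trials


def congruent_mask(trials: pd.DataFrame) -> pd.Series:
    """Congruency is derived: cued side equals response side."""
    return trials["cued_side"] == trials["response_side"]


# ---------------------------------------------------------------------------
# on-disk I/O
# ---------------------------------------------------------------------------


def write_epochs(path: str | Path, epochs: EpochSet) -> Path:
    """Write ``epochs.h5`` + ``meta.json`` into directory ``path``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    epochs.validate()
    with h5py.File(path / "epochs.h5", "w") as f:
        f.create_dataset("data", data=epochs.data)
    meta = {
        "subject_id": epochs.subject_id,
        "srate": epochs.srate,
        "tmin": epochs.tmin,
        "tmax": epochs.tmax,
        "source_labels": list(epochs.source_labels),
        "axes": ["trials", "sources", "time"],
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1))
    return path


def read_epochs(path: str | Path) -> EpochSet:
    """Read an EpochSet from a subject directory written by :func:`write_epochs`."""
    path = Path(path)
    sidecar = path / "meta.json"
    if not sidecar.exists():
        raise DataFormatError(f"missing sidecar {sidecar}")
    try:
        meta = json.loads(sidecar.read_text())
    except json.JSONDecodeError as e:
        raise DataFormatError(f"unparseable sidecar {sidecar}: {e}") from e
    h5 = path / "epochs.h5"
    if not h5.exists():
        raise DataFormatError(f"missing array container {h5}")
    with h5py.File(h5, "r") as f:
        if "data" not in f:
            raise DataFormatError(f"{h5} has no 'data' dataset")
        data = f["data"][()]
    es = EpochSet(
        subject_id=str(meta["subject_id"]),
        data=data,
        srate=float(meta["srate"]),
        tmin=float(meta["tmin"]),
        source_labels=list(meta["source_labels"]),
    )
    es.validate()
    # sidecar carries the declared epoch end; the array must agree within 1 sample
    n_expected = round((float(meta["tmax"]) - es.tmin) * es.srate) + 1
    if abs(n_expected - es.n_times) > 1:
        raise IntegrityError(
            f"sidecar declares {n_expected} samples, array has {es.n_times}"
        )
    if "n_trials" in meta and int(meta["n_trials"]) != es.n_trials:
        raise IntegrityError(
            f"sidecar declares {meta['n_trials']} trials, array has {es.n_trials}"
        )
    return es


def write_trials(path: str | Path, trials: pd.DataFrame) -> Path:
    """Write ``trials.tsv`` (canonical eight columns only, 'n/a' for missing RT)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    validate_trials(trials)
    out = trials[TRIAL_COLUMNS].copy()
    out["correct"] = out["correct"].astype(bool)
    out["catch"] = out["catch"].astype(bool)
    out.to_csv(path / "trials.tsv", sep="\t", index=False, na_rep="n/a",
               float_format="%.6g")
    return path


def read_trials(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    f = path / "trials.tsv"
    if not f.exists():
        raise DataFormatError(f"missing {f}")
    trials = pd.read_csv(f, sep="\t", na_values=["n/a"])
    header = list(trials.columns)
    if header != TRIAL_COLUMNS:
        raise DataFormatError(
            f"trials.tsv header {header} != expected {TRIAL_COLUMNS}"
        )
    trials["correct"] = trials["correct"].astype(bool)
    trials["catch"] = trials["catch"].astype(bool)
    return validate_trials(trials)


def write_rois(path: str | Path, rois: list[ROIDefinition]) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    payload = [
        {
            "name": r.name,
            "source_indices": list(map(int, r.source_indices)),
            "orientation_signs": list(map(int, r.orientation_signs)),
            "hemisphere": r.hemisphere,
        }
        for r in rois
    ]
    (path / "rois.json").write_text(json.dumps(payload, indent=1))
    return path


def read_rois(path: str | Path, n_sources: int | None = None) -> list[ROIDefinition]:
    path = Path(path)
    f = path / "rois.json"
    if not f.exists():
        raise DataFormatError(f"missing {f}")
    payload = json.loads(f.read_text())
    return [
        ROIDefinition(
            name=d["name"],
            source_indices=list(d["source_indices"]),
            orientation_signs=list(d["orientation_signs"]),
            hemisphere=d["hemisphere"],
        ).validate(n_sources)
        for d in payload
    ]


# ---------------------------------------------------------------------------
# filtering rules
# ---------------------------------------------------------------------------


def trim_by_sd(values, k: float) -> np.ndarray:
    """Single-pass outlier mask: keep x with |x - mean| <= k * SD (SD with n-1).

    The mean and SD are computed once on the full input; the rule is never
    iterated on the survivors.  Returns a boolean keep-mask.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("trim_by_sd needs a 1-D array of at least 3 values")
    if not np.isfinite(x).all():
        raise ValueError("trim_by_sd requires finite values")
    if not k > 0:
        raise ValueError("k must be positive")
    sd = x.std(ddof=1)
    if sd == 0.0:
        warnings.warn("trim_by_sd: zero SD (all values identical); keeping all",
                      RuntimeWarning, stacklevel=2)
        return np.ones(x.size, dtype=bool)
    return np.abs(x - x.mean()) <= k * sd


def subject_exclusion(
    accuracy: float,
    group_accuracies,
    catch_accuracy: dict[str, float],
    k: float = 2.5,
    catch_floor: float = 0.60,
) -> tuple[bool, list[str]]:
    """Keep/drop decision for one subject with machine-readable reasons.

    Drops if overall accuracy is more than ``k`` SD *below* the group mean
    (the low-performance reading of the deviation rule; see docs), or if
    catch-trial accuracy falls below ``catch_floor`` in either task.

    Returns ``(keep, reasons)`` where reasons is a subset of
    ``{"low_accuracy", "catch_floor"}``.
    """
    acc = np.asarray(group_accuracies, dtype=float)
    if acc.size < 3:
        raise ValueError("need at least 3 subjects to form the group rule")
    vals = np.concatenate([[accuracy], acc.ravel(), list(catch_accuracy.values())])
    if np.any((vals < 0) | (vals > 1)):
        raise ValueError("accuracies must lie in [0, 1]")
    reasons: list[str] = []
    cutoff = acc.mean() - k * acc.std(ddof=1)
    if accuracy < cutoff:
        reasons.append("low_accuracy")
    if any(v < catch_floor for v in catch_accuracy.values()):
        reasons.append("catch_floor")
    if reasons:
        logger.info(
            "subject excluded (%s); accuracy=%.3f cutoff=%.3f (mean - %.1f SD, "
            "low-performance reading of the deviation rule)",
            ",".join(reasons), accuracy, cutoff, k,
        )
    return (not reasons, reasons)
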