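"""Per-subject estimated time from onset (ETO) and its evaluation.

Each biomarker measurement is aligned to that biomarker's probabilistic
trajectory: the time at which the average trajectory passes through the
measured value is a biomarker-specific estimate of the subject's years
from onset, and the interquartile spread of sample-trajectory times at
that value is its credible-interval width. A single ETO per subject is
the average of the per-biomarker times weighted by the inverse interval
width, with missing biomarkers (and measurements outside every sampled
trajectory's range) omitted.

Evaluation mirrors the out-of-sample design used for converters —
carriers whose global CDR becomes non-zero after baseline, held out of
all model fits: estimated years-from-onset at baseline are compared to
actual years-from-onset by RMSE and the adjusted coefficient of
determination, head-to-head against familial surrogates (parental and
mutation-type estimated years to onset).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["OnsetEstimate", "OnsetEvaluation",
           "estimate_time_from_onset", "evaluate_onset_predictions"]

log = logging.getLogger(__name__)


@dataclass
class OnsetEstimate:
    """Weighted estimated time from onset for one subject (years;
    negative = before onset)."""

    subject_id: str
    eto: float
    per_biomarker: pd.DataFrame   # biomarker, t, width, weight, used
    n_biomarkers_used: int


@dataclass
class OnsetEvaluation:
    """Estimated-vs-actual onset comparison across prediction methods."""

    pairs: pd.DataFrame           # subject_id, actual, model_eto, parental_eyo, mutation_eyo
    rmse: dict = field(default_factory=dict)
    adjusted_r2: dict = field(default_factory=dict)
    signed_errors: dict = field(default_factory=dict)


def estimate_time_from_onset(measurements: dict, trajectories: dict,
                             subject_id: str = "",
                             alignment: str = "mean",
                             min_coverage: float = 0.5) -> OnsetEstimate:
    """Align one subject's measurements to the trajectory posteriors.

    ``measurements`` maps biomarker -> value (NaN allowed = missing);
    ``trajectories`` maps biomarker -> TrajectoryPosterior. With
    ``alignment="mean"`` the biomarker time is read off the average
    trajectory; ``alignment="samples"`` instead averages the per-sample
    times. Either way the weight is the inverse interquartile spread of
    sample times at the measured value.

    A measurement inside the value range of fewer than ``min_coverage``
    of the trajectory samples is treated as out of range and dropped:
    the interquartile spread over a handful of covering samples would
    wildly understate the uncertainty of the alignment.

    The trajectory model constrains only the monotone transition between
    the canonical normal and abnormal levels; outside that band the
    time-course is extrapolation. Measurements beyond either level are
    therefore censored at the level they exceed (aligned to the
    boundary time, i.e. t(canonical normal) or 0) rather than mapped
    deep into the flat tails, where a noise-sized value difference
    translates into decades of spurious time.
    """
    rows = []
    for b, value in measurements.items():
        traj = trajectories.get(b)
        if traj is None or not np.isfinite(value):
            continue
        a = traj.anchors
        lo = min(a.canonical_normal, a.canonical_abnormal)
        hi = max(a.canonical_normal, a.canonical_abnormal)
        value = min(max(float(value), lo), hi)
        ts = traj.times_at_value(float(value))
        n_total = len(ts)
        ts = ts[np.isfinite(ts)]
        if len(ts) < max(1, min_coverage * n_total):
            rows.append((b, np.nan, np.nan, 0.0, False))
            log.info("%s: %s measurement outside the supported trajectory "
                     "range; dropped", subject_id, b)
            continue
        if alignment == "mean":
            t_b = traj.mean_time_at_value(float(value))
            if not np.isfinite(t_b):
                t_b = float(np.mean(ts))
        elif alignment == "samples":
            t_b = float(np.mean(ts))
        else:
            raise ValueError(f"unknown alignment {alignment!r}")
        q25, q75 = np.percentile(ts, [25, 75])
        width = float(q75 - q25)
        rows.append((b, t_b, width, np.nan, True))
    per = pd.DataFrame(rows, columns=["biomarker", "t", "width", "weight", "used"])
    usable = per[per["used"]]
    if len(usable) == 0:
        raise ValueError(f"{subject_id}: no usable biomarker for onset estimation")
    widths = usable["width"].to_numpy(float)
    if np.all(widths <= 0):
        log.warning("%s: degenerate (zero) interval widths; equal weights", subject_id)
        weights = np.ones(len(usable))
    else:
        weights = 1.0 / np.maximum(widths, 1e-12)
    per.loc[per["used"], "weight"] = weights
    eto = float(np.sum(weights * usable["t"].to_numpy(float)) / np.sum(weights))
    return OnsetEstimate(subject_id=subject_id, eto=eto, per_biomarker=per,
                         n_biomarkers_used=int(len(usable)))


def find_converters(cohort: pd.DataFrame) -> list:
    """Carriers with global CDR 0 at baseline that becomes non-zero at a
    later visit. These subjects must be held out of all model fits."""
    carriers = cohort[cohort["carrier"].astype(bool)]
    bl = carriers[carriers["visit_index"] == 0].set_index("subject_id")
    later = carriers[carriers["visit_index"] > 0]
    ever = later.groupby("subject_id")["cdr_global"].max()
    common = bl.index.intersection(ever.index)
    return sorted(sid for sid in common
                  if bl.loc[sid, "cdr_global"] == 0 and ever.loc[sid] > 0)


def _adjusted_r2(actual: np.ndarray, estimated: np.ndarray) -> float:
    """Adjusted R^2 of the linear fit of estimated on actual."""
    n = len(actual)
    if n < 3:
        return float("nan")
    X = sm.add_constant(np.asarray(actual, float))
    fit = sm.OLS(np.asarray(estimated, float), X).fit()
    return float(fit.rsquared_adj)


def evaluate_onset_predictions(estimates: dict, cohort: pd.DataFrame,
                               converters: list | None = None) -> OnsetEvaluation:
    """Compare model ETO and the familial surrogates against actual
    years-from-onset at baseline for converters.

    ``estimates`` maps subject_id -> OnsetEstimate (or float). Actual
    years from onset is baseline age minus the observed onset age; the
    familial surrogates are read from the cohort's ``parental_eyo`` and
    ``mutation_eyo`` baseline columns.
    """
    if converters is None:
        converters = find_converters(cohort)
    bl = cohort[cohort["visit_index"] == 0].set_index("subject_id")
    rows = []
    for sid in converters:
        if sid not in bl.index or sid not in estimates:
            continue
        r = bl.loc[sid]
        if not np.isfinite(r["actual_onset_age"]):
            continue
        actual = float(r["age"] - r["actual_onset_age"])
        est = estimates[sid]
        eto = est.eto if isinstance(est, OnsetEstimate) else float(est)
        rows.append((sid, actual, eto, float(r["parental_eyo"]),
                     float(r["mutation_eyo"])))
    pairs = pd.DataFrame(rows, columns=["subject_id", "actual", "model_eto",
                                        "parental_eyo", "mutation_eyo"])
    if len(pairs) == 0:
        raise ValueError("no converters with observed onset to evaluate")
    if len(pairs) < 2:
        log.warning("fewer than 2 converters: R^2 undefined")
    rmse, r2, signed = {}, {}, {}
    actual = pairs["actual"].to_numpy(float)
    for method in ["model_eto", "parental_eyo", "mutation_eyo"]:
        est = pairs[method].to_numpy(float)
        err = est - actual
        rmse[method] = float(np.sqrt(np.mean(err ** 2)))
        r2[method] = _adjusted_r2(actual, est) if len(pairs) >= 2 else float("nan")
        signed[method] = err
    return OnsetEvaluation(pairs=pairs, rmse=rmse, adjusted_r2=r2,
                           signed_errors=signed)
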