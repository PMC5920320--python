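"""Data preparation: covariate adjustment, disease-signal biomarker
selection, per-subject rate-of-change estimation, and the exclusion rules
that clean differential data before trajectory fitting.

Covariate adjustment regresses each biomarker on age, sex, education and
head size (total intracranial volume, MRI volumes only) with backward
elimination, fitted on non-carriers so disease signal is not removed, and
subtracts the fitted prediction from every subject's values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from sklearn.mixture import GaussianMixture

__all__ = [
    "AdjustedPanel",
    "DifferentialDataset",
    "adjust_covariates",
    "select_biomarkers",
    "compute_rates",
    "apply_dem_exclusions",
]

log = logging.getLogger(__name__)

#: Exclusion reason codes used in the differential-data log.
CV_TOO_LARGE = "cv_too_large"
NORMAL_NONPROGRESSING = "normal_nonprogressing"
TOO_FEW_VISITS = "too_few_visits"


@dataclass
class AdjustedPanel:
    """A cohort table with covariate-residualized biomarker values.

    ``raw`` keeps the pre-adjustment values (used e.g. for the
    coefficient-of-variation exclusion, which is meaningless on residual
    scale); ``retained_covariates`` records which covariates survived
    backward elimination per biomarker.
    """

    table: pd.DataFrame
    biomarkers: list
    retained_covariates: dict = field(default_factory=dict)
    raw: pd.DataFrame | None = None
    directions: dict | None = None

    @classmethod
    def from_table(cls, table: pd.DataFrame, biomarkers: list,
                   directions: dict | None = None) -> "AdjustedPanel":
        """Wrap an unadjusted table (identity adjustment)."""
        return cls(table=table.copy(), biomarkers=list(biomarkers),
                   retained_covariates={b: [] for b in biomarkers},
                   raw=table.copy(), directions=directions)

    def baseline(self) -> pd.DataFrame:
        return self.table[self.table["visit_index"] == 0]


@dataclass
class DifferentialDataset:
    """Per-biomarker differential data: one (x, dx/dt) point per subject.

    ``points`` maps biomarker -> DataFrame(subject_id, x, dxdt, n_visits);
    x is the mean of the fitted within-subject line over that subject's
    visits and dxdt its least-squares slope per year. ``exclusions`` is a
    log DataFrame(biomarker, subject_id, reason).
    """

    points: dict
    exclusions: pd.DataFrame

    def n_included(self, biomarker: str) -> int:
        return len(self.points.get(biomarker, ()))


def adjust_covariates(table: pd.DataFrame, covariates: list,
                      biomarkers: list, p_threshold: float = 0.05,
                      mri_volume_markers: list | None = None,
                      directions: dict | None = None) -> AdjustedPanel:
    """Residualize biomarkers against nuisance covariates.

    For each biomarker a linear model is fitted on non-carrier baseline
    rows (one independent observation per subject: repeat visits share
    subject-level variability and would inflate significance) with
    backward elimination: the covariate with the largest p-value is
    dropped until every remaining one has p < ``p_threshold``. The fitted
    prediction (including intercept) is then subtracted from all
    subjects' values, so non-carrier residuals are centred at zero. TIV
    is offered as a covariate only to biomarkers listed in
    ``mri_volume_markers`` (default: names containing ``"vol"`` or
    ``"ventricles"`` or ``"whole_brain"``).

    An empty covariate list returns the values unchanged.
    """
    panel = table.copy()
    retained = {}
    if not covariates:
        return AdjustedPanel(table=panel, biomarkers=list(biomarkers),
                             retained_covariates={b: [] for b in biomarkers},
                             raw=table.copy(), directions=directions)

    if mri_volume_markers is None:
        mri_volume_markers = [b for b in biomarkers
                              if ("vol" in b) or ("ventricles" in b) or ("whole_brain" in b)]

    controls = table[~table["carrier"].astype(bool)
                     & (table["visit_index"] == 0)]
    for b in biomarkers:
        if b not in table.columns:
            raise KeyError(f"biomarker column {b!r} not in table")
        if table[b].isna().all():
            raise ValueError(f"biomarker {b!r} has no observed values")
        cands = [c for c in covariates if c != "tiv" or b in mri_volume_markers]
        # Constant covariates carry no information; drop with a warning.
        usable = []
        for c in cands:
            if np.nanstd(controls[c].to_numpy(float)) == 0:
                warnings.warn(f"covariate {c!r} is constant among non-carriers; dropped")
            else:
                usable.append(c)
        kept = list(usable)
        fit = None
        mask = controls[b].notna()
        while kept:
            X = sm.add_constant(controls.loc[mask, kept].astype(float))
            fit = sm.OLS(controls.loc[mask, b].astype(float), X).fit()
            pvals = fit.pvalues.drop("const", errors="ignore")
            worst = pvals.idxmax()
            if pvals.loc[worst] >= p_threshold:
                kept.remove(worst)
                fit = None
            else:
                break
        if kept and fit is not None:
            Xall = sm.add_constant(panel[kept].astype(float), has_constant="add")
            pred = fit.predict(Xall[["const"] + kept])
        else:
            # Intercept-only model: centre on the non-carrier mean.
            pred = pd.Series(float(controls.loc[mask, b].mean()), index=panel.index)
        panel[b] = panel[b] - pred
        retained[b] = kept

    return AdjustedPanel(table=panel, biomarkers=list(biomarkers),
                         retained_covariates=retained, raw=table.copy(),
                         directions=directions)


def select_biomarkers(panel: AdjustedPanel, alpha_family: float = 0.01,
                      symptomatic_cdr_min: float = 0.5) -> list:
    """Keep biomarkers with disease signal: a Welch two-sample t-test
    between baseline non-carriers and baseline symptomatic carriers
    (global CDR > ``symptomatic_cdr_min``), retained iff
    p < alpha_family / n_biomarkers (Bonferroni across the panel).
    """
    bl = panel.baseline()
    controls = bl[~bl["carrier"].astype(bool)]
    sympt = bl[bl["carrier"].astype(bool) & (bl["cdr_global"] > symptomatic_cdr_min)]
    if len(controls) < 3 or len(sympt) < 3:
        raise ValueError(
            f"need >= 3 subjects per group (non-carriers: {len(controls)}, "
            f"symptomatic carriers: {len(sympt)})")
    threshold = alpha_family / len(panel.biomarkers)
    kept = []
    for b in panel.biomarkers:
        a = controls[b].dropna().to_numpy(float)
        c = sympt[b].dropna().to_numpy(float)
        if len(a) < 3 or len(c) < 3:
            continue
        p = stats.ttest_ind(a, c, equal_var=False).pvalue
        if p < threshold:
            kept.append(b)
    return kept


def compute_rates(panel: AdjustedPanel, biomarkers: list | None = None,
                  subjects: list | None = None) -> DifferentialDataset:
    """Ordinary-least-squares rate of change per carrier per biomarker.

    For each carrier with >= 2 non-missing visits of a biomarker, fit
    value ~ years-from-baseline; emit the slope (per year) and the mean of
    the fitted line over the observed visits as the representative value x.
    Carriers with fewer visits are logged with reason ``too_few_visits``.
    """
    biomarkers = list(biomarkers if biomarkers is not None else panel.biomarkers)
    tab = panel.table[panel.table["carrier"].astype(bool)]
    if subjects is not None:
        tab = tab[tab["subject_id"].isin(subjects)]
    points = {}
    excl = []
    for b in biomarkers:
        recs = []
        for sid, grp in tab.groupby("subject_id", sort=True):
            g = grp.dropna(subset=[b])
            if len(g) < 2:
                excl.append((b, sid, TOO_FEW_VISITS))
                continue
            t = g["years_from_baseline"].to_numpy(float)
            y = g[b].to_numpy(float)
            slope, intercept = np.polyfit(t, y, 1)
            fitted = intercept + slope * t
            recs.append((sid, float(fitted.mean()), float(slope), len(g)))
        points[b] = pd.DataFrame(recs, columns=["subject_id", "x", "dxdt", "n_visits"])
    exclusions = pd.DataFrame(excl, columns=["biomarker", "subject_id", "reason"])
    return DifferentialDataset(points=points, exclusions=exclusions)


def _gaussian_boundary(values: np.ndarray) -> float:
    """Normal/abnormal boundary from a deterministic 1-D two-component
    Gaussian mixture: the point between the component means where the
    posterior responsibilities cross. Falls back to the midpoint of the
    halves' medians on degenerate data."""
    v = np.sort(values[np.isfinite(values)])
    lo_med = float(np.median(v[: max(1, len(v) // 2)]))
    hi_med = float(np.median(v[len(v) // 2:]))
    fallback = 0.5 * (lo_med + hi_med)
    if len(v) < 6 or np.ptp(v) == 0:
        log.warning("degenerate data for clustering; using median midpoint")
        return fallback
    q25, q75 = np.percentile(v, [25, 75])
    try:
        gm = GaussianMixture(n_components=2, n_init=1, random_state=0,
                             means_init=[[q25], [q75]], reg_covar=1e-6,
                             max_iter=500)
        gm.fit(v.reshape(-1, 1))
    except Exception:
        log.warning("Gaussian mixture failed; using median midpoint")
        return fallback
    mus = gm.means_.ravel()
    lo, hi = float(mus.min()), float(mus.max())
    if not np.isfinite([lo, hi]).all() or np.isclose(lo, hi):
        log.warning("mixture components collapsed; using median midpoint")
        return fallback
    grid = np.linspace(lo, hi, 2001)
    resp = gm.predict_proba(grid.reshape(-1, 1))
    which_lo = int(np.argmin(gm.means_.ravel()))
    diff = resp[:, which_lo] - 0.5
    sgn = np.sign(diff)
    idx = np.nonzero(np.diff(sgn))[0]
    if len(idx) == 0:
        return fallback
    return float(grid[idx[0]])


def apply_dem_exclusions(dd: DifferentialDataset, panel: AdjustedPanel,
                         cv_threshold: float = 0.5,
                         directions: dict | None = None) -> DifferentialDataset:
    """Remove noisy and contradictory differential points.

    1. ``cv_too_large``: the within-subject coefficient of variation of
       the raw (pre-adjustment) values, sd/|mean| across that subject's
       visits, exceeds ``cv_threshold``.
    2. ``normal_nonprogressing``: the point lies on the normal side of a
       boundary found by two-component Gaussian clustering of carrier
       baseline values AND its slope has the sign contrary to the
       biomarker's progression direction. Abnormal-side points are kept
       regardless of slope sign.
    """
    if directions is None:
        directions = panel.directions or {}
    raw = panel.raw if panel.raw is not None else panel.table
    raw = raw[raw["carrier"].astype(bool)]
    bl = panel.baseline()
    carriers_bl = bl[bl["carrier"].astype(bool)]

    new_points = {}
    excl = [tuple(r) for r in dd.exclusions.itertuples(index=False)]
    for b, pts in dd.points.items():
        direction = directions.get(b)
        if direction is None:
            sym = carriers_bl[carriers_bl["cdr_global"] > 0][b].dropna()
            asym = carriers_bl[carriers_bl["cdr_global"] == 0][b].dropna()
            direction = int(np.sign(sym.median() - asym.median())) or 1
        vals = carriers_bl[b].dropna().to_numpy(float)
        boundary = _gaussian_boundary(vals) if len(vals) else 0.0

        keep = []
        for rec in pts.itertuples(index=False):
            rv = raw.loc[raw["subject_id"] == rec.subject_id, b].dropna().to_numpy(float)
            if np.isfinite(cv_threshold) and len(rv) >= 2:
                m = np.mean(rv)
                cv = np.inf if m == 0 else float(np.std(rv, ddof=1) / abs(m))
                if cv > cv_threshold:
                    excl.append((b, rec.subject_id, CV_TOO_LARGE))
                    continue
            normal_side = direction * rec.x < direction * boundary
            contrary = direction * rec.dxdt <= 0
            if normal_side and contrary:
                excl.append((b, rec.subject_id, NORMAL_NONPROGRESSING))
                continue
            keep.append(rec)
        new_points[b] = pd.DataFrame(keep, columns=pts.columns)

    exclusions = pd.DataFrame(excl, columns=["biomarker", "subject_id", "reason"])
    return DifferentialDataset(points=new_points, exclusions=exclusions)
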