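"""Synthetic cohorts for familial Alzheimer's-like disease progression.

Generates subject-visit biomarker tables that mimic the structure of an
autosomal-dominant Alzheimer's disease observational study: mutation
carriers and non-carrier family members, a latent ordered sequence of
biomarker abnormality events, sigmoidal long-time trajectories observed
as short longitudinal segments, additive covariate confounding,
per-modality missingness, and observed symptom onset for the small
subset of carriers who convert during follow-up.

Every downstream model in this package is validated against cohorts from
this module, because the ground truth (event sequence, per-subject latent
time from onset, analytic transition times) is known exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "BiomarkerSpec",
    "VisitSchedule",
    "CohortConfig",
    "GroundTruth",
    "generate_cohort",
    "ground_truth",
    "default_biomarker_specs",
    "default_config",
    "uniform_panel",
    "COVARIATE_COLUMNS",
]

#: Covariate columns emitted by the generator (and expected by preprocessing).
COVARIATE_COLUMNS = ["age", "sex", "education", "tiv"]

#: Non-biomarker columns of a cohort table.
METADATA_COLUMNS = [
    "subject_id", "visit_index", "years_from_baseline", "age", "sex",
    "education", "tiv", "carrier", "mutation_type", "apoe4", "cdr_global",
    "parental_eyo", "mutation_eyo", "actual_onset_age",
]

#: Hidden ground-truth columns, emitted only when requested.
TRUTH_COLUMNS = ["latent_time", "true_stage"]


class ConfigurationError(ValueError):
    """Raised when a cohort configuration violates its invariants."""


@dataclass(frozen=True)
class BiomarkerSpec:
    """Generative description of one biomarker.

    The long-time course of the biomarker in carriers is a logistic
    sigmoid in latent disease time t (years from symptom onset):

        mu(t) = normal_mean + (abnormal_mean - normal_mean) * s(t)
        s(t)  = 1 / (1 + exp(-sigmoid_rate * (t - sigmoid_midpoint)))

    Observation noise interpolates between ``normal_sd`` (t -> -inf)
    and ``abnormal_sd`` (t -> +inf) with the same sigmoid weight, so
    far-presymptomatic carriers and non-carriers share one Gaussian.
    """

    name: str
    direction: int                 # +1 pathological increase, -1 decrease
    normal_mean: float
    normal_sd: float
    abnormal_mean: float
    abnormal_sd: float
    sigmoid_rate: float            # 1/years, > 0
    sigmoid_midpoint: float        # years relative to onset
    missing_rate: float = 0.0      # probability a visit lacks this modality
    modality: str | None = None    # missingness is drawn per modality

    def __post_init__(self):
        if self.direction not in (-1, 1):
            raise ConfigurationError(f"{self.name}: direction must be +1 or -1")
        if self.normal_sd <= 0 or self.abnormal_sd <= 0:
            raise ConfigurationError(f"{self.name}: standard deviations must be > 0")
        if self.direction * (self.abnormal_mean - self.normal_mean) <= 0:
            raise ConfigurationError(
                f"{self.name}: abnormal_mean must lie on the pathological side of normal_mean")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigurationError(f"{self.name}: missing_rate must be in [0, 1)")
        if self.sigmoid_rate <= 0:
            raise ConfigurationError(f"{self.name}: sigmoid_rate must be > 0")

    def mean_at(self, t):
        """Noise-free trajectory value at latent time ``t`` (years from onset)."""
        s = _expit(self.sigmoid_rate * (np.asarray(t, dtype=float) - self.sigmoid_midpoint))
        return self.normal_mean + (self.abnormal_mean - self.normal_mean) * s

    def sd_at(self, t):
        s = _expit(self.sigmoid_rate * (np.asarray(t, dtype=float) - self.sigmoid_midpoint))
        return self.normal_sd + (self.abnormal_sd - self.normal_sd) * s

    def transition_time(self, lower_frac: float = 0.25, upper_frac: float = 0.75) -> float:
        """Closed-form years for the noise-free sigmoid to pass between two
        fractional levels of its range (default the 25%..75% band, for which
        a logistic with rate r gives 2*ln(3)/r)."""
        lo = np.log(lower_frac / (1 - lower_frac))
        hi = np.log(upper_frac / (1 - upper_frac))
        return (hi - lo) / self.sigmoid_rate


def _expit(z):
    from scipy.special import expit
    return expit(z)


@dataclass(frozen=True)
class VisitSchedule:
    """Per-subject visit counts (1..4) and spacing in years."""

    n_visits_probs: tuple = (0.45, 0.25, 0.20, 0.10)
    spacing_mean: float = 1.1      # years between consecutive visits
    spacing_jitter: float = 0.25   # half-width of uniform jitter

    def __post_init__(self):
        p = np.asarray(self.n_visits_probs, dtype=float)
        if p.ndim != 1 or len(p) < 1 or np.any(p < 0) or not np.isclose(p.sum(), 1.0):
            raise ConfigurationError("n_visits_probs must be non-negative and sum to 1")
        if self.spacing_mean <= 0 or self.spacing_jitter < 0:
            raise ConfigurationError("visit spacing must be positive")


@dataclass
class CohortConfig:
    """Full recipe for one synthetic cohort."""

    n_carriers: int
    n_noncarriers: int
    event_sequence: list                      # permutation of biomarker names
    biomarker_specs: list                     # list[BiomarkerSpec]
    visit_schedule: VisitSchedule = field(default_factory=VisitSchedule)
    onset_age_mean: float = 46.0
    onset_age_sd: float = 7.0
    baseline_age_mean: float = 39.0
    baseline_age_sd: float = 10.0
    tau_window: tuple = (-30.0, 10.0)         # latent baseline time from onset
    cdr1_threshold: float = 3.0               # years post-onset before CDR >= 1
    covariate_effects: dict = field(default_factory=dict)  # name -> {cov: coef}
    eyo_surrogate_sd: float = 5.0             # parental-estimate noise, years
    mutation_eyo_sd: float = 8.0              # mutation-type estimate noise
    couple_age_to_tau: bool = False
    noise_scale: float = 1.0                  # 0 gives noise-free trajectories
    subject_noise_frac: float = 0.75          # noise variance that is a stable
                                              # per-subject offset (rest is
                                              # visit-level measurement error)
    seed: int = 0

    def __post_init__(self):
        if self.n_carriers <= 0 or self.n_noncarriers <= 0:
            raise ConfigurationError("group sizes must be positive")
        names = [s.name for s in self.biomarker_specs]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate biomarker names")
        if sorted(self.event_sequence) != sorted(names):
            raise ConfigurationError(
                "event_sequence must be a permutation of the biomarker names")
        spec_by_name = {s.name: s for s in self.biomarker_specs}
        mids = [spec_by_name[n].sigmoid_midpoint for n in self.event_sequence]
        if not np.all(np.diff(mids) > 0):
            raise ConfigurationError(
                "sigmoid midpoints must be strictly increasing along event_sequence")
        lo, hi = self.tau_window
        if not lo < hi:
            raise ConfigurationError("tau_window must satisfy lo < hi")
        if self.noise_scale < 0:
            raise ConfigurationError("noise_scale must be >= 0")
        if not (0.0 <= self.subject_noise_frac <= 1.0):
            raise ConfigurationError("subject_noise_frac must be in [0, 1]")

    @property
    def biomarker_names(self):
        return [s.name for s in self.biomarker_specs]

    @property
    def directions(self):
        return {s.name: s.direction for s in self.biomarker_specs}

    def to_dict(self) -> dict:
        d = asdict(self)
        d["visit_schedule"]["n_visits_probs"] = list(self.visit_schedule.n_visits_probs)
        d["tau_window"] = list(self.tau_window)
        return d


@dataclass
class GroundTruth:
    """What the generator knows and the models try to recover."""

    sequence: list                      # true event ordering (names)
    latent_times: pd.DataFrame          # subject_id, visit_index, latent_time, true_stage
    transition_times: dict              # name -> analytic transition time, years
    midpoints: dict                     # name -> sigmoid midpoint, years from onset


def default_biomarker_specs() -> list:
    """A 24-biomarker panel patterned on a multimodal familial-AD study:
    amyloid PET SUVRs, CSF analytes, FDG PET, regional MRI volumes and
    thicknesses, and a global cognitive score. Twenty-one biomarkers carry
    disease signal with sigmoid midpoints spread over roughly 25
    presymptomatic years; three volumes (entorhinal, thalamus, caudate)
    are null markers with no carrier effect, so selection procedures have
    something to reject. Directions follow the pathology (SUVR and CSF
    tau rise, volumes/thickness/cognition/FDG fall, CSF amyloid-beta
    falls). Units are plausible natural scales (SUVR, pg/ml, mm^3, mm,
    MMSE points) so rules that presume positive-valued assays — notably
    the within-subject coefficient-of-variation exclusion — behave as on
    real data; effect sizes are given in normal-sd units, the quantity
    every model actually sees.
    """
    # name, direction, normal (mu, sd), effect (sd units), sd ratio, rate, midpoint, modality, missing
    rows = [
        ("pib_precuneus",      +1, 1.15, 0.18,  3.0, 1.2, 0.45, -24.0, "pib", 0.30),
        ("pib_cortical_mean",  +1, 1.10, 0.15,  3.0, 1.2, 0.45, -23.0, "pib", 0.30),
        ("pib_caudate",        +1, 1.10, 0.16,  2.8, 1.2, 0.40, -21.5, "pib", 0.30),
        ("pib_putamen",        +1, 1.15, 0.16,  2.8, 1.2, 0.40, -20.5, "pib", 0.30),
        ("pib_accumbens",      +1, 1.10, 0.17,  2.6, 1.2, 0.40, -19.5, "pib", 0.30),
        ("csf_ptau",           +1, 28.0, 9.0,   2.6, 1.3, 0.35, -17.5, "csf", 0.20),
        ("csf_tau",            +1, 65.0, 22.0,  2.5, 1.3, 0.35, -16.0, "csf", 0.20),
        ("csf_ab42",           -1, 420.0, 95.0, -2.5, 1.2, 0.35, -14.5, "csf", 0.20),
        ("mri_putamen_vol",    -1, 10400.0, 900.0, -2.4, 1.1, 0.40, -12.5, "mri", 0.15),
        ("mri_accumbens_vol",  -1, 1350.0, 170.0, -2.4, 1.1, 0.40, -11.5, "mri", 0.15),
        ("mmse",               -1, 29.0, 1.1,  -2.6, 1.3, 0.50,  -9.5, "cog", 0.07),
        ("fdg_postcingulate",  -1, 1.55, 0.12, -2.2, 1.2, 0.45,  -8.0, "fdg", 0.25),
        ("fdg_cortical_mean",  -1, 1.45, 0.10, -2.2, 1.2, 0.45,  -7.0, "fdg", 0.25),
        ("fdg_hippocampus",    -1, 1.20, 0.10, -2.0, 1.2, 0.45,  -6.0, "fdg", 0.25),
        ("mri_hippocampus_vol", -1, 8800.0, 750.0, -2.4, 1.1, 0.50,  -5.0, "mri", 0.15),
        ("mri_midtemporal_th", -1, 2.85, 0.14, -2.2, 1.1, 0.50,  -4.0, "mri", 0.15),
        ("mri_fusiform_th",    -1, 2.70, 0.13, -2.2, 1.1, 0.50,  -3.0, "mri", 0.15),
        ("mri_precuneus_th",   -1, 2.40, 0.12, -2.2, 1.1, 0.50,  -2.0, "mri", 0.15),
        ("mri_ventricles",     +1, 24000.0, 7000.0, 2.4, 1.2, 0.45,  -1.0, "mri", 0.15),
        ("mri_whole_brain",    -1, 1.10e6, 7.5e4, -2.2, 1.1, 0.45,   0.5, "mri", 0.15),
        ("mri_postcingulate_th", -1, 2.50, 0.12, -2.0, 1.1, 0.45,  1.5, "mri", 0.15),
        # Null markers: no real carrier effect (tiny nominal offset keeps the
        # abnormal mean on the pathological side as the invariant requires).
        ("mri_entorhinal_vol", -1, 1800.0, 250.0, -0.05, 1.0, 0.30,  5.0, "mri", 0.15),
        ("mri_thalamus_vol",   -1, 14200.0, 1200.0, -0.05, 1.0, 0.30,  6.0, "mri", 0.15),
        ("mri_caudate_vol",    -1, 7100.0, 700.0, -0.05, 1.0, 0.30,  7.0, "mri", 0.15),
    ]
    return [
        BiomarkerSpec(name=n, direction=d, normal_mean=mn, normal_sd=sn,
                      abnormal_mean=mn + d_sd * sn, abnormal_sd=ratio * sn,
                      sigmoid_rate=r, sigmoid_midpoint=m, modality=mod,
                      missing_rate=miss)
        for (n, d, mn, sn, d_sd, ratio, r, m, mod, miss) in rows
    ]


def uniform_panel(n_biomarkers: int, effect_size: float = 2.0,
                  sd_abnormal: float = 1.2, sigmoid_rate: float = 0.4,
                  midpoint_range: tuple = (-24.0, 0.0),
                  missing_rate: float = 0.0, alternate_direction: bool = True) -> list:
    """A homogeneous panel for controlled experiments: ``n_biomarkers``
    unit-normal biomarkers with |abnormal - normal| = ``effect_size``
    (in normal-sd units), sigmoid midpoints evenly spaced over
    ``midpoint_range``, alternating direction by default."""
    mids = np.linspace(*midpoint_range, n_biomarkers)
    specs = []
    for i, m in enumerate(mids):
        d = -1 if (alternate_direction and i % 2) else 1
        specs.append(BiomarkerSpec(
            name=f"bm_{i:02d}", direction=d, normal_mean=0.0, normal_sd=1.0,
            abnormal_mean=d * effect_size, abnormal_sd=sd_abnormal,
            sigmoid_rate=sigmoid_rate, sigmoid_midpoint=float(m),
            missing_rate=missing_rate))
    return specs


def default_config(seed: int = 0, **overrides) -> CohortConfig:
    """Study-scale default cohort: 211 carriers, 127 non-carriers (the
    cross-sectional sample sizes of the emulated study), default panel,
    mild age/education/sex/TIV confounding on a few biomarkers."""
    specs = default_biomarker_specs()
    sequence = sorted((s.name for s in specs),
                      key=lambda n: {x.name: x.sigmoid_midpoint for x in specs}[n])
    effects = {
        # natural units per year of age / year of education / mm^3 of TIV
        "mri_hippocampus_vol": {"age": -9.0, "tiv": 1.5e-3},
        "mri_whole_brain": {"age": -1500.0, "tiv": 0.25},
        "mri_ventricles": {"age": 250.0},
        "mmse": {"education": 0.06, "age": -0.012},
        "pib_cortical_mean": {"age": 0.0015},
    }
    cfg = dict(n_carriers=211, n_noncarriers=127, event_sequence=sequence,
               biomarker_specs=specs, covariate_effects=effects, seed=seed)
    cfg.update(overrides)
    return CohortConfig(**cfg)


def generate_cohort(config: CohortConfig, keep_truth: bool = False) -> pd.DataFrame:
    """Draw one cohort table. One row per subject-visit; missing biomarker
    cells are NaN. With ``keep_truth`` the hidden latent_time and true_stage
    columns are included (required by :func:`ground_truth`).

    Reproducible: identical config (including seed) gives an identical table.
    """
    rng = np.random.default_rng(config.seed)
    specs = config.biomarker_specs
    spec_by_name = {s.name: s for s in specs}
    mids_in_seq = np.array([spec_by_name[n].sigmoid_midpoint for n in config.event_sequence])

    n_c, n_n = config.n_carriers, config.n_noncarriers
    n_total = n_c + n_n
    carrier = np.concatenate([np.ones(n_c, bool), np.zeros(n_n, bool)])
    subject_ids = ([f"C{i:04d}" for i in range(n_c)]
                   + [f"N{i:04d}" for i in range(n_n)])

    # Covariates (population-level, independent of disease by default).
    sex = (rng.random(n_total) < 0.55).astype(int)            # 1 = female
    education = np.clip(np.round(rng.normal(14.0, 3.0, n_total)), 6, 22)
    tiv = rng.normal(1.45e6, 1.3e5, n_total) - 8.0e4 * sex    # mm^3, sex-linked
    apoe4 = rng.random(n_total) < 0.29
    mut_labels = np.where(
        carrier,
        rng.choice(["PSEN1", "PSEN2", "APP"], size=n_total, p=[0.77, 0.08, 0.15]),
        "NC",
    )

    # Latent disease clock for carriers.
    tau_bl = np.full(n_total, np.nan)
    tau_bl[:n_c] = rng.uniform(*config.tau_window, size=n_c)
    onset_age = rng.normal(config.onset_age_mean, config.onset_age_sd, n_total)
    if config.couple_age_to_tau:
        age_bl = np.where(carrier, onset_age + tau_bl,
                          rng.normal(config.baseline_age_mean, config.baseline_age_sd, n_total))
    else:
        age_bl = rng.normal(config.baseline_age_mean, config.baseline_age_sd, n_total)
    age_bl = np.clip(age_bl, 18.0, 75.0)

    # Familial surrogate errors: one draw per subject, constant across visits.
    eyo_err = rng.normal(0.0, config.eyo_surrogate_sd, n_total)
    mut_err = rng.normal(0.0, config.mutation_eyo_sd, n_total)

    sched = config.visit_schedule
    n_visits = rng.choice(np.arange(1, len(sched.n_visits_probs) + 1),
                          size=n_total, p=sched.n_visits_probs)

    # Population means used to centre covariate effects so that marginal
    # biomarker distributions keep their configured normal/abnormal levels.
    cov_means = {"age": float(np.mean(age_bl)), "sex": float(np.mean(sex)),
                 "education": float(np.mean(education)), "tiv": float(np.mean(tiv))}

    modalities = {}
    for s in specs:
        modalities.setdefault(s.modality or s.name, []).append(s.name)
    modality_rate = {}
    for mod, names in modalities.items():
        rates = {spec_by_name[n].missing_rate for n in names}
        if len(rates) != 1:
            raise ConfigurationError(
                f"modality {mod!r}: all member biomarkers must share one missing_rate")
        modality_rate[mod] = rates.pop()

    # Measurement noise splits into a stable subject-level offset and
    # independent visit-level error; the marginal at any visit keeps the
    # configured sd, while within-subject visit-to-visit scatter is
    # reduced, as in real longitudinal measurements.
    f_sub = np.sqrt(config.subject_noise_frac)
    f_vis = np.sqrt(1.0 - config.subject_noise_frac)
    z_subject = rng.standard_normal((n_total, len(specs)))

    rows = []
    for i in range(n_total):
        offsets = [0.0]
        for _ in range(int(n_visits[i]) - 1):
            gap = sched.spacing_mean + rng.uniform(-sched.spacing_jitter, sched.spacing_jitter)
            offsets.append(offsets[-1] + gap)
        for v, off in enumerate(offsets):
            t = tau_bl[i] + off if carrier[i] else np.nan
            if carrier[i]:
                if t < 0:
                    cdr = 0.0
                elif t < config.cdr1_threshold:
                    cdr = 0.5
                else:
                    cdr = 1.0
                true_stage = int(np.searchsorted(mids_in_seq, t, side="right"))
                p_eyo = t + eyo_err[i]
                m_eyo = t + mut_err[i]
            else:
                cdr, true_stage, p_eyo, m_eyo = 0.0, 0, np.nan, np.nan
            row = {
                "subject_id": subject_ids[i],
                "visit_index": v,
                "years_from_baseline": off,
                "age": age_bl[i] + off,
                "sex": int(sex[i]),
                "education": float(education[i]),
                "tiv": float(tiv[i]),
                "carrier": bool(carrier[i]),
                "mutation_type": mut_labels[i],
                "apoe4": bool(apoe4[i]),
                "cdr_global": cdr,
                "parental_eyo": p_eyo,
                "mutation_eyo": m_eyo,
                "actual_onset_age": np.nan,   # filled in for converters below
                "latent_time": t,
                "true_stage": true_stage,
            }
            cov_dev = {c: row[c] - cov_means[c] for c in COVARIATE_COLUMNS}
            for k, s in enumerate(specs):
                if carrier[i]:
                    mu, sd = float(s.mean_at(t)), float(s.sd_at(t))
                else:
                    mu, sd = s.normal_mean, s.normal_sd
                eff = config.covariate_effects.get(s.name, {})
                mu = mu + sum(coef * cov_dev[c] for c, coef in eff.items())
                z = f_sub * z_subject[i, k] + f_vis * rng.standard_normal()
                row[s.name] = mu + config.noise_scale * sd * z
            # Missingness: one draw per modality per visit row.
            for mod, names in modalities.items():
                if modality_rate[mod] > 0 and rng.random() < modality_rate[mod]:
                    for n in names:
                        row[n] = np.nan
            rows.append(row)

    table = pd.DataFrame(rows)

    # Observed onset age for converters: CDR 0 at baseline, non-zero later.
    bl = table[table["visit_index"] == 0].set_index("subject_id")
    ever_sym = table.groupby("subject_id")["cdr_global"].max()
    converters = bl.index[(bl["cdr_global"] == 0) & (ever_sym.loc[bl.index] > 0)]
    for sid in converters:
        r = bl.loc[sid]
        table.loc[table["subject_id"] == sid, "actual_onset_age"] = (
            r["age"] - r["latent_time"])

    if not keep_truth:
        table = table.drop(columns=TRUTH_COLUMNS)
    return table


def ground_truth(table: pd.DataFrame, config: CohortConfig,
                 lower_frac: float = 0.25, upper_frac: float = 0.75) -> GroundTruth:
    """Extract the generator's ground truth from a table built with
    ``keep_truth=True``: the true event sequence, per-subject-visit latent
    times and stages, and the closed-form transition time of each sigmoid
    between fractional levels of its range."""
    missing = [c for c in TRUTH_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(
            f"ground truth columns {missing} absent: generate with keep_truth=True")
    latents = table[["subject_id", "visit_index", "latent_time", "true_stage"]].copy()
    trans = {s.name: s.transition_time(lower_frac, upper_frac)
             for s in config.biomarker_specs}
    mids = {s.name: s.sigmoid_midpoint for s in config.biomarker_specs}
    return GroundTruth(sequence=list(config.event_sequence), latent_times=latents,
                       transition_times=trans, midpoints=mids)


# ---------------------------------------------------------------------------
# Serialization helpers (CSV table + JSON ground-truth sidecar, config YAML)

def write_cohort(table: pd.DataFrame, path, truth: GroundTruth | None = None,
                 config: CohortConfig | None = None) -> None:
    """Write the cohort as CSV (missing cells empty) plus optional JSON
    sidecars: the ground truth and the generating configuration."""
    path = Path(path)
    table.to_csv(path, index=False)
    if truth is not None:
        sidecar = path.with_suffix(".truth.json")
        payload = {
            "sequence": truth.sequence,
            "transition_times": truth.transition_times,
            "midpoints": truth.midpoints,
            "latent_times": truth.latent_times.to_dict(orient="list"),
        }
        sidecar.write_text(json.dumps(payload, indent=1))
    if config is not None:
        path.with_suffix(".config.json").write_text(
            json.dumps(config.to_dict(), indent=1))


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path)
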