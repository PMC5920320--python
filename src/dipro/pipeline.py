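"""End-to-end pipeline: simulate or load a cohort, adjust covariates,
select disease-signal biomarkers, fit the event-based model (sequence,
uncertainty, bootstrap, staging) and the differential-equation models
(rates, exclusions, trajectories, cumulative-abnormality sigmoids), then
estimate and evaluate time from onset for held-out converters.

Every stochastic stage draws from a seed spawned deterministically from
the master seed, so a rerun with the same configuration reproduces all
numeric outputs exactly. A machine-readable manifest records seeds,
versions, selections and exclusion counts; per-stage timings go to the
log only so the manifest itself is reproducible.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (BiomarkerSpec, CohortConfig, VisitSchedule, default_config,
                     generate_cohort, ground_truth, read_cohort, write_cohort,
                     COVARIATE_COLUMNS)
from .preprocess import (adjust_covariates, select_biomarkers, compute_rates,
                         apply_dem_exclusions)
from . import ebm as _ebm
from . import dem as _dem
from .onset import estimate_time_from_onset, evaluate_onset_predictions, find_converters

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class EbmSettings:
    n_mcmc: int = 100_000
    burn_in: int = 10_000
    thin: int = 10
    n_boot: int = 100
    n_restarts: int = 10


@dataclass
class DemSettings:
    method: str = "laplace"        # or "mcmc"
    n_samples: int = 100
    grid_size: int = 200
    margin: float = 0.10
    eps_frac: float = 1e-4
    min_points: int = 8


@dataclass
class PipelineConfig:
    """Everything one run needs. Either ``input_csv`` (a cohort table on
    disk) or ``cohort`` (a synthetic recipe) supplies the data."""

    cohort: CohortConfig | None = None
    input_csv: str | None = None
    covariates: list = field(default_factory=lambda: list(COVARIATE_COLUMNS))
    alpha_family: float = 0.01
    cv_threshold: float = 0.5
    ebm: EbmSettings = field(default_factory=EbmSettings)
    dem: DemSettings = field(default_factory=DemSettings)
    seed: int = 0
    out_dir: str = "dipro_output"
    make_plots: bool = True

    def __post_init__(self):
        if self.cohort is None and self.input_csv is None:
            self.cohort = default_config(seed=self.seed)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "cohort" in d and d["cohort"] is not None and not isinstance(d["cohort"], CohortConfig):
            cd = dict(d["cohort"])
            if "biomarker_specs" in cd:
                cd["biomarker_specs"] = [BiomarkerSpec(**s) for s in cd["biomarker_specs"]]
            if "visit_schedule" in cd:
                vs = dict(cd["visit_schedule"])
                if "n_visits_probs" in vs:
                    vs["n_visits_probs"] = tuple(vs["n_visits_probs"])
                cd["visit_schedule"] = VisitSchedule(**vs)
            if "tau_window" in cd:
                cd["tau_window"] = tuple(cd["tau_window"])
            d["cohort"] = CohortConfig(**cd)
        if "ebm" in d and not isinstance(d.get("ebm"), EbmSettings):
            d["ebm"] = EbmSettings(**(d["ebm"] or {}))
        if "dem" in d and not isinstance(d.get("dem"), DemSettings):
            d["dem"] = DemSettings(**(d["dem"] or {}))
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _spawn_seeds(seed: int, n: int = 8) -> list:
    """Deterministic per-stage seeds below 2**31."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2 ** 31) for s in ss.generate_state(n)]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and write the output bundle; returns a dict of
    in-memory results keyed by stage."""
    t_start = time.perf_counter()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _spawn_seeds(config.seed)
    manifest = {
        "dipro_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "master_seed": config.seed,
        "stage_seeds": {"ebm_mcmc": seeds[1], "ebm_bootstrap": seeds[2],
                        "ebm_restarts": seeds[3], "dem": seeds[4]},
    }
    if config.cohort is not None:
        manifest["cohort_seed"] = config.cohort.seed
    manifest["config"] = {
        "cohort": config.cohort.to_dict() if config.cohort is not None else None,
        "input_csv": config.input_csv,
        "covariates": list(config.covariates),
        "alpha_family": config.alpha_family,
        "cv_threshold": config.cv_threshold,
        "ebm": asdict(config.ebm),
        "dem": asdict(config.dem),
        "seed": config.seed,
    }
    results: dict = {}

    # --- data -------------------------------------------------------------
    t0 = time.perf_counter()
    if config.input_csv is not None:
        table = read_cohort(config.input_csv)
        truth = None
        manifest["input"] = str(config.input_csv)
    else:
        cohort_cfg = config.cohort
        table = generate_cohort(cohort_cfg, keep_truth=True)
        truth = ground_truth(table, cohort_cfg)
        write_cohort(table, out / "cohort.csv", truth)
        manifest["input"] = "synthetic"
        manifest["n_carriers"] = int(cohort_cfg.n_carriers)
        manifest["n_noncarriers"] = int(cohort_cfg.n_noncarriers)
    biomarkers = [c for c in table.columns
                  if c not in ("subject_id", "visit_index", "years_from_baseline",
                               "carrier", "mutation_type", "apoe4", "cdr_global",
                               "parental_eyo", "mutation_eyo", "actual_onset_age",
                               "latent_time", "true_stage", *COVARIATE_COLUMNS)]
    if config.cohort is not None:
        missing_cols = [b for b in config.cohort.biomarker_names
                        if b not in table.columns]
        if missing_cols:
            raise KeyError(f"configured biomarker columns missing from data: "
                           f"{missing_cols}")
        biomarkers = config.cohort.biomarker_names
        directions = config.cohort.directions
    else:
        directions = None
    converters = find_converters(table)
    manifest["n_converters"] = len(converters)
    results["cohort"] = table
    results["truth"] = truth
    log.info("data stage: %.1fs (%d rows)", time.perf_counter() - t0, len(table))

    # --- preprocess -------------------------------------------------------
    t0 = time.perf_counter()
    panel = adjust_covariates(table, config.covariates, biomarkers,
                              directions=directions)
    retained = select_biomarkers(panel, alpha_family=config.alpha_family)
    panel.table.to_csv(out / "adjusted_panel.csv", index=False)
    (out / "retained_biomarkers.json").write_text(json.dumps(retained, indent=1))
    manifest["n_biomarkers_panel"] = len(biomarkers)
    manifest["n_biomarkers_retained"] = len(retained)
    manifest["retained_covariates"] = panel.retained_covariates
    results["panel"] = panel
    results["retained"] = retained
    log.info("preprocess stage: %.1fs (%d/%d biomarkers retained)",
             time.perf_counter() - t0, len(retained), len(biomarkers))

    # --- event-based model -------------------------------------------------
    t0 = time.perf_counter()
    model = _ebm.fit_event_distributions(panel, retained, directions=directions)
    carriers_bl = panel.baseline()[panel.baseline()["carrier"].astype(bool)]
    L = _ebm.compute_likelihoods(carriers_bl, model, retained)
    ml_order, ml_ll = _ebm.find_ml_sequence(
        L, n_restarts=config.ebm.n_restarts,
        rng=np.random.default_rng(seeds[3]))
    posterior = _ebm.mcmc_sample_sequences(
        L, ml_order, n_samples=config.ebm.n_mcmc, burn_in=config.ebm.burn_in,
        thin=config.ebm.thin, rng=np.random.default_rng(seeds[1]))
    boot = _ebm.bootstrap_sequence(
        panel, retained, n_boot=config.ebm.n_boot,
        n_restarts=config.ebm.n_restarts, directions=directions,
        rng=np.random.default_rng(seeds[2]))
    L_all = _ebm.compute_likelihoods(panel.table, model, retained)
    best_order = [retained.index(n) for n in posterior.ml_sequence]
    staging = _ebm.stage_subjects(L_all, best_order)
    posterior.positional_variance_frame().to_csv(out / "positional_variance_mcmc.csv")
    boot.positional_variance_frame().to_csv(out / "positional_variance_bootstrap.csv")
    staging.stages.to_csv(out / "staging.csv", index=False)
    manifest["ml_sequence"] = posterior.ml_sequence
    manifest["ml_log_likelihood"] = posterior.ml_log_likelihood
    manifest["mcmc_acceptance_rate"] = posterior.acceptance_rate
    results["event_model"] = model
    results["sequence_posterior"] = posterior
    results["bootstrap_posterior"] = boot
    results["staging"] = staging
    if config.make_plots:
        from .plotting import plot_positional_variance
        plot_positional_variance(posterior, out / "positional_variance_mcmc.png",
                                 title="Sequence posterior (MCMC)")
        plot_positional_variance(boot, out / "positional_variance_bootstrap.png",
                                 title="Sequence (bootstrap)")
    log.info("ebm stage: %.1fs", time.perf_counter() - t0)

    # --- differential-equation models --------------------------------------
    t0 = time.perf_counter()
    dem_subjects = [s for s in table[table["carrier"].astype(bool)]["subject_id"].unique()
                    if s not in converters]
    rates = compute_rates(panel, retained, subjects=dem_subjects)
    rates = apply_dem_exclusions(rates, panel, cv_threshold=config.cv_threshold,
                                 directions=directions)
    rates.exclusions.to_csv(out / "dem_exclusions.csv", index=False)
    manifest["dem_exclusion_counts"] = (
        rates.exclusions.groupby("reason").size().to_dict())
    dem_rng = np.random.default_rng(seeds[4])
    dem_results = {}
    dem_failures = {}
    curves = {}
    for b in retained:
        pts = rates.points.get(b)
        if pts is None or len(pts) < config.dem.min_points:
            dem_failures[b] = f"too few differential points ({0 if pts is None else len(pts)})"
            continue
        try:
            post = _dem.fit_rate_function(
                pts["x"], pts["dxdt"], grid_size=config.dem.grid_size,
                margin=config.dem.margin, n_samples=config.dem.n_samples,
                method=config.dem.method, rng=dem_rng)
            anchors = _dem.compute_anchor_levels(panel, b,
                                                 direction=(directions or {}).get(b))
            traj = _dem.integrate_trajectory(post, anchors,
                                             eps_frac=config.dem.eps_frac)
            curve = _dem.cumulative_abnormality_curve(traj)
            dem_results[b] = {"posterior": post, "anchors": anchors,
                              "trajectory": traj, "curve": curve}
            curves[b] = curve
        except (ValueError, RuntimeError) as exc:
            dem_failures[b] = str(exc)
            log.warning("dem: biomarker %s skipped: %s", b, exc)
    if dem_results:
        tt = {b: {"quartiles": r["trajectory"].transition_time_quartiles,
                  "t50": r["curve"][2],
                  "n_rejected": r["trajectory"].n_rejected,
                  "n_truncated": r["trajectory"].n_truncated}
              for b, r in dem_results.items()}
        pd.DataFrame(tt).T.to_csv(out / "transition_times.csv")
        t50_order = sorted(curves, key=lambda b: curves[b][2])
        manifest["t50_ordering"] = t50_order
    manifest["dem_failures"] = dem_failures
    results["dem"] = dem_results
    results["rates"] = rates
    if config.make_plots and dem_results:
        from .plotting import plot_trajectory_fan, plot_cumulative_curves
        for b, r in dem_results.items():
            plot_trajectory_fan(r["trajectory"], out / f"trajectory_{b}.png", title=b)
        plot_cumulative_curves(curves, out / "cumulative_abnormality.png")
    log.info("dem stage: %.1fs (%d trajectories)", time.perf_counter() - t0,
             len(dem_results))

    # --- onset -------------------------------------------------------------
    t0 = time.perf_counter()
    results["onset"] = None
    if converters and dem_results:
        trajs = {b: r["trajectory"] for b, r in dem_results.items()}
        bl = panel.baseline().set_index("subject_id")
        estimates = {}
        for sid in converters:
            if sid not in bl.index:
                continue
            meas = {b: float(bl.loc[sid, b]) for b in trajs
                    if np.isfinite(bl.loc[sid, b])}
            try:
                estimates[sid] = estimate_time_from_onset(meas, trajs, subject_id=sid)
            except ValueError as exc:
                log.warning("onset: %s skipped: %s", sid, exc)
        if estimates:
            evaluation = evaluate_onset_predictions(estimates, table,
                                                    converters=converters)
            evaluation.pairs.to_csv(out / "onset_predictions.csv", index=False)
            manifest["onset_rmse"] = evaluation.rmse
            manifest["onset_adjusted_r2"] = evaluation.adjusted_r2
            results["onset"] = evaluation
    log.info("onset stage: %.1fs", time.perf_counter() - t0)

    manifest["outputs"] = sorted(p.name for p in out.iterdir() if p.is_file())
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    log.info("pipeline complete: %.1fs", time.perf_counter() - t_start)
    results["manifest"] = manifest
    return results
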