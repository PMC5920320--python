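"""Stage subjects along the fitted event sequence.

Every subject-visit is assigned the sequence position that maximizes the
likelihood of its biomarker profile. Non-carriers should sit at stage 0;
carrier stages should track the latent number of abnormal biomarkers.
"""

import numpy as np
from scipy.stats import spearmanr

from dipro import (AdjustedPanel, CohortConfig, compute_likelihoods,
                   find_ml_sequence, fit_event_distributions, generate_cohort,
                   stage_subjects, uniform_panel)

specs = uniform_panel(12, effect_size=4.0)
cfg = CohortConfig(n_carriers=200, n_noncarriers=100, biomarker_specs=specs,
                   event_sequence=[s.name for s in specs], seed=3)
table = generate_cohort(cfg, keep_truth=True)
panel = AdjustedPanel.from_table(table, cfg.biomarker_names,
                                 directions=cfg.directions)
model = fit_event_distributions(panel, cfg.biomarker_names,
                                directions=cfg.directions)
bl = panel.baseline()
order, _ = find_ml_sequence(
    compute_likelihoods(bl[bl["carrier"]], model, cfg.biomarker_names),
    n_restarts=10, rng=np.random.default_rng(0))
staged = stage_subjects(
    compute_likelihoods(panel.table, model, cfg.biomarker_names), order)

merged = staged.stages.merge(
    table[["subject_id", "visit_index", "carrier", "true_stage", "cdr_global"]],
    on=["subject_id", "visit_index"])
nc = merged[~merged["carrier"]]
cc = merged[merged["carrier"]]
rho = spearmanr(cc["stage"], cc["true_stage"]).statistic
print(f"non-carrier visits at stage 0: {(nc['stage'] == 0).mean():.1%} "
      "(the staging system should treat controls as disease-free)")
print(f"Spearman(assigned stage, latent stage) among carriers: {rho:.3f}")
for label, sel in [("CDR 0  ", cc["cdr_global"] == 0),
                   ("CDR 0.5", cc["cdr_global"] == 0.5),
                   ("CDR >=1", cc["cdr_global"] > 0.5)]:
    s = cc.loc[sel, "stage"]
    print(f"  carriers {label}: median stage {s.median():4.1f} "
          f"(IQR {s.quantile(.25):.0f}-{s.quantile(.75):.0f}, n={len(s)})")
print("later clinical groups occupy later model stages, giving a "
      "fine-grained in-between scale for trials.")
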