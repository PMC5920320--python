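"""Fit the event-based model: in what order do biomarkers go abnormal?

Generates a moderate cohort, adjusts covariates, selects biomarkers with
disease signal, fits the two-component event distributions, finds the
maximum-likelihood event sequence by greedy ascent, and samples the
sequence posterior by MCMC. Prints the recovered ordering against the
generative truth and the positional confidence of each event.
"""

import numpy as np
from scipy.stats import kendalltau

from dipro import (adjust_covariates, compute_likelihoods, default_config,
                   find_ml_sequence, fit_event_distributions, generate_cohort,
                   mcmc_sample_sequences, select_biomarkers)

cfg = default_config(seed=2, n_carriers=200, n_noncarriers=100)
table = generate_cohort(cfg, keep_truth=True)
panel = adjust_covariates(table, ["age", "sex", "education", "tiv"],
                          cfg.biomarker_names, directions=cfg.directions)
retained = select_biomarkers(panel, alpha_family=0.01)
print(f"{len(retained)}/{len(cfg.biomarker_names)} biomarkers show disease "
      "signal (non-carriers vs symptomatic carriers, Bonferroni-corrected)")

model = fit_event_distributions(panel, retained, directions=cfg.directions)
bl = panel.baseline()
L = compute_likelihoods(bl[bl["carrier"]], model, retained)
order, ll = find_ml_sequence(L, n_restarts=10, rng=np.random.default_rng(0))
post = mcmc_sample_sequences(L, order, n_samples=20_000, burn_in=2000,
                             thin=10, rng=np.random.default_rng(1))

true_order = [b for b in cfg.event_sequence if b in retained]
pos_true = {b: i for i, b in enumerate(true_order)}
est = post.ml_sequence
tau = kendalltau([pos_true[b] for b in est], range(len(est))).statistic
print(f"ML sequence log-likelihood {post.ml_log_likelihood:.1f}; "
      f"Kendall tau vs generative ordering = {tau:.2f} (1 = perfect)")
print("\nrecovered ordering (posterior confidence of the ML position):")
pv = post.positional_variance
for k, name in enumerate(est):
    i = post.biomarkers.index(name)
    print(f"  {k + 1:2d}. {name:22s} p(position) = {pv[i, k]:.2f}")
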