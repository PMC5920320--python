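"""Estimate long-term biomarker trajectories from short follow-ups.

Each carrier contributes one (value, rate-of-change) point per
biomarker; Gaussian-process regression of rate on value gives a
distribution of differential equations, whose integration yields
probabilistic long-time trajectories anchored at the canonical abnormal
level (median value at carriers' first symptomatic visit, t = 0).
Prints the abnormality transition time (years from the canonical normal
to the canonical abnormal level) and the time each biomarker reaches
50% cumulative probability of abnormality.
"""

import numpy as np

from dipro import (AdjustedPanel, BiomarkerSpec, CohortConfig, VisitSchedule,
                   apply_dem_exclusions, compute_anchor_levels, compute_rates,
                   cumulative_abnormality_curve, fit_rate_function,
                   generate_cohort, integrate_trajectory)

specs = [
    BiomarkerSpec(name="amyloid_like", direction=1, normal_mean=1.1,
                  normal_sd=0.15, abnormal_mean=2.0, abnormal_sd=0.15,
                  sigmoid_rate=0.2, sigmoid_midpoint=-10.5),
    BiomarkerSpec(name="metabolic_like", direction=-1, normal_mean=1.5,
                  normal_sd=0.12, abnormal_mean=0.78, abnormal_sd=0.12,
                  sigmoid_rate=0.5, sigmoid_midpoint=-0.5),
]
cfg = CohortConfig(n_carriers=350, n_noncarriers=30, biomarker_specs=specs,
                   event_sequence=[s.name for s in specs],
                   visit_schedule=VisitSchedule(n_visits_probs=(0, 0, 0.1, 0.9),
                                                spacing_mean=1.4),
                   seed=4)
table = generate_cohort(cfg, keep_truth=True)
panel = AdjustedPanel.from_table(table, cfg.biomarker_names,
                                 directions=cfg.directions)
rates = apply_dem_exclusions(compute_rates(panel), panel,
                             cv_threshold=np.inf)
rng = np.random.default_rng(0)
for b in cfg.biomarker_names:
    pts = rates.points[b]
    post = fit_rate_function(pts["x"], pts["dxdt"], n_samples=150, rng=rng)
    anchors = compute_anchor_levels(panel, b)
    traj = integrate_trajectory(post, anchors)
    t_grid, C, t50 = cumulative_abnormality_curve(traj)
    q25, q50, q75 = traj.transition_time_quartiles
    print(f"{b}:")
    print(f"  {len(pts)} differential points; anchors "
          f"{anchors.canonical_normal:.2f} -> {anchors.canonical_abnormal:.2f}")
    print(f"  abnormality transition time: median {q50:.1f} y "
          f"(IQR {q25:.1f}-{q75:.1f}; {traj.n_rejected} wrong-sign samples "
          "rejected)")
    print(f"  reaches 50% cumulative abnormality at t = {t50:.1f} y "
          "before canonical abnormality")
print("\nthe early slow marker shows the longer measured transition and the "
      "earlier t50: ordering biomarkers by t50 recovers the event sequence "
      "from purely longitudinal information.")
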