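import numpy as np
import pytest

from dipro import (AdjustedPanel, CohortConfig, VisitSchedule, generate_cohort,
                   uniform_panel)


@pytest.fixture(scope="session")
def strong_cohort():
    """Strong-signal uniform cohort with ground truth, shared across tests."""
    specs = uniform_panel(6, effect_size=6.0)
    cfg = CohortConfig(n_carriers=150, n_noncarriers=75, biomarker_specs=specs,
                       event_sequence=[s.name for s in specs], seed=42)
    table = generate_cohort(cfg, keep_truth=True)
    panel = AdjustedPanel.from_table(table, cfg.biomarker_names,
                                     directions=cfg.directions)
    return cfg, table, panel


@pytest.fixture(scope="session")
def longitudinal_cohort():
    """Dense-follow-up cohort for differential-data tests."""
    specs = uniform_panel(4, effect_size=4.0, sd_abnormal=1.0,
                          midpoint_range=(-18.0, -3.0), alternate_direction=True)
    cfg = CohortConfig(
        n_carriers=150, n_noncarriers=40, biomarker_specs=specs,
        event_sequence=[s.name for s in specs],
        visit_schedule=VisitSchedule(n_visits_probs=(0.0, 0.0, 0.2, 0.8),
                                     spacing_mean=1.3),
        seed=7)
    table = generate_cohort(cfg, keep_truth=True)
    panel = AdjustedPanel.from_table(table, cfg.biomarker_names,
                                     directions=cfg.directions)
    return cfg, table, panel


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def _constant_rate_posterior(c=0.5, lo=-1.0, hi=11.0, n_grid=200,
                             n_samples=100):
    """Hand-built rate-function posterior with every sample equal to the
    constant c: trajectories then have the closed form t(x) = (x - x0)/c."""
    from dipro import Kernel
    from dipro.dem import RateFunctionPosterior
    grid = np.linspace(lo, hi, n_grid)
    return RateFunctionPosterior(
        grid=grid, mean=np.full(n_grid, c),
        samples=np.full((n_samples, n_grid), c),
        hyper_samples=np.tile([1.0, 1.0, 0.1], (n_samples, 1)),
        kernel_map=Kernel(1.0, 1.0, 0.1),
        x=np.linspace(lo + 1, hi - 1, 10), y=np.full(10, c), y_center=c)


@pytest.fixture()
def constant_rate_posterior():
    return _constant_rate_posterior
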