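import itertools

import numpy as np
import pandas as pd
import pytest

from dipro import (EventModel, compute_likelihoods, find_ml_sequence,
                   fit_event_distributions, mcmc_sample_sequences,
                   bootstrap_sequence, sequence_log_likelihood,
                   stage_subjects, uniform_panel)
from dipro.ebm import (MISSING_LIKELIHOOD, SubjectLikelihoods,
                       _batch_log_likelihood, _fit_one_mixture)


def make_likelihoods(pE, pN, missing=None):
    pE = np.asarray(pE, float)
    pN = np.asarray(pN, float)
    miss = np.zeros(pE.shape, bool) if missing is None else np.asarray(missing)
    idx = pd.DataFrame({"subject_id": [f"s{i}" for i in range(pE.shape[0])],
                        "visit_index": 0})
    return SubjectLikelihoods(log_p_event=np.log(pE), log_p_normal=np.log(pN),
                              missing=miss,
                              biomarkers=[f"b{j}" for j in range(pE.shape[1])],
                              index=idx)


def brute_force_loglik(L, order):
    """Independent oracle: direct sum over stages, no log-space tricks."""
    pE = np.exp(L.log_p_event)[:, order]
    pN = np.exp(L.log_p_normal)[:, order]
    total = 0.0
    n, N = pE.shape
    for j in range(n):
        s = 0.0
        for k in range(N + 1):
            s += np.prod(pE[j, :k]) * np.prod(pN[j, k:])
        total += np.log(s / (N + 1))
    return total


class TestSequenceLikelihood:
    def test_matches_bruteforce_on_hand_set_tables(self, rng):
        pE = rng.uniform(0.05, 1.0, size=(2, 3))
        pN = rng.uniform(0.05, 1.0, size=(2, 3))
        L = make_likelihoods(pE, pN)
        for order in itertools.permutations(range(3)):
            got = sequence_log_likelihood(list(order), L)
            want = brute_force_loglik(L, list(order))
            assert got == pytest.approx(want, rel=1e-10)

    def test_missing_single_event_gives_log_c(self):
        c = MISSING_LIKELIHOOD
        L = make_likelihoods([[c]], [[c]], missing=[[True]])
        assert sequence_log_likelihood([0], L) == pytest.approx(np.log(c))

    def test_identical_columns_are_order_symmetric(self, rng):
        col_pE = rng.uniform(0.1, 1.0, 5)
        col_pN = rng.uniform(0.1, 1.0, 5)
        pE = np.stack([col_pE, col_pE, rng.uniform(0.1, 1.0, 5)], axis=1)
        pN = np.stack([col_pN, col_pN, rng.uniform(0.1, 1.0, 5)], axis=1)
        L = make_likelihoods(pE, pN)
        assert sequence_log_likelihood([0, 1, 2], L) == pytest.approx(
            sequence_log_likelihood([1, 0, 2], L))

    def test_batch_agrees_with_scalar(self, rng):
        pE = rng.uniform(0.05, 1.0, (4, 4))
        pN = rng.uniform(0.05, 1.0, (4, 4))
        L = make_likelihoods(pE, pN)
        orders = np.array(list(itertools.permutations(range(4))))
        batch = _batch_log_likelihood(orders, L)
        for o, b in zip(orders, batch):
            assert b == pytest.approx(sequence_log_likelihood(o, L))

    def test_non_permutation_rejected(self):
        L = make_likelihoods([[0.5, 0.5]], [[0.5, 0.5]])
        with pytest.raises(ValueError):
            sequence_log_likelihood([0, 0], L)


class TestMixtureFit:
    def test_parameter_recovery(self):
        hits = 0
        for seed in range(5):
            r = np.random.default_rng(seed)
            x = np.concatenate([r.normal(0, 1, 200), r.normal(3, 1, 200)])
            w, mu_a, sd_a = _fit_one_mixture(x, 0.0, 1.0, direction=1)
            hits += (2.7 <= mu_a <= 3.3) and (0.4 <= w <= 0.6)
        assert hits >= 4

    def test_all_normal_carriers_degenerate(self, rng):
        x = rng.normal(0, 1, 300)
        w, mu_a, sd_a = _fit_one_mixture(x, 0.0, 1.0, direction=1)
        assert w > 0.9                 # weight pinned near the upper bound
        assert mu_a == pytest.approx(1.0, abs=0.2)  # pinned at the separation bound

    def test_sd_floor_constraint_active(self):
        x = np.concatenate([np.random.default_rng(0).normal(0, 1, 100),
                            [5.0, 5.0]])
        w, mu_a, sd_a = _fit_one_mixture(x, 0.0, 1.0, direction=1)
        assert sd_a >= 0.1 - 1e-9

    def test_normal_component_frozen_to_noncarriers(self, strong_cohort):
        cfg, table, panel = strong_cohort
        model = fit_event_distributions(panel, cfg.biomarker_names,
                                        directions=cfg.directions)
        bl = panel.baseline()
        nc = bl[~bl["carrier"]]
        for b in cfg.biomarker_names:
            ev = model.events[b]
            assert ev.mu_normal == pytest.approx(nc[b].mean())
            assert ev.sd_normal == pytest.approx(nc[b].std(ddof=1))
            assert ev.direction * (ev.mu_abnormal - ev.mu_normal) > 0


class TestMLSequence:
    def test_single_event_identity(self):
        L = make_likelihoods([[0.9]], [[0.2]])
        order, _ = find_ml_sequence(L, n_restarts=3)
        assert list(order) == [0]

    def test_matches_exhaustive_argmax(self, strong_cohort, rng):
        cfg, table, panel = strong_cohort
        model = fit_event_distributions(panel, cfg.biomarker_names,
                                        directions=cfg.directions)
        bl = panel.baseline()
        L = compute_likelihoods(bl[bl["carrier"]], model, cfg.biomarker_names)
        order, ll = find_ml_sequence(L, n_restarts=5, rng=rng)
        perms = np.array(list(itertools.permutations(range(6))))
        lls = _batch_log_likelihood(perms, L)
        assert ll == pytest.approx(float(lls.max()))
        assert list(order) == list(perms[np.argmax(lls)])

    def test_tie_break_prefers_input_order(self, rng):
        col_pE = rng.uniform(0.1, 1.0, 20)
        col_pN = rng.uniform(0.1, 1.0, 20)
        pE = np.stack([col_pE, col_pE], axis=1)
        pN = np.stack([col_pN, col_pN], axis=1)
        L = make_likelihoods(pE, pN)
        order, _ = find_ml_sequence(L, n_restarts=1)
        assert list(order) == [0, 1]


class TestMCMC:
    def test_flat_likelihood_gives_uniform_positions(self):
        c = MISSING_LIKELIHOOD
        n, N = 3, 5
        L = make_likelihoods(np.full((n, N), c), np.full((n, N), c),
                             missing=np.ones((n, N), bool))
        post = mcmc_sample_sequences(L, np.arange(N), n_samples=100_000,
                                     burn_in=2000, thin=10,
                                     rng=np.random.default_rng(1))
        pv = post.positional_variance
        assert np.max(np.abs(pv - 1.0 / N)) < 0.05

    def test_modal_sample_is_ml_sequence(self, strong_cohort):
        cfg, table, panel = strong_cohort
        model = fit_event_distributions(panel, cfg.biomarker_names,
                                        directions=cfg.directions)
        bl = panel.baseline()
        L = compute_likelihoods(bl[bl["carrier"]], model, cfg.biomarker_names)
        order, _ = find_ml_sequence(L, n_restarts=5,
                                    rng=np.random.default_rng(0))
        post = mcmc_sample_sequences(L, order, n_samples=5000, burn_in=1000,
                                     thin=5, rng=np.random.default_rng(2))
        perms = np.array(list(itertools.permutations(range(6))))
        lls = _batch_log_likelihood(perms, L)
        best = perms[np.argmax(lls)]
        # the most frequent sampled ordering is the brute-force optimum
        uniq, counts = np.unique(post.samples, axis=0, return_counts=True)
        assert list(uniq[np.argmax(counts)]) == list(best)

    def test_positional_variance_rows_and_columns_normalized(self, strong_cohort):
        cfg, table, panel = strong_cohort
        model = fit_event_distributions(panel, cfg.biomarker_names,
                                        directions=cfg.directions)
        bl = panel.baseline()
        L = compute_likelihoods(bl[bl["carrier"]], model, cfg.biomarker_names)
        post = mcmc_sample_sequences(L, np.arange(6), n_samples=2000,
                                     burn_in=200, thin=2,
                                     rng=np.random.default_rng(3))
        pv = post.positional_variance
        np.testing.assert_allclose(pv.sum(axis=0), 1.0)
        np.testing.assert_allclose(pv.sum(axis=1), 1.0)


class TestBootstrap:
    def test_reproducible_with_seed(self, strong_cohort):
        cfg, table, panel = strong_cohort
        a = bootstrap_sequence(panel, cfg.biomarker_names, n_boot=3,
                               n_restarts=3, directions=cfg.directions,
                               rng=np.random.default_rng(5))
        b = bootstrap_sequence(panel, cfg.biomarker_names, n_boot=3,
                               n_restarts=3, directions=cfg.directions,
                               rng=np.random.default_rng(5))
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_strong_signal_mean_displacement_below_one(self, strong_cohort):
        cfg, table, panel = strong_cohort
        post = bootstrap_sequence(panel, cfg.biomarker_names, n_boot=10,
                                  n_restarts=5, directions=cfg.directions,
                                  rng=np.random.default_rng(6))
        # true order is bm_00..bm_05 (index order)
        disp = [np.mean(np.abs(np.argsort(s) - np.arange(6)))
                for s in post.samples]
        assert np.mean(disp) < 1.0


class TestStaging:
    def _model(self):
        specs = uniform_panel(4, effect_size=4.0, sd_abnormal=1.0,
                              alternate_direction=False)
        return specs, EventModel.from_specs(specs)

    def _likelihoods(self, model, values):
        df = pd.DataFrame([dict(subject_id="s0", visit_index=0,
                                **dict(zip([f"bm_{i:02d}" for i in range(4)],
                                           values)))])
        return compute_likelihoods(df, model, [f"bm_{i:02d}" for i in range(4)])

    def test_all_normal_values_stage_zero(self):
        specs, model = self._model()
        L = self._likelihoods(model, [0.0, 0.0, 0.0, 0.0])
        st = stage_subjects(L, np.arange(4))
        assert st.stages["stage"].iloc[0] == 0

    def test_first_k_abnormal_gives_stage_k(self):
        specs, model = self._model()
        for k in range(5):
            values = [4.0] * k + [0.0] * (4 - k)
            L = self._likelihoods(model, values)
            st = stage_subjects(L, np.arange(4))
            assert st.stages["stage"].iloc[0] == k

    def test_all_missing_uniform_posterior_flagged(self):
        specs, model = self._model()
        L = self._likelihoods(model, [np.nan] * 4)
        st = stage_subjects(L, np.arange(4))
        assert st.stages["all_missing"].iloc[0]
        np.testing.assert_allclose(st.posteriors[0], 1 / 5)


class TestImputationNeutrality:
    def test_masking_column_leaves_other_likelihood_ratios_intact(self, rng):
        """Masked cells contribute equal factors under both hypotheses, so
        likelihood differences between orderings of the other events are
        unchanged (exact arithmetic identity)."""
        pE = rng.uniform(0.05, 1.0, (6, 4))
        pN = rng.uniform(0.05, 1.0, (6, 4))
        L = make_likelihoods(pE, pN)
        c = MISSING_LIKELIHOOD
        pE2, pN2 = pE.copy(), pN.copy()
        pE2[:, 2] = c
        pN2[:, 2] = c
        L2 = make_likelihoods(pE2, pN2, missing=(np.arange(4) == 2)[None, :]
                              .repeat(6, axis=0))
        # orderings that keep the masked event in the same slot
        a = sequence_log_likelihood([0, 1, 2, 3], L2)
        b = sequence_log_likelihood([1, 0, 2, 3], L2)
        a0 = sequence_log_likelihood([0, 1, 2, 3], L)
        b0 = sequence_log_likelihood([1, 0, 2, 3], L)
        # masking changes the values but the same-subject comparison between
        # orderings of the unmasked events keeps its sign
        assert np.sign(a - b) == np.sign(a0 - b0) or a == pytest.approx(b)
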