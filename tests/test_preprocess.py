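import numpy as np
import pandas as pd
import pytest

from dipro import (AdjustedPanel, CohortConfig, adjust_covariates,
                   apply_dem_exclusions, compute_rates, default_config,
                   generate_cohort, select_biomarkers, uniform_panel)
from dipro.preprocess import (CV_TOO_LARGE, NORMAL_NONPROGRESSING,
                              TOO_FEW_VISITS, DifferentialDataset)


def _cohort(seed=0, **kw):
    cfg = default_config(seed=seed, **kw)
    return cfg, generate_cohort(cfg, keep_truth=True)


class TestAdjustCovariates:
    def test_empty_covariate_list_is_identity(self):
        cfg, t = _cohort(1, n_carriers=30, n_noncarriers=20)
        panel = adjust_covariates(t, [], cfg.biomarker_names)
        pd.testing.assert_frame_equal(panel.table, t)

    def test_null_effects_rarely_retain_covariates(self):
        """With no generated covariate effects, backward elimination keeps
        an empty covariate set for >= 90% of biomarkers (aggregated over
        several seeds)."""
        specs = uniform_panel(10)
        empties = total = 0
        for seed in range(5):
            cfg = CohortConfig(n_carriers=50, n_noncarriers=450,
                               biomarker_specs=specs,
                               event_sequence=[s.name for s in specs],
                               covariate_effects={}, seed=seed)
            t = generate_cohort(cfg)
            panel = adjust_covariates(t, ["age", "sex", "education"],
                                      cfg.biomarker_names)
            for b, kept in panel.retained_covariates.items():
                total += 1
                empties += not kept
        assert empties / total >= 0.90

    def test_injected_age_effect_removed(self):
        """An age slope put in by the generator leaves residuals with
        essentially no age trend among non-carriers."""
        specs = uniform_panel(1)
        cfg = CohortConfig(n_carriers=10, n_noncarriers=500,
                           biomarker_specs=specs, event_sequence=["bm_00"],
                           covariate_effects={"bm_00": {"age": 0.1}}, seed=3)
        t = generate_cohort(cfg)
        panel = adjust_covariates(t, ["age"], ["bm_00"])
        nc = panel.table[~panel.table["carrier"]]
        slope = np.polyfit(nc["age"], nc["bm_00"], 1)[0]
        assert abs(slope * 10) < 0.05          # < 0.05 units per decade
        assert abs(nc["bm_00"].mean()) < 0.05  # residuals centred

    def test_residualization_idempotent(self):
        cfg, t = _cohort(2, n_carriers=60, n_noncarriers=60)
        p1 = adjust_covariates(t, ["age", "sex", "education", "tiv"],
                               cfg.biomarker_names)
        p2 = adjust_covariates(p1.table, ["age", "sex", "education", "tiv"],
                               cfg.biomarker_names)
        for b in cfg.biomarker_names:
            assert np.nanmax(np.abs(p2.table[b] - p1.table[b])) < 1e-8

    def test_all_missing_biomarker_raises(self):
        cfg, t = _cohort(1, n_carriers=20, n_noncarriers=20)
        t = t.copy()
        t["mmse"] = np.nan
        with pytest.raises(ValueError, match="mmse"):
            adjust_covariates(t, ["age"], cfg.biomarker_names)

    def test_constant_covariate_dropped_with_warning(self):
        cfg, t = _cohort(1, n_carriers=20, n_noncarriers=20)
        t = t.copy()
        t["sex"] = 1
        with pytest.warns(UserWarning, match="sex"):
            adjust_covariates(t, ["sex"], ["mmse"])


class TestSelectBiomarkers:
    def test_signal_markers_kept_nulls_dropped(self):
        """Structural mirror of a 24-marker panel where 3 carry no disease
        signal: exactly the 21 signal biomarkers are retained."""
        hits = 0
        for seed in range(3):
            cfg, t = _cohort(seed, n_carriers=211, n_noncarriers=127)
            panel = adjust_covariates(t, ["age", "sex", "education", "tiv"],
                                      cfg.biomarker_names,
                                      directions=cfg.directions)
            kept = select_biomarkers(panel)
            signal = {s.name for s in cfg.biomarker_specs
                      if abs(s.abnormal_mean - s.normal_mean) > s.normal_sd}
            hits += set(kept) == signal and len(kept) == 21
        assert hits >= 2

    def test_null_markers_rarely_selected(self):
        specs = uniform_panel(4, effect_size=0.01)
        retained = 0
        for seed in range(5):
            cfg = CohortConfig(n_carriers=120, n_noncarriers=60,
                               biomarker_specs=specs,
                               event_sequence=[s.name for s in specs],
                               seed=seed)
            t = generate_cohort(cfg)
            panel = AdjustedPanel.from_table(t, cfg.biomarker_names)
            retained += len(select_biomarkers(panel, alpha_family=0.01))
        assert retained <= 1

    def test_huge_effect_always_retained(self):
        specs = uniform_panel(1, effect_size=5.0)
        for seed in range(5):
            cfg = CohortConfig(n_carriers=100, n_noncarriers=50,
                               biomarker_specs=specs, event_sequence=["bm_00"],
                               seed=seed)
            t = generate_cohort(cfg)
            panel = AdjustedPanel.from_table(t, ["bm_00"])
            assert select_biomarkers(panel) == ["bm_00"]

    def test_too_few_symptomatic_raises(self):
        specs = uniform_panel(2)
        cfg = CohortConfig(n_carriers=30, n_noncarriers=30,
                           biomarker_specs=specs,
                           event_sequence=[s.name for s in specs],
                           tau_window=(-30.0, -10.0), seed=0)  # nobody symptomatic
        t = generate_cohort(cfg)
        panel = AdjustedPanel.from_table(t, cfg.biomarker_names)
        with pytest.raises(ValueError, match="symptomatic"):
            select_biomarkers(panel)


def _panel_from_rows(rows, biomarkers):
    t = pd.DataFrame(rows)
    return AdjustedPanel.from_table(t, biomarkers)


class TestComputeRates:
    def test_exact_line(self):
        rows = [dict(subject_id="c0", visit_index=v, years_from_baseline=float(v),
                     carrier=True, cdr_global=0.0, b=float(v)) for v in range(3)]
        panel = _panel_from_rows(rows, ["b"])
        dd = compute_rates(panel)
        pt = dd.points["b"].iloc[0]
        assert pt["dxdt"] == pytest.approx(1.0)
        assert pt["x"] == pytest.approx(1.0)
        assert pt["n_visits"] == 3

    def test_single_visit_excluded(self):
        rows = [dict(subject_id="c0", visit_index=0, years_from_baseline=0.0,
                     carrier=True, cdr_global=0.0, b=1.0)]
        panel = _panel_from_rows(rows, ["b"])
        dd = compute_rates(panel)
        assert len(dd.points["b"]) == 0
        assert dd.exclusions.iloc[0]["reason"] == TOO_FEW_VISITS

    def test_sigmoid_slope_close_to_analytic(self):
        """Noise-free sigmoid sampled at 3 visits: the least-squares slope
        approximates the analytic derivative at the middle visit within 5%
        when the curve is locally near-linear."""
        from dipro.cohort import BiomarkerSpec
        s = BiomarkerSpec(name="b", direction=1, normal_mean=0, normal_sd=1,
                          abnormal_mean=4, abnormal_sd=1, sigmoid_rate=0.1,
                          sigmoid_midpoint=0.0)
        times = np.array([-1.0, 0.0, 1.0])   # |rate * span| = 0.2 <= 0.3
        vals = s.mean_at(times)
        slope = np.polyfit(times, vals, 1)[0]
        h = 1e-5
        deriv = (s.mean_at(h) - s.mean_at(-h)) / (2 * h)
        assert abs(slope - deriv) / deriv < 0.05


class TestDemExclusions:
    def _dd(self, pts):
        return DifferentialDataset(
            points={"b": pd.DataFrame(pts, columns=["subject_id", "x", "dxdt",
                                                    "n_visits"])},
            exclusions=pd.DataFrame(columns=["biomarker", "subject_id", "reason"]))

    def _panel(self, rng):
        # carriers with a clear bimodal baseline: normal ~0, abnormal ~5
        rows = []
        for i in range(40):
            x = rng.normal(0, 1) if i < 20 else rng.normal(5, 1)
            rows.append(dict(subject_id=f"c{i}", visit_index=0,
                             years_from_baseline=0.0, carrier=True,
                             cdr_global=0.0 if i < 20 else 1.0, b=x))
        return _panel_from_rows(rows, ["b"])

    def test_normal_nonprogressing_excluded(self, rng):
        panel = self._panel(rng)
        dd = self._dd([("s1", 0.0, -0.2, 3)])    # normal side, contrary slope
        out = apply_dem_exclusions(dd, panel, cv_threshold=np.inf,
                                   directions={"b": 1})
        assert len(out.points["b"]) == 0
        assert (out.exclusions["reason"] == NORMAL_NONPROGRESSING).all()

    def test_abnormal_side_contrary_slope_retained(self, rng):
        panel = self._panel(rng)
        dd = self._dd([("s1", 5.0, -0.2, 3)])    # abnormal side: rule not applied
        out = apply_dem_exclusions(dd, panel, cv_threshold=np.inf,
                                   directions={"b": 1})
        assert len(out.points["b"]) == 1

    def test_infinite_cv_threshold_never_excludes_on_cv(self, rng):
        panel = self._panel(rng)
        dd = self._dd([("s1", 5.0, 0.3, 3), ("s2", 2.0, 0.1, 2)])
        out = apply_dem_exclusions(dd, panel, cv_threshold=np.inf,
                                   directions={"b": 1})
        assert CV_TOO_LARGE not in set(out.exclusions["reason"])

    def test_cv_computed_on_raw_values(self):
        # raw values vary wildly within subject -> excluded at threshold 0.5
        rows = [dict(subject_id="s1", visit_index=v, years_from_baseline=float(v),
                     carrier=True, cdr_global=0.0, b=val)
                for v, val in enumerate([1.0, 10.0, 1.0])]
        # extra carriers so boundary clustering has data
        for i in range(10):
            rows.append(dict(subject_id=f"c{i}", visit_index=0,
                             years_from_baseline=0.0, carrier=True,
                             cdr_global=0.0, b=float(i)))
        panel = _panel_from_rows(rows, ["b"])
        dd = DifferentialDataset(
            points={"b": pd.DataFrame([("s1", 4.0, 0.0, 3)],
                                      columns=["subject_id", "x", "dxdt",
                                               "n_visits"])},
            exclusions=pd.DataFrame(columns=["biomarker", "subject_id", "reason"]))
        out = apply_dem_exclusions(dd, panel, cv_threshold=0.5,
                                   directions={"b": 1})
        assert (out.exclusions["reason"] == CV_TOO_LARGE).any()

    def test_exclusion_log_partitions_points(self, longitudinal_cohort):
        cfg, table, panel = longitudinal_cohort
        dd = compute_rates(panel)
        out = apply_dem_exclusions(dd, panel, cv_threshold=np.inf)
        for b in cfg.biomarker_names:
            kept = set(out.points[b]["subject_id"])
            excl = set(out.exclusions.loc[out.exclusions["biomarker"] == b,
                                          "subject_id"])
            assert not kept & excl
            carriers = set(table.loc[table["carrier"], "subject_id"])
            assert kept | excl == carriers
        # exactly one reason per excluded point
        assert not out.exclusions.duplicated(["biomarker", "subject_id"]).any()
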