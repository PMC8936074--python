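import dataclasses

import numpy as np
import pytest

from aodkit import (FitConfig, GeneratorConfig, expected_vo2, simulate_cohort,
                    truths_from_json, truths_to_json)
from aodkit.datamodel import measurements_frame, write_measurements
from aodkit.errors import ConfigError
from aodkit.methods import build_method_relation
from aodkit.simulate import sample_subject


def _noise_free(**kw):
    base = dict(noise_sd=0.0, lactate_noise_sd=0.0, seed=1)
    base.update(kw)
    return GeneratorConfig(**base)


class TestSampling:
    def test_degenerate_sds_give_identical_subjects(self):
        cfg = GeneratorConfig(intercept_sd=0, slope_sd=0, vo2max_sd=0,
                              resting_sd=0, mass_sd=0, seed=3)
        _, truths = simulate_cohort(cfg)
        assert len({t.intercept_true for t in truths}) == 1
        assert all(t.slope_true == cfg.slope_mean for t in truths)

    def test_same_seed_identical_cohorts(self):
        a = simulate_cohort(GeneratorConfig(seed=9))
        b = simulate_cohort(GeneratorConfig(seed=9))
        assert a[1] == b[1]
        fa, fb = measurements_frame(a[0]), measurements_frame(b[0])
        assert fa.equals(fb)

    def test_population_means_recovered(self):
        cfg = GeneratorConfig(seed=17)
        rng = np.random.default_rng(17)
        truths = [sample_subject(cfg, rng, index=i % 13) for i in range(1000)]
        for attr, mean, sd in (("intercept_true", 0.50, 0.05),
                               ("slope_true", 8.8, 0.8),
                               ("resting_vo2", 0.26, 0.03)):
            xs = [getattr(t, attr) for t in truths]
            se = sd / np.sqrt(len(xs))
            assert abs(np.mean(xs) - mean) < 3 * se
        vmax = [t.vo2max for t in truths]
        # truncation (power at VO2max >= 150 W) shifts the mean slightly up
        assert 2.85 < np.mean(vmax) < 3.05

    def test_infeasible_truncation_rejected(self):
        cfg = GeneratorConfig(seed=1)
        rng = np.random.default_rng(1)
        with pytest.raises(ConfigError):
            from aodkit.simulate import _truncated_normal
            _truncated_normal(rng, -5.0, 0.01, 0.0)

    def test_config_validation(self):
        with pytest.raises(ConfigError):
            GeneratorConfig(n_subjects=0)
        with pytest.raises(ConfigError):
            GeneratorConfig(noise_sd=-0.1)


class TestExpectedVo2:
    def setup_method(self):
        self.cfg = GeneratorConfig(intercept_sd=0, slope_sd=0, vo2max_sd=0,
                                   resting_sd=0, mass_sd=0, seed=0)
        self.truth = sample_subject(self.cfg, np.random.default_rng(0))

    def test_linear_regime_above_threshold(self):
        t = self.truth
        for P in (75.0, 120.0, 250.0):
            v = expected_vo2(t, P, 1.5, "bout10", "late", self.cfg)
            assert v == pytest.approx(
                t.intercept_true + t.slope_true * P / 1000.0, rel=1e-12)

    def test_loadless_follows_cubic_anchor(self):
        # resting 0.26 + 0.1185 * 1.5^3 = 0.66 mmol/s
        v = expected_vo2(self.truth, 0.0, 1.5, "loadless", cfg=self.cfg)
        assert v == pytest.approx(0.26 + 0.1185 * 1.5 ** 3, rel=1e-9)
        assert v == pytest.approx(0.66, abs=1e-3)

    def test_low_power_excess_decays_to_zero_at_threshold(self):
        t = self.truth
        linear = lambda P: t.intercept_true + t.slope_true * P / 1000.0
        below = expected_vo2(t, 30.0, 1.5, "bout10", "late", self.cfg)
        at = expected_vo2(t, 75.0, 1.5, "bout10", "late", self.cfg)
        assert below > linear(30.0)
        assert at == pytest.approx(linear(75.0), rel=1e-12)

    def test_drift_ratio_below_threshold(self):
        t = self.truth
        P = 100.0   # below the lactate threshold
        early = expected_vo2(t, P, 1.5, "bout10", "early", self.cfg)
        late = expected_vo2(t, P, 1.5, "bout10", "late", self.cfg)
        assert early / late == pytest.approx(1 / 1.018, rel=1e-12)

    def test_drift_larger_at_or_above_threshold(self):
        t = self.truth
        P = t.lt_power + 10.0
        early = expected_vo2(t, P, 1.5, "bout10", "early", self.cfg)
        late = expected_vo2(t, P, 1.5, "bout10", "late", self.cfg)
        assert early / late == pytest.approx(1 / 1.049, rel=1e-12)

    def test_step_protocol_offset_at_reference_frequency(self):
        t = self.truth
        P = 100.0
        step = expected_vo2(t, P, 1.5, "step4", "early", self.cfg)
        rested = expected_vo2(t, P, 1.5, "bout4_rest", "early", self.cfg)
        assert step - rested == pytest.approx(0.015, rel=1e-9)
        assert expected_vo2(t, P, 0.75, "step4", "early", self.cfg) == \
            pytest.approx(expected_vo2(t, P, 0.75, "bout4_rest", "early",
                                       self.cfg), rel=1e-12)

    def test_rest_is_resting_vo2(self):
        assert expected_vo2(self.truth, 0.0, 0.0, "rest", cfg=self.cfg) == \
            self.truth.resting_vo2

    def test_unknown_protocol_rejected(self):
        with pytest.raises(ConfigError):
            expected_vo2(self.truth, 100.0, 1.5, "sprint", "late", self.cfg)


class TestSimulatedCohorts:
    def test_noiseless_identifiability(self):
        cfg = _noise_free(drift_below=0.0, drift_above=0.0, freq_cubic_k=0.0,
                          resting_mean=0.2, intercept_sd=0.0)
        cohort, truths = simulate_cohort(cfg)
        tr = {t.subject_id: t for t in truths}
        for s in cohort:
            rel = build_method_relation(s, "M0", FitConfig(), 1.5)
            assert rel.intercept == pytest.approx(
                tr[s.subject_id].intercept_true, abs=1e-9)
            assert rel.slope == pytest.approx(
                tr[s.subject_id].slope_true, abs=1e-9)

    def test_bout_grid_structure(self, default_cohort):
        cohort, truths = default_cohort
        tr = {t.subject_id: t for t in truths}
        for s in cohort:
            powers = sorted({m.power for m in s.measurements
                             if m.protocol == "bout10"})
            steps = np.diff(powers)
            assert (steps <= 22.0 + 1e-9).all()
            p_max = tr[s.subject_id].vo2max_power
            assert powers[0] == pytest.approx(0.30 * p_max, abs=0.5)
            assert powers[-1] == pytest.approx(0.95 * p_max, abs=0.5)

    def test_both_windows_recorded_per_bout(self, default_cohort):
        cohort, _ = default_cohort
        s = cohort.subjects[0]
        bouts = [m for m in s.measurements if m.protocol == "bout10"]
        powers = {m.power for m in bouts}
        assert len(bouts) == 2 * len(powers)

    def test_lactate_crosses_criterion_near_true_threshold(self):
        cohort, truths = simulate_cohort(_noise_free())
        from aodkit import lactate_threshold_power
        for s, t in zip(cohort, truths):
            pts = sorted((m.power, m.lactate) for m in s.measurements
                         if m.protocol == "bout10" and m.lactate is not None)
            est = lactate_threshold_power(pts)
            # bout grid spacing bounds the interpolation error
            assert est == pytest.approx(t.lt_power, abs=5.0)

    def test_pooled_drift_matches_generator_construction(self):
        cohort, truths = simulate_cohort(_noise_free())
        tr = {t.subject_id: t for t in truths}
        diffs_below, diffs_above = [], []
        for s in cohort:
            t = tr[s.subject_id]
            bouts = {}
            for m in s.measurements:
                if m.protocol == "bout10":
                    bouts.setdefault(m.power, {})[
                        "late" if m.is_late_window else "early"] = m.vo2
            for P, w in bouts.items():
                d = w["late"] - w["early"]
                (diffs_below if P < t.lt_power else diffs_above).append(d)
        from aodkit import pooled_drift
        pooled = pooled_drift([(np.mean(diffs_below), len(diffs_below)),
                               (np.mean(diffs_above), len(diffs_above))])
        direct = np.mean(diffs_below + diffs_above)
        assert pooled == pytest.approx(direct, rel=1e-12)
        # the two regimes reproduce the small-below / large-above structure
        assert 0 < np.mean(diffs_below) < np.mean(diffs_above)
        assert np.mean(diffs_below) == pytest.approx(0.026, abs=0.02)
        assert np.mean(diffs_above) == pytest.approx(0.113, abs=0.05)

    def test_truths_json_round_trip(self, tmp_path, default_cohort):
        _, truths = default_cohort
        path = tmp_path / "truths.json"
        truths_to_json(truths, path)
        assert truths_from_json(path) == truths

    def test_csv_byte_identical_for_fixed_seed(self, tmp_path):
        for name in ("a.csv", "b.csv"):
            cohort, _ = simulate_cohort(GeneratorConfig(seed=123))
            write_measurements(cohort, tmp_path / name, header_comment="x")
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()
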