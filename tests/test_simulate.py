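"""Generator tests: behavior rules, latent AR-BEKK dynamics, cohort assembly."""

import numpy as np
import pytest

from gcsdn.behavior import behavioral_profile
from gcsdn.simulate import (
    CONSERVATIVE,
    INCREMENTALIST,
    STRATEGIST,
    CohortDesign,
    GroupDesign,
    NetworkSpec,
    ScanParams,
    StrategySpec,
    default_cohort_design,
    simulate_bargaining_behavior,
    simulate_cohort,
    simulate_subject,
    simulate_var_bekk,
)

from .conftest import scalar_network


class TestBargainingBehavior:
    def test_identity_rule_recovers_unit_slope(self):
        """noise_sd=0, slope=1, intercept=0 makes suggestion == value."""
        spec = StrategySpec("incrementalist", ir_mean=1.0, ir_sd=0.0, noise_sd=0.0,
                            intercept_rule=lambda s: 0.0)
        trials = simulate_bargaining_behavior(spec, 60, seed=0)
        assert all(t.suggestion == t.value for t in trials)
        prof = behavioral_profile(trials, last_n=30)
        assert prof.ir == pytest.approx(1.0)
        assert prof.r2 == pytest.approx(1.0)

    def test_constant_suggestions_give_zero_slope_and_zero_r2(self):
        """A conservative sending a constant price has IR 0 and R^2 0 by the
        constant-response convention."""
        spec = StrategySpec("conservative", ir_mean=0.0, ir_sd=0.0, noise_sd=0.0,
                            intercept_rule=lambda s: 2.0)
        trials = simulate_bargaining_behavior(spec, 60, seed=1)
        assert len({t.suggestion for t in trials}) == 1
        prof = behavioral_profile(trials, last_n=30)
        assert prof.ir == pytest.approx(0.0)
        assert prof.r2 == 0.0

    def test_strategist_fits_negative_ir(self):
        trials = simulate_bargaining_behavior(STRATEGIST, 60, seed=3)
        prof = behavioral_profile(trials, last_n=30)
        assert prof.ir < 0

    @pytest.mark.parametrize("spec", [CONSERVATIVE, INCREMENTALIST, STRATEGIST])
    def test_fitted_ir_distribution_recovers_planted_slope(self, spec):
        """Mean fitted IR over 200 subjects lies within 2 SEs of ir_mean."""
        irs = np.array([
            behavioral_profile(simulate_bargaining_behavior(spec, 60, seed=s), 30).ir
            for s in range(200)
        ])
        se = irs.std(ddof=1) / np.sqrt(len(irs))
        assert abs(irs.mean() - spec.ir_mean) < 2 * se + 0.03

    def test_trial_invariants(self):
        trials = simulate_bargaining_behavior(INCREMENTALIST, 60, seed=9)
        for t in trials:
            assert 1 <= t.value <= 10 and 1 <= t.suggestion <= 10
            assert t.onset_s < t.choice_s <= t.keypress_s
            assert 4.0 <= t.iti_s <= 6.0
        onsets = [t.onset_s for t in trials]
        assert onsets == sorted(onsets)

    def test_rejects_nonpositive_trial_count(self):
        with pytest.raises(ValueError):
            simulate_bargaining_behavior(CONSERVATIVE, 0, seed=0)


class TestVarBekk:
    def test_zero_var_coeffs_reduce_to_constant_variance_ar(self):
        """With no variance coupling, squared AR residuals are uncorrelated
        with the lagged squared signal."""
        net = scalar_network(a=0.5, b=0.0, c=1.0)
        x = simulate_var_bekk(net, 20000, seed=0)[:, 0]
        resid = x[1:] - 0.5 * x[:-1]
        r = np.corrcoef(resid[1:] ** 2, x[1:-1] ** 2)[0, 1]
        assert abs(r) < 0.03

    def test_scalar_stationary_variance_closed_form(self):
        """Long-run variance matches c^2 / (1 - a^2 - b^2) = 1.695 for the
        canonical scalar case (a=0.5, b=0.4, c=1)."""
        net = scalar_network(0.5, 0.4, 1.0)
        x = simulate_var_bekk(net, 10**6, seed=123)[:, 0]
        assert x.var() == pytest.approx(1.0 / (1.0 - 0.41), rel=0.02)

    @pytest.mark.parametrize("a,b", [(0.3, 0.3), (0.6, 0.5), (0.0, 0.8)])
    def test_stationary_variance_on_grid(self, a, b):
        net = scalar_network(a, b, 1.0)
        x = simulate_var_bekk(net, 200000, seed=17)[:, 0]
        expect = 1.0 / (1.0 - a * a - b * b)
        # 3 Monte-Carlo SEs, conservatively via batch means
        batches = x.reshape(40, -1).var(axis=1)
        se = batches.std(ddof=1) / np.sqrt(len(batches))
        assert abs(x.var() - expect) < 3 * se + 0.02 * expect

    def test_variance_only_edge_couples_squared_residuals(self):
        """Planted y -> x edge in the variance only: squared AR residuals of x
        correlate with the lagged squared driver."""
        net = NetworkSpec(
            regions=("x", "y"),
            self_coeffs={"x": 0.5, "y": 0.5},
            var_coeffs={("x", "x"): 0.2, ("y", "y"): 0.2, ("y", "x"): 0.5},
            base_noise={"x": 1.0, "y": 1.0},
        )
        xy = simulate_var_bekk(net, 20000, seed=5)
        x, y = xy[:, 0], xy[:, 1]
        a_hat = np.polyfit(x[:-1], x[1:], 1)[0]
        resid = x[1:] - a_hat * x[:-1]
        r = np.corrcoef(resid**2, y[:-1] ** 2)[0, 1]
        assert r > 0.05

    def test_nonstationary_spec_refused_with_region_name(self):
        with pytest.raises(ValueError, match="region x"):
            NetworkSpec(regions=("x",), self_coeffs={"x": 0.9},
                        var_coeffs={("x", "x"): 0.7}, base_noise={"x": 1.0})

    def test_determinism(self):
        net = scalar_network()
        a = simulate_var_bekk(net, 500, seed=7)
        b = simulate_var_bekk(net, 500, seed=7)
        assert np.array_equal(a, b)


class TestSubjectAndCohort:
    def test_series_structure_and_finiteness(self, strategist_subject):
        s = strategist_subject
        assert s.series.shape[1] == 5
        assert np.all(np.isfinite(s.series))
        # covers the whole task plus trailing window
        assert (s.n_scans - 1) * s.tr_s >= s.trials[-1].keypress_s

    def test_baseline_offset_dominates(self, strategist_subject):
        assert strategist_subject.series.mean() == pytest.approx(100.0, abs=5.0)

    def test_subject_determinism(self):
        net = scalar_network()
        kw = dict(scan_params=ScanParams(), seed=21, subject_id="S9")
        s1 = simulate_subject(CONSERVATIVE, net, **kw)
        s2 = simulate_subject(CONSERVATIVE, net, **kw)
        assert np.array_equal(s1.series, s2.series)
        assert s1.trials == s2.trials

    def test_default_design_sizes(self):
        design = default_cohort_design()
        assert design.n_subjects == 76
        assert [g.n_subjects for g in design.groups] == [28, 32, 16]

    def test_small_cohort_groups_and_determinism(self):
        design = default_cohort_design()
        small = CohortDesign(groups=tuple(
            GroupDesign(g.spec, g.net, 1, g.scan_params) for g in design.groups
        ))
        c1 = simulate_cohort(small, seed=3)
        c2 = simulate_cohort(small, seed=3)
        assert [s.group_truth for s in c1] == [
            "conservative", "incrementalist", "strategist"
        ]
        assert all(np.array_equal(a.series, b.series) for a, b in zip(c1, c2))

    def test_empty_design_rejected(self):
        with pytest.raises(ValueError):
            CohortDesign(groups=())
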