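"""AR-BEKK likelihood, fitting and causality-statistic tests."""

import math

import numpy as np
import pytest

from gcsdn.arbekk import (
    ARBEKKParams,
    causality,
    connectivity_matrix,
    direction_order,
    fit_ar_bekk,
    granger_constant_variance_test,
    nll_ar_bekk,
    surrogate_driver,
)
from gcsdn.preprocess import events_from_trials, remove_evoked_and_detrend, segment_trials
from gcsdn.simulate import simulate_var_bekk

from .conftest import pair_network, scalar_network

LOG_2PI = math.log(2.0 * math.pi)


class TestNLL:
    def test_hand_computed_four_point_segment(self):
        """X=[1,2,1,0], a=0.5, b=0.5, c=1: three conditional terms evaluated
        by independent arithmetic."""
        params = ARBEKKParams(mean_self=(0.5,), var_coeffs=(0.5,), base_noise=1.0)
        # t=1: r = 2 - 0.5*1 = 1.5, H = 1 + 0.25
        # t=2: r = 1 - 0.5*2 = 0.0, H = 1 + 1.0
        # t=3: r = 0 - 0.5*1 = -0.5, H = 1 + 0.25
        expected = 0.5 * (
            (LOG_2PI + math.log(1.25) + 1.5**2 / 1.25)
            + (LOG_2PI + math.log(2.0) + 0.0)
            + (LOG_2PI + math.log(1.25) + 0.25 / 1.25)
        )
        value = nll_ar_bekk(params, [np.array([1.0, 2.0, 1.0, 0.0])])
        assert value == pytest.approx(expected, abs=1e-12)

    def test_reduces_to_gaussian_ar_likelihood_when_b_zero(self, bekk_series_2000):
        """With var_coeffs pinned to zero the objective equals the
        constant-variance Gaussian AR log-likelihood."""
        x = bekk_series_2000[:500]
        a, c = 0.4, 1.3
        params = ARBEKKParams(mean_self=(a,), var_coeffs=(0.0,), base_noise=c)
        resid = x[1:] - a * x[:-1]
        expected = 0.5 * np.sum(LOG_2PI + math.log(c * c) + resid**2 / (c * c))
        assert nll_ar_bekk(params, [x]) == pytest.approx(expected, rel=1e-12)

    def test_additivity_over_segments(self, bekk_series_2000):
        params = ARBEKKParams(mean_self=(0.5,), var_coeffs=(0.4,), base_noise=1.0)
        seg = bekk_series_2000[:100]
        one = nll_ar_bekk(params, [seg])
        two = nll_ar_bekk(params, [seg, seg])
        assert two == pytest.approx(2 * one, rel=1e-12)

    def test_driver_variance_term_matches_manual_sum(self):
        """Full-model H uses (b1*X + b2*Y)^2, the 2x1-B BEKK form."""
        x = np.array([0.3, -0.2, 0.5, 0.1])
        y = np.array([1.0, -1.0, 0.5, 0.0])
        params = ARBEKKParams(
            mean_self=(0.2,), mean_driver=(0.3,), var_coeffs=(0.4, -0.6), base_noise=0.9
        )
        manual = 0.0
        for t in range(1, 4):
            r = x[t] - 0.2 * x[t - 1] - 0.3 * y[t - 1]
            h = 0.81 + (0.4 * x[t - 1] - 0.6 * y[t - 1]) ** 2
            manual += 0.5 * (LOG_2PI + math.log(h) + r * r / h)
        assert nll_ar_bekk(params, [x], [y]) == pytest.approx(manual, rel=1e-12)


class TestFit:
    def test_parameter_recovery_scalar_case(self):
        """a=0.5, b=0.4, c=1, single T=2000 segment: parameters recovered
        within 0.05 on average over seeds."""
        errs = []
        for s in range(12):
            x = simulate_var_bekk(scalar_network(), 2000, seed=s)[:, 0]
            p = fit_ar_bekk([x], include_driver=False, seed=s).params
            errs.append([
                abs(p.mean_self[0] - 0.5),
                abs(p.var_coeffs[0] - 0.4),
                abs(p.base_noise - 1.0),
            ])
        assert np.all(np.mean(errs, axis=0) <= 0.05)

    def test_null_variance_coupling_estimates_near_zero(self):
        net = scalar_network(a=0.5, b=0.0, c=1.0)
        bs = [
            abs(fit_ar_bekk(
                [simulate_var_bekk(net, 2000, seed=s)[:, 0]],
                include_driver=False, seed=s,
            ).params.var_coeffs[0])
            for s in range(10)
        ]
        assert np.mean(bs) < 0.08

    def test_reduction_equivalence_with_ols(self, bekk_series_2000):
        """With weak/no variance coupling the fitted mean coefficient is close
        to the OLS AR estimate."""
        net = scalar_network(a=0.6, b=0.0, c=1.0)
        x = simulate_var_bekk(net, 3000, seed=2)[:, 0]
        fit = fit_ar_bekk([x], include_driver=False, seed=0)
        a_ols = float(np.linalg.lstsq(x[:-1, None], x[1:], rcond=None)[0][0])
        assert fit.params.mean_self[0] == pytest.approx(a_ols, abs=0.02)

    def test_full_never_worse_than_restricted(self, bekk_series_2000):
        x = bekk_series_2000[:600]
        y = simulate_var_bekk(scalar_network(), 600, seed=77)[:, 0]
        r = fit_ar_bekk([x], include_driver=False, seed=1)
        res = causality([x], [y], seed=1, fit_restricted=r)
        tol = 1e-6 * abs(r.neg_log_lik)
        assert res.fit_full.neg_log_lik <= r.neg_log_lik + tol
        assert res.f_raw >= -1e-6

    def test_b1_canonicalized_nonnegative(self, bekk_series_2000):
        fit = fit_ar_bekk([bekk_series_2000], include_driver=False, seed=3)
        assert fit.params.var_coeffs[0] >= 0

    def test_too_short_segments_rejected(self):
        with pytest.raises(ValueError, match="usable"):
            fit_ar_bekk([np.array([1.0, 2.0])], include_driver=False)


class TestCausality:
    def test_null_driver_centered_at_zero(self):
        """Independent driver: mean F over subjects within 2 SE of 0."""
        net = scalar_network(a=0.5, b=0.35, c=1.0)
        fs = []
        for s in range(30):
            x = simulate_var_bekk(net, 300, seed=s)[:, 0]
            y = simulate_var_bekk(net, 300, seed=10_000 + s)[:, 0]
            fs.append(causality([x], [y], seed=s).f)
        fs = np.array(fs)
        se = fs.std(ddof=1) / np.sqrt(len(fs))
        assert abs(fs.mean()) < 2 * se + 0.01

    def test_mean_coupling_detected(self):
        """Planted mean-level influence: F > 0 and LR test significant with
        high power."""
        net = pair_network(d=0.35)
        hits_f = hits_lr = 0
        for s in range(20):
            xy = simulate_var_bekk(net, 500, seed=s)
            res = causality([xy[:, 0]], [xy[:, 1]], seed=s)
            hits_f += res.f > 0
            hits_lr += res.lr_p < 0.05
        assert hits_f >= 16  # >= 80% power
        assert hits_lr >= 16

    def test_variance_only_coupling_beats_classic_granger(self):
        """Driver entering only the variance term: the SDN-aware test detects
        it while the constant-variance Granger test stays near its size."""
        net = pair_network(b_cross=0.25)
        lr_hits = granger_hits = 0
        reps = 25
        for s in range(reps):
            xy = simulate_var_bekk(net, 500, seed=s)
            res = causality([xy[:, 0]], [xy[:, 1]], seed=s, null_correction="none")
            lr_hits += res.lr_p < 0.05
            _, gp = granger_constant_variance_test([xy[:, 0]], [xy[:, 1]])
            granger_hits += gp < 0.05
        assert lr_hits > granger_hits
        assert lr_hits / reps >= 0.4
        assert granger_hits / reps <= 0.2

    def test_surrogate_driver_preserves_lengths_and_values(self):
        segs = [np.arange(4.0), np.arange(4.0) + 10, np.arange(5.0) + 20]
        sur = surrogate_driver(segs, shift=1)
        assert [len(s) for s in sur] == [4, 4, 5]
        # equal-length pair rotated
        assert np.array_equal(sur[0], segs[1])
        assert np.array_equal(sur[1], segs[0])
        # singleton length class time-reversed
        assert np.array_equal(sur[2], segs[2][::-1])


class TestConnectivityMatrix:
    def _segments(self, subject):
        events = events_from_trials(subject.trials)
        resid = remove_evoked_and_detrend(subject.series, events, subject.tr_s)
        return segment_trials(resid, events, subject.tr_s, regions=subject.regions,
                              subject_id=subject.subject_id)

    def test_twenty_entries_no_self_pairs(self, conservative_subject):
        m = connectivity_matrix(self._segments(conservative_subject), seed=0)
        assert len(m.f) == 20
        assert all(d != t for d, t in m.f)
        assert set(m.f) == set(direction_order(conservative_subject.regions))

    def test_independent_regions_give_small_f(self, conservative_subject):
        """All-null network: the 20 F values scatter around zero."""
        m = connectivity_matrix(self._segments(conservative_subject), seed=0)
        v = m.as_vector()
        assert np.all(np.isfinite(v))
        assert abs(np.mean(v)) < 0.05
        assert np.max(np.abs(v)) < 0.5
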