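"""Evoked removal, Fourier basis and trial segmentation tests."""

import numpy as np
import pytest

from gcsdn.preprocess import (
    EventTrainSet,
    build_event_design,
    events_from_trials,
    fourier_hrf_basis,
    remove_evoked_and_detrend,
    segment_trials,
)


class TestFourierBasis:
    def test_shape_fourth_order(self):
        basis = fourier_hrf_basis(order=4, window_s=32.0, tr_s=2.0)
        assert basis.shape == (16, 9)

    def test_untapered_columns_orthogonal(self):
        n = 16
        frac = np.arange(n) / n
        cols = [np.ones(n)]
        for k in range(1, 2):
            cols.append(np.sin(2 * np.pi * k * frac))
            cols.append(np.cos(2 * np.pi * k * frac))
        raw = np.column_stack(cols)
        gram = raw.T @ raw
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-10

    def test_impulse_convolution_reproduces_shifted_column(self):
        basis = fourier_hrf_basis(order=2, window_s=16.0, tr_s=2.0)
        train = np.zeros(30)
        train[7] = 1.0
        for j in range(basis.shape[1]):
            conv = np.convolve(train, basis[:, j])[:30]
            assert np.allclose(conv[7 : 7 + basis.shape[0]], basis[:, j])

    def test_rejects_bad_window(self):
        with pytest.raises(ValueError):
            fourier_hrf_basis(order=4, window_s=1.0, tr_s=2.0)


class TestEvokedRemoval:
    def _events(self):
        return EventTrainSet(
            trial_onset=(4.0, 20.0, 40.0),
            choice=(10.0, 28.0, 46.0),
            key_press=(10.4, 28.4, 46.4),
        )

    def test_design_span_annihilated(self):
        """A series lying exactly in the design span leaves zero residual."""
        events = self._events()
        basis = fourier_hrf_basis(4, 32.0, 2.0)
        design = build_event_design(events, 40, 2.0, basis)
        rng = np.random.default_rng(0)
        series = design @ rng.normal(size=(design.shape[1], 3))
        resid = remove_evoked_and_detrend(series, events, 2.0, basis)
        assert np.max(np.abs(resid)) < 1e-8

    def test_residual_orthogonal_to_design(self):
        events = self._events()
        basis = fourier_hrf_basis(4, 32.0, 2.0)
        rng = np.random.default_rng(1)
        series = rng.normal(size=(40, 2)) + 50.0
        resid = remove_evoked_and_detrend(series, events, 2.0, basis)
        design = build_event_design(events, 40, 2.0, basis)
        inner = design.T @ resid
        assert np.max(np.abs(inner)) < 1e-8 * np.linalg.norm(series)

    def test_linear_ramp_removed(self):
        events = self._events()
        t = np.arange(40, dtype=float)
        series = (5.0 + 0.3 * t)[:, None]
        resid = remove_evoked_and_detrend(series, events, 2.0)
        assert np.max(np.abs(resid)) < 1e-8

    def test_evoked_variance_reduced_on_synthetic_subject(self, strategist_subject):
        """Projection removes >99% of the variance the event design explains."""
        s = strategist_subject
        events = events_from_trials(s.trials)
        basis = fourier_hrf_basis(4, 32.0, s.tr_s)
        design = build_event_design(events, s.n_scans, s.tr_s, basis)

        def explained(x):
            beta, *_ = np.linalg.lstsq(design, x, rcond=None)
            fit = design @ beta
            return float(np.sum(fit**2))

        resid = remove_evoked_and_detrend(s.series, events, s.tr_s, basis)
        before = explained(s.series - s.series.mean(axis=0))
        after = explained(resid)
        assert after < 0.01 * before


class TestSegmentation:
    def test_enumeration_convention(self):
        """Onset 10 s, choice 16 s, TR 2 s keeps scans at 10, 12, 14, 16 s."""
        events = EventTrainSet(trial_onset=(10.0,), choice=(16.0,), key_press=(16.2,))
        resid = np.arange(40, dtype=float)[:, None]
        segs = segment_trials(resid, events, tr_s=2.0)
        seg = segs.segments[0]
        assert (seg.scan_start, seg.scan_stop) == (5, 8)
        assert seg.n_scans == 4

    def test_segments_demeaned(self, conservative_subject):
        s = conservative_subject
        events = events_from_trials(s.trials)
        resid = remove_evoked_and_detrend(s.series, events, s.tr_s)
        segs = segment_trials(resid, events, s.tr_s, regions=s.regions)
        for seg in segs.usable():
            assert np.max(np.abs(seg.data.mean(axis=0))) < 1e-12

    def test_partition_no_scan_in_two_segments(self, conservative_subject):
        s = conservative_subject
        events = events_from_trials(s.trials)
        resid = remove_evoked_and_detrend(s.series, events, s.tr_s)
        segs = segment_trials(resid, events, s.tr_s)
        seen = set()
        for seg in segs.segments:
            idx = set(range(seg.scan_start, seg.scan_stop + 1))
            assert not idx & seen
            seen |= idx

    def test_short_segments_flagged_not_dropped(self):
        events = EventTrainSet(trial_onset=(10.0, 30.0), choice=(12.0, 40.0),
                               key_press=(12.2, 40.2))
        resid = np.random.default_rng(0).normal(size=(40, 1))
        segs = segment_trials(resid, events, tr_s=2.0, min_len=3)
        assert len(segs.segments) == 2
        assert not segs.segments[0].usable  # 2 scans only
        assert segs.segments[1].usable

    def test_choice_before_onset_names_trial(self):
        events = EventTrainSet.__new__(EventTrainSet)
        object.__setattr__(events, "trial_onset", (10.0,))
        object.__setattr__(events, "choice", (8.0,))
        object.__setattr__(events, "key_press", (10.5,))
        resid = np.zeros((20, 1))
        with pytest.raises(ValueError, match="trial 1"):
            segment_trials(resid, events, tr_s=2.0)

    def test_usable_scan_count_near_study_comparator(self, conservative_subject):
        """Late-game segmentation yields on the order of 127 usable scans."""
        s = conservative_subject
        events = events_from_trials(s.trials[-30:])
        resid = remove_evoked_and_detrend(
            s.series, events_from_trials(s.trials), s.tr_s
        )
        segs = segment_trials(resid, events, s.tr_s)
        assert 90 <= segs.n_usable_scans() <= 165
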