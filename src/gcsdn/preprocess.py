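"""Event-evoked removal, detrending and per-trial segmentation of ROI series.

The causal analysis must not be driven by the task-evoked dynamic common to
all regions, so each event train (trial onset, choice, key press) is convolved
with a flexible Fourier HRF basis and projected out, together with a linear
trend.  The residual series is then cut into per-trial segments (onset to
choice, inter-trial scans excluded) and each segment demeaned per region —
these segments are the unit of causal inference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "EventTrainSet",
    "TrialSegment",
    "TrialSegmentSet",
    "fourier_hrf_basis",
    "remove_evoked_and_detrend",
    "segment_trials",
    "events_from_trials",
]

EVENT_TYPES = ("trial_onset", "choice", "key_press")


@dataclass(frozen=True)
class EventTrainSet:
    """Event times in seconds per event type, strictly increasing."""

    trial_onset: tuple[float, ...]
    choice: tuple[float, ...]
    key_press: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        for name in EVENT_TYPES:
            times = getattr(self, name)
            arr = np.asarray(times, dtype=float)
            if arr.size and arr.min() < 0:
                raise ValueError(f"{name} times must be nonnegative")
            if arr.size > 1 and not np.all(np.diff(arr) > 0):
                raise ValueError(f"{name} times must be strictly increasing")

    def as_dict(self) -> dict[str, tuple[float, ...]]:
        return {name: getattr(self, name) for name in EVENT_TYPES}


def events_from_trials(trials) -> EventTrainSet:
    """Build an EventTrainSet from a list of BargainTrial."""
    return EventTrainSet(
        trial_onset=tuple(t.onset_s for t in trials),
        choice=tuple(t.choice_s for t in trials),
        key_press=tuple(t.keypress_s for t in trials),
    )


def fourier_hrf_basis(order: int = 4, window_s: float = 32.0, tr_s: float = 2.0) -> np.ndarray:
    """Fourier HRF basis set: constant plus sine/cosine pairs, Hanning-tapered.

    Returns a ``(window_s / tr_s) x (2 * order + 1)`` matrix sampled at the TR.
    Before tapering, the columns are mutually orthogonal on the sample grid
    (exact Fourier modes on n points for harmonics up to order <= n/2).
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    if window_s <= tr_s:
        raise ValueError("window must exceed one TR")
    n = int(round(window_s / tr_s))
    frac = np.arange(n) / n  # t / window on the sample grid
    cols = [np.ones(n)]
    for k in range(1, order + 1):
        cols.append(np.sin(2 * np.pi * k * frac))
        cols.append(np.cos(2 * np.pi * k * frac))
    basis = np.column_stack(cols)
    taper = np.hanning(n)
    return basis * taper[:, None]


def _impulse_train(times, n_scans: int, tr_s: float) -> np.ndarray:
    train = np.zeros(n_scans)
    for t_s in times:
        i = int(round(t_s / tr_s))
        if 0 <= i < n_scans:
            train[i] += 1.0
    return train


def build_event_design(
    events: EventTrainSet, n_scans: int, tr_s: float, basis: np.ndarray
) -> np.ndarray:
    """One regressor per (event type x basis column), by impulse-train
    convolution, plus intercept and linear trend (last two columns)."""
    cols = []
    for name in EVENT_TYPES:
        times = getattr(events, name)
        if not times:
            continue
        train = _impulse_train(times, n_scans, tr_s)
        for j in range(basis.shape[1]):
            cols.append(np.convolve(train, basis[:, j])[:n_scans])
    cols.append(np.ones(n_scans))
    t = np.arange(n_scans, dtype=float)
    cols.append((t - t.mean()) / max(t.std(), 1.0))
    return np.column_stack(cols)


def remove_evoked_and_detrend(
    series: np.ndarray,
    events: EventTrainSet,
    tr_s: float = 2.0,
    basis: np.ndarray | None = None,
) -> np.ndarray:
    """Project the event design (all event types x basis columns), a linear
    trend and an intercept out of every region by least squares.

    Head-motion regressors are deliberately not included.  A rank-deficient
    design is handled by the minimum-norm solution; dependent columns are
    reported with a warning.  Residuals are orthogonal to the design span.
    """
    series = np.atleast_2d(np.asarray(series, dtype=float))
    if series.shape[0] < series.shape[1]:
        raise ValueError("series must be (n_scans, n_regions) with n_scans >= n_regions")
    n_scans = series.shape[0]
    if basis is None:
        basis = fourier_hrf_basis(order=4, window_s=32.0, tr_s=tr_s)
    design = build_event_design(events, n_scans, tr_s, basis)
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        logger.warning(
            "event design is rank deficient (%d of %d columns); dependent "
            "columns are absorbed by the minimum-norm fit", rank, design.shape[1]
        )
    beta, *_ = np.linalg.lstsq(design, series, rcond=None)
    return series - design @ beta


@dataclass(frozen=True)
class TrialSegment:
    """Per-trial demeaned residual matrix (scans x regions) with provenance."""

    trial_index: int
    scan_start: int  # first scan index (inclusive)
    scan_stop: int  # last scan index (inclusive)
    data: np.ndarray
    usable: bool

    @property
    def n_scans(self) -> int:
        return int(self.data.shape[0])


@dataclass(frozen=True)
class TrialSegmentSet:
    """Ordered, non-overlapping per-trial segments for one subject."""

    segments: tuple[TrialSegment, ...]
    regions: tuple[str, ...] = ()
    subject_id: str = ""

    def usable(self) -> tuple[TrialSegment, ...]:
        return tuple(s for s in self.segments if s.usable)

    def region_arrays(self, region: str) -> list[np.ndarray]:
        """Usable single-region segment series, in trial order."""
        i = self.regions.index(region)
        return [s.data[:, i] for s in self.usable()]

    def n_usable_scans(self) -> int:
        return sum(s.n_scans for s in self.usable())


def segment_trials(
    residual: np.ndarray,
    events: EventTrainSet,
    tr_s: float = 2.0,
    min_len: int = 3,
    regions: tuple[str, ...] = (),
    subject_id: str = "",
) -> TrialSegmentSet:
    """Cut the residual series into onset-to-choice trial segments.

    Scan ``i`` occurs at ``t = i * tr_s``; a trial keeps scans with
    ``onset_s <= t <= choice_s`` (inclusive at both ends) and is demeaned per
    region.  Segments shorter than ``min_len`` scans are flagged unusable, not
    dropped.
    """
    residual = np.atleast_2d(np.asarray(residual, dtype=float))
    n_scans = residual.shape[0]
    onsets = events.trial_onset
    choices = events.choice
    if len(onsets) != len(choices):
        raise ValueError("onset and choice trains must have equal length")
    segments: list[TrialSegment] = []
    for k, (on, ch) in enumerate(zip(onsets, choices), start=1):
        if ch < on:
            raise ValueError(f"trial {k}: choice time {ch} precedes onset {on}")
        i0 = int(np.ceil(on / tr_s - 1e-9))
        i1 = int(np.floor(ch / tr_s + 1e-9))
        i0 = max(i0, 0)
        i1 = min(i1, n_scans - 1)
        if i1 < i0:
            segments.append(
                TrialSegment(k, i0, i0 - 1, np.empty((0, residual.shape[1])), usable=False)
            )
            continue
        seg = residual[i0 : i1 + 1].copy()
        seg -= seg.mean(axis=0, keepdims=True)
        segments.append(TrialSegment(k, i0, i1, seg, usable=seg.shape[0] >= min_len))
    return TrialSegmentSet(tuple(segments), regions=tuple(regions), subject_id=subject_id)
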