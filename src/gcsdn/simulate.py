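"""Synthetic cohorts for the two-person bargaining task.

Generates buyers with known strategy groups (conservative / incrementalist /
strategist), self-paced trial event trains, and ROI BOLD-like series whose
latent dynamics follow a vector autoregression with signal-dependent noise
(a BEKK-style conditional-variance recursion).  Every downstream stage of the
package is testable against the ground truth stored in these records.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np

__all__ = [
    "StrategySpec",
    "BargainTrial",
    "NetworkSpec",
    "ScanParams",
    "SubjectRecord",
    "GroupDesign",
    "CohortDesign",
    "simulate_bargaining_behavior",
    "simulate_var_bekk",
    "simulate_subject",
    "simulate_cohort",
    "double_gamma_hrf",
    "default_cohort_design",
    "DEFAULT_REGIONS",
    "CONSERVATIVE",
    "INCREMENTALIST",
    "STRATEGIST",
]

DEFAULT_REGIONS: tuple[str, ...] = ("rPFC", "DLPFC", "RSC", "dACC", "MPC")

#: Directed edges boosted in the strategist group's latent network.  These are
#: the directions whose group difference the end-to-end analysis should flag.
STRATEGIST_BOOSTED_EDGES: tuple[tuple[str, str], ...] = (
    ("RSC", "rPFC"),
    ("dACC", "rPFC"),
    ("DLPFC", "rPFC"),
)


def _midscale_intercept(slope: float) -> float:
    """Intercept keeping the mean suggestion at mid-scale (5.5) for any slope."""
    return 5.5 * (1.0 - slope)


def _low_anchor_intercept(slope: float) -> float:
    """Intercept anchoring suggestions near the low end of the price scale."""
    return 2.0


@dataclass(frozen=True)
class StrategySpec:
    """Behavioral parameters of one buyer strategy group.

    ``ir_mean``/``ir_sd`` are the mean and between-subject SD of the slope of
    the suggestion-on-value rule (the information-revelation coefficient);
    ``noise_sd`` is the within-subject suggestion noise in price units.
    """

    name: str
    ir_mean: float
    ir_sd: float
    noise_sd: float
    intercept_rule: Callable[[float], float] = _midscale_intercept

    def __post_init__(self) -> None:
        if self.name not in ("conservative", "incrementalist", "strategist"):
            raise ValueError(f"unknown strategy name {self.name!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.name == "strategist" and not self.ir_mean < 0:
            raise ValueError("strategist ir_mean must be negative")
        if self.name == "conservative" and abs(self.ir_mean) > 0.2:
            raise ValueError("conservative |ir_mean| must be <= 0.2")
        if self.name == "incrementalist" and not self.ir_mean > 0:
            raise ValueError("incrementalist ir_mean must be positive")


# Group-level defaults.  The slope distributions use the reported group
# statistics of the study population; the suggestion-noise SDs are set so the
# suggestion-on-value regression attains the reported group-level R^2 given
# uniform integer values 1-10 (Var = 8.25).
CONSERVATIVE = StrategySpec(
    "conservative", ir_mean=0.13, ir_sd=0.23, noise_sd=0.66,
    intercept_rule=_low_anchor_intercept,
)
INCREMENTALIST = StrategySpec("incrementalist", ir_mean=0.57, ir_sd=0.18, noise_sd=0.82)
STRATEGIST = StrategySpec("strategist", ir_mean=-0.68, ir_sd=0.21, noise_sd=1.80)


@dataclass(frozen=True)
class BargainTrial:
    """One bargaining round: private value, suggested price, event times."""

    index: int
    value: int
    suggestion: int
    onset_s: float
    choice_s: float
    keypress_s: float
    iti_s: float

    def __post_init__(self) -> None:
        if not 1 <= self.value <= 10:
            raise ValueError("value must be in 1..10")
        if not 1 <= self.suggestion <= 10:
            raise ValueError("suggestion must be in 1..10")
        if not self.onset_s < self.choice_s <= self.keypress_s:
            raise ValueError("require onset < choice <= keypress")
        if not 4.0 <= self.iti_s <= 6.0:
            raise ValueError("iti must lie in [4, 6] s")


@dataclass(frozen=True)
class NetworkSpec:
    """Latent directed-network parameters for the AR-BEKK generator.

    ``mean_coeffs[(driver, target)]`` is the lag-1 influence of the driver on
    the target's conditional mean; ``self_coeffs[region]`` the autoregressive
    coefficient; ``var_coeffs[(driver, target)]`` the lag-1 influence entering
    the target's conditional *standard deviation* term; ``base_noise[region]``
    the constant noise scale; ``baseline_offset`` a positive scanner-units
    offset added to emitted series.
    """

    regions: tuple[str, ...] = DEFAULT_REGIONS
    mean_coeffs: Mapping[tuple[str, str], float] = field(default_factory=dict)
    self_coeffs: Mapping[str, float] = field(default_factory=dict)
    var_coeffs: Mapping[tuple[str, str], float] = field(default_factory=dict)
    base_noise: Mapping[str, float] = field(default_factory=dict)
    baseline_offset: float = 100.0

    def __post_init__(self) -> None:
        if self.baseline_offset <= 0:
            raise ValueError("baseline_offset must be positive")
        for r in self.regions:
            c = self.base_noise.get(r, 1.0)
            if c <= 0:
                raise ValueError(f"base_noise must be positive for region {r}")
            a = self.self_coeffs.get(r, 0.0)
            b = self.var_coeffs.get((r, r), 0.0)
            if a * a + b * b >= 1.0:
                raise ValueError(
                    f"non-stationary marginal for region {r}: "
                    f"self^2 + own-var^2 = {a * a + b * b:.3f} >= 1"
                )
        known = set(self.regions)
        for d, t in list(self.mean_coeffs) + list(self.var_coeffs):
            if d not in known or t not in known:
                raise ValueError(f"edge ({d}, {t}) names an unknown region")

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    def mean_matrix(self) -> np.ndarray:
        """Lag-1 mean transition matrix A, A[target, driver]."""
        k = self.n_regions
        a = np.zeros((k, k))
        idx = {r: i for i, r in enumerate(self.regions)}
        for r in self.regions:
            a[idx[r], idx[r]] = self.self_coeffs.get(r, 0.0)
        for (d, t), v in self.mean_coeffs.items():
            a[idx[t], idx[d]] += v
        return a

    def var_matrix(self) -> np.ndarray:
        """Lag-1 variance-coupling matrix B, B[target, driver]."""
        k = self.n_regions
        b = np.zeros((k, k))
        idx = {r: i for i, r in enumerate(self.regions)}
        for (d, t), v in self.var_coeffs.items():
            b[idx[t], idx[d]] += v
        return b

    def base_noise_vector(self) -> np.ndarray:
        return np.array([self.base_noise.get(r, 1.0) for r in self.regions])


def simulate_bargaining_behavior(
    spec: StrategySpec, n_trials: int = 60, seed: int | np.random.SeedSequence = 0
) -> list[BargainTrial]:
    """Simulate one buyer's 60-round bargaining record.

    Private values are uniform integers 1-10.  The suggested price follows
    ``round(intercept + slope * value + noise)`` clipped to 1-10, with the
    subject's slope drawn from the group's ``(ir_mean, ir_sd)``.  Trials are
    self-paced: decisions take 10-16 s early in the game, settling to 6-9 s
    (three to four scans at TR = 2 s) in the stable last half, with
    inter-trial intervals uniform on [4, 6] s.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    slope = rng.normal(spec.ir_mean, spec.ir_sd)
    intercept = spec.intercept_rule(slope)
    values = rng.integers(1, 11, size=n_trials)
    noise = rng.normal(0.0, spec.noise_sd, size=n_trials) if spec.noise_sd > 0 else np.zeros(n_trials)
    suggestions = np.clip(np.rint(intercept + slope * values + noise), 1, 10).astype(int)

    trials: list[BargainTrial] = []
    t = float(rng.uniform(4.0, 6.0))  # lead-in before the first onset
    half = n_trials // 2
    for i in range(n_trials):
        lo, hi = (10.0, 16.0) if i < half else (6.0, 9.0)
        rt = float(rng.uniform(lo, hi))
        onset = t
        choice = onset + rt
        keypress = choice + float(rng.uniform(0.1, 0.5))
        iti = float(rng.uniform(4.0, 6.0))
        trials.append(
            BargainTrial(
                index=i + 1,
                value=int(values[i]),
                suggestion=int(suggestions[i]),
                onset_s=onset,
                choice_s=choice,
                keypress_s=keypress,
                iti_s=iti,
            )
        )
        t = keypress + iti
    return trials


def simulate_var_bekk(
    net: NetworkSpec,
    n_steps: int,
    seed: int | np.random.SeedSequence = 0,
    burn_in: int = 200,
) -> np.ndarray:
    """Simulate the latent vector AR process with signal-dependent noise.

    Each region's next value is its own-lag mean term plus incoming mean-level
    terms plus noise whose conditional SD is
    ``sqrt(base^2 + (sum of lagged values via var_coeffs)^2)``.  The process
    starts at zero and a burn-in of ``burn_in`` steps is discarded.

    Returns an ``(n_steps, n_regions)`` array.
    """
    if n_steps < 10:
        raise ValueError("n_steps must be >= 10")
    a = net.mean_matrix()
    b = net.var_matrix()
    c2 = net.base_noise_vector() ** 2
    k = net.n_regions
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal((burn_in + n_steps, k))
    out = np.empty((burn_in + n_steps, k))
    x = np.zeros(k)
    for t in range(burn_in + n_steps):
        s = b @ x
        sd = np.sqrt(c2 + s * s)
        x = a @ x + sd * eps[t]
        out[t] = x
    return out[burn_in:]


def double_gamma_hrf(tr_s: float = 2.0, duration_s: float = 32.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response sampled at the TR.

    Peak at ~6 s with an undershoot at ~16 s (1/6 amplitude), normalized to a
    unit peak.  Deliberately different in shape from the Fourier basis the
    preprocessing stage uses for removal.
    """
    t = np.arange(0.0, duration_s, tr_s)
    from scipy.stats import gamma as _gamma

    h = _gamma.pdf(t, a=6, scale=1.0) - _gamma.pdf(t, a=16, scale=1.0) / 6.0
    peak = h.max()
    return h / peak if peak > 0 else h


@dataclass(frozen=True)
class ScanParams:
    """Acquisition and evoked-response settings for the BOLD emitter.

    ``evoked_amplitudes`` maps each event type to per-region response
    amplitudes in scanner units (a scalar broadcasts over regions);
    ``amplitude_cv`` is the between-subject coefficient of variation of those
    amplitudes.  Defaults put evoked responses at ~2% of a baseline of 100,
    a realistic BOLD effect size.
    """

    tr_s: float = 2.0
    evoked_amplitudes: Mapping[str, float | Sequence[float]] = field(
        default_factory=lambda: {"trial_onset": 2.0, "choice": 2.0, "key_press": 1.0}
    )
    amplitude_cv: float = 0.15
    hrf_duration_s: float = 32.0
    post_window_s: float = 16.0
    burn_in: int = 200


@dataclass
class SubjectRecord:
    """One buyer: ROI series, event log, behavior, and ground truth."""

    subject_id: str
    group_truth: str
    trials: list[BargainTrial]
    series: np.ndarray  # (n_scans, n_regions), scanner units
    network_truth: NetworkSpec
    rng_seed: int
    tr_s: float = 2.0

    @property
    def regions(self) -> tuple[str, ...]:
        return self.network_truth.regions

    @property
    def n_scans(self) -> int:
        return int(self.series.shape[0])

    def event_times(self) -> dict[str, list[float]]:
        return {
            "trial_onset": [tr.onset_s for tr in self.trials],
            "choice": [tr.choice_s for tr in self.trials],
            "key_press": [tr.keypress_s for tr in self.trials],
        }


def _amplitude_vector(spec_amp, k: int) -> np.ndarray:
    arr = np.asarray(spec_amp, dtype=float)
    if arr.ndim == 0:
        return np.full(k, float(arr))
    if arr.shape != (k,):
        raise ValueError(f"evoked amplitude must be scalar or length {k}")
    return arr


def simulate_subject(
    spec: StrategySpec,
    net: NetworkSpec,
    scan_params: ScanParams = ScanParams(),
    seed: int = 0,
    n_trials: int = 60,
    subject_id: str = "S000",
) -> SubjectRecord:
    """Simulate one buyer end to end.

    The emitted series is ``baseline_offset + evoked + latent``: event trains
    (onset, choice, key press) are placed on the scan grid, convolved with a
    canonical double-gamma HRF and scaled by per-region amplitudes with
    between-subject jitter; the latent component follows the AR-BEKK network.
    """
    ss = np.random.SeedSequence(seed)
    beh_ss, net_ss, amp_ss = ss.spawn(3)
    trials = simulate_bargaining_behavior(spec, n_trials, seed=beh_ss)

    tr = scan_params.tr_s
    duration = trials[-1].keypress_s + scan_params.post_window_s
    n_scans = int(math.ceil(duration / tr)) + 1

    latent = simulate_var_bekk(net, n_scans, seed=net_ss, burn_in=scan_params.burn_in)

    k = net.n_regions
    hrf = double_gamma_hrf(tr, scan_params.hrf_duration_s)
    amp_rng = np.random.default_rng(amp_ss)
    evoked = np.zeros((n_scans, k))
    events = {
        "trial_onset": [t.onset_s for t in trials],
        "choice": [t.choice_s for t in trials],
        "key_press": [t.keypress_s for t in trials],
    }
    for ev_type, times in events.items():
        base_amp = _amplitude_vector(scan_params.evoked_amplitudes.get(ev_type, 0.0), k)
        jitter = amp_rng.normal(1.0, scan_params.amplitude_cv, size=k) if scan_params.amplitude_cv > 0 else np.ones(k)
        amp = base_amp * np.clip(jitter, 0.1, None)
        train = np.zeros(n_scans)
        for t_s in times:
            i = int(round(t_s / tr))
            if i >= n_scans:
                raise ValueError("scan budget shorter than task events")
            train[i] += 1.0
        conv = np.convolve(train, hrf)[:n_scans]
        evoked += conv[:, None] * amp[None, :]

    series = net.baseline_offset + evoked + latent
    if not np.all(np.isfinite(series)):
        raise FloatingPointError("non-finite values in emitted series")
    return SubjectRecord(
        subject_id=subject_id,
        group_truth=spec.name,
        trials=trials,
        series=series,
        network_truth=net,
        rng_seed=seed,
        tr_s=tr,
    )


@dataclass(frozen=True)
class GroupDesign:
    """One strategy group's cohort slice: behavior spec, network, size."""

    spec: StrategySpec
    net: NetworkSpec
    n_subjects: int
    scan_params: ScanParams = ScanParams()


@dataclass(frozen=True)
class CohortDesign:
    groups: tuple[GroupDesign, ...]

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("cohort design must contain at least one group")
        for g in self.groups:
            if g.n_subjects < 1:
                raise ValueError("each group needs at least one subject")

    @property
    def n_subjects(self) -> int:
        return sum(g.n_subjects for g in self.groups)


def _base_network() -> NetworkSpec:
    """Shared latent network: moderate autoregression, own-signal SDN, and a
    few weak directed edges common to all groups.

    The shared edges deliberately avoid rPFC: rPFC is the target of the
    strategist-specific edges, so any shared edge out of it would propagate
    group differences into otherwise group-invariant regions.
    """
    regions = DEFAULT_REGIONS
    return NetworkSpec(
        regions=regions,
        self_coeffs={r: 0.5 for r in regions},
        var_coeffs={(r, r): 0.35 for r in regions},
        base_noise={r: 1.0 for r in regions},
        mean_coeffs={
            ("DLPFC", "RSC"): 0.12,
            ("MPC", "dACC"): 0.10,
            ("dACC", "MPC"): 0.12,
            ("RSC", "MPC"): 0.10,
        },
        baseline_offset=100.0,
    )


def strategist_network(boost: float = 0.6) -> NetworkSpec:
    """The strategist latent network: the shared base plus boosted mean-level
    edges RSC->rPFC, dACC->rPFC and DLPFC->rPFC."""
    base = _base_network()
    mean = dict(base.mean_coeffs)
    for edge in STRATEGIST_BOOSTED_EDGES:
        mean[edge] = mean.get(edge, 0.0) + boost
    return replace(base, mean_coeffs=mean)


#: Choice-locked response amplitudes per group, region order
#: (rPFC, DLPFC, RSC, dACC, MPC).  Strategists respond more in rPFC, DLPFC
#: and RSC and less in MPC; incrementalists more in dACC and MPC.  The
#: contrasts are kept small (<= 0.3 scanner units on a ~2-unit response):
#: group-different evoked responses survive the evoked-removal step as a
#: group-different common signal across regions, and large contrasts would
#: confound the directed-connectivity comparison.
_CHOICE_AMPLITUDES = {
    "conservative": (2.0, 2.0, 2.0, 2.0, 2.0),
    "incrementalist": (2.0, 2.0, 2.0, 2.3, 2.3),
    "strategist": (2.3, 2.3, 2.15, 2.0, 1.85),
}


def _scan_params_for(group: str) -> ScanParams:
    """Per-group acquisition settings: a group-specific choice-locked
    activation profile on top of shared onset/key-press responses."""
    amp = {
        "trial_onset": 2.0,
        "choice": _CHOICE_AMPLITUDES[group],
        "key_press": 1.0,
    }
    return ScanParams(evoked_amplitudes=amp)


def default_cohort_design(strategist_boost: float = 0.6) -> CohortDesign:
    """The study-sized cohort: 28 conservatives, 32 incrementalists and 16
    strategists, sharing a base network; strategists add boosted edges into
    rPFC and a stronger choice-evoked response in rPFC/DLPFC."""
    base = _base_network()
    return CohortDesign(
        groups=(
            GroupDesign(CONSERVATIVE, base, 28, _scan_params_for("conservative")),
            GroupDesign(INCREMENTALIST, base, 32, _scan_params_for("incrementalist")),
            GroupDesign(STRATEGIST, strategist_network(strategist_boost), 16,
                        _scan_params_for("strategist")),
        )
    )


def simulate_cohort(design: CohortDesign, seed: int = 0, n_trials: int = 60) -> list[SubjectRecord]:
    """Simulate a full cohort; per-subject seeds derive deterministically from
    the cohort seed."""
    ss = np.random.SeedSequence(seed)
    n = design.n_subjects
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]
    subjects: list[SubjectRecord] = []
    i = 0
    for g in design.groups:
        for _ in range(g.n_subjects):
            subjects.append(
                simulate_subject(
                    g.spec,
                    g.net,
                    g.scan_params,
                    seed=child_seeds[i],
                    n_trials=n_trials,
                    subject_id=f"S{i + 1:03d}",
                )
            )
            i += 1
    return subjects
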