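"""Group-level inference on directed connectivity.

Per directed connection: a one-sample t-test collapsed over strategy groups,
direction-wise outlier exclusion within each group (the causality estimates
are noisy at ~127 usable scans per subject), a three-group one-way ANOVA with
Bonferroni correction over the 20 directions, Welch post-hoc comparisons, and
Pearson correlations of connectivity strength with the behavioral indices
(IR and R^2).  Also computes the per-ROI activation index used as the
baseline neural feature: the median over late trials of the choice-scan to
onset-scan signal ratio on the raw (positive-baseline) series.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .arbekk import CausalityMatrix, direction_order
from .behavior import BehavioralProfile
from .preprocess import EventTrainSet

logger = logging.getLogger(__name__)

__all__ = [
    "ActivationIndex",
    "DirectionStats",
    "activation_index",
    "exclude_outliers",
    "direction_tests",
]


@dataclass(frozen=True)
class ActivationIndex:
    """Per-ROI activation: median over analyzed trials of the choice/onset
    signal ratio (dimensionless, ~1 for no evoked response)."""

    subject_id: str
    values: dict[str, float]  # region -> median ratio


def activation_index(
    series: np.ndarray,
    events: EventTrainSet,
    regions: Sequence[str],
    tr_s: float = 2.0,
    last_n: int = 30,
    subject_id: str = "",
) -> ActivationIndex:
    """Choice-to-onset signal ratio, median over the last ``last_n`` trials.

    Operates on the raw positive-baseline series (before residualization).
    Each trial contributes the signal at the scan nearest the choice time
    divided by the signal at the scan nearest the onset; trials whose onset
    scan is non-positive are skipped with a warning.
    """
    series = np.atleast_2d(np.asarray(series, dtype=float))
    n_scans = series.shape[0]
    onsets = events.trial_onset[-last_n:]
    choices = events.choice[-last_n:]
    ratios: dict[str, list[float]] = {r: [] for r in regions}
    for on, ch in zip(onsets, choices):
        i_on = min(max(int(round(on / tr_s)), 0), n_scans - 1)
        i_ch = min(max(int(round(ch / tr_s)), 0), n_scans - 1)
        onset_vals = series[i_on]
        if np.any(onset_vals <= 0):
            logger.warning("%s: non-positive onset-scan signal, trial skipped", subject_id)
            continue
        for j, r in enumerate(regions):
            ratios[r].append(float(series[i_ch, j] / onset_vals[j]))
    values = {
        r: float(np.median(v)) if v else math.nan for r, v in ratios.items()
    }
    return ActivationIndex(subject_id, values)


def exclude_outliers(values: np.ndarray, z: float = 2.7) -> np.ndarray:
    """Single-pass inclusion mask: keep values within ``mean +/- z * SD``.

    The +/-2.7 SD band covers ~99.3% of a normal distribution, so on-model
    estimates are rarely touched while gross fit failures are removed.  NaNs
    are excluded.  Groups smaller than 3 are returned unmasked (no basis for
    an SD).
    """
    values = np.asarray(values, dtype=float)
    finite = np.isfinite(values)
    if finite.sum() < 3:
        return finite
    m = values[finite].mean()
    sd = values[finite].std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        return finite
    return finite & (np.abs(values - m) <= z * sd)


@dataclass(frozen=True)
class DirectionStats:
    """All group-level statistics for one directed connection."""

    direction: tuple[str, str]  # (driver, target)
    group_means: dict[str, float]  # after exclusion
    anova_p: float
    posthoc_p: dict[tuple[str, str], float]  # Welch t, per group pair
    one_sample_t: float
    one_sample_p: float
    pearson_r_ir: float
    pearson_p_ir: float
    pearson_r_r2: float
    pearson_p_r2: float
    n_excluded: dict[str, int]
    significant: bool  # ANOVA p below the Bonferroni threshold
    flagged: bool = False  # too few usable values


def direction_tests(
    matrices: Sequence[CausalityMatrix],
    group_labels: Sequence[str],
    profiles: Sequence[BehavioralProfile],
    alpha: float = 0.05,
    outlier_z: float = 2.7,
) -> list[DirectionStats]:
    """Per-direction inference across the cohort.

    For each of the 20 directions: one-sample t-test against zero over all
    subjects (collapsed over groups, before exclusion, following the analysis
    order); within-group +/-``outlier_z`` SD exclusion; group means; one-way
    ANOVA over the strategy groups; pairwise Welch post-hoc t-tests; Pearson
    correlation of F with IR and with R^2 over retained subjects.  A
    direction is significant when its ANOVA p-value falls below
    ``alpha / n_directions`` (Bonferroni over the 20 directions).
    """
    if not (len(matrices) == len(group_labels) == len(profiles)):
        raise ValueError("matrices, labels and profiles must align")
    regions = matrices[0].regions
    directions = direction_order(regions)
    n_dir = len(directions)
    threshold = alpha / n_dir
    groups = sorted(set(group_labels))
    labels = np.array(group_labels)
    ir = np.array([p.ir for p in profiles])
    r2 = np.array([p.r2 for p in profiles])

    out: list[DirectionStats] = []
    for d in directions:
        f = np.array([m.f[d] for m in matrices])
        finite = np.isfinite(f)
        t1, p1 = (math.nan, math.nan)
        if finite.sum() >= 3:
            t1, p1 = stats.ttest_1samp(f[finite], 0.0)
        keep = np.zeros(len(f), dtype=bool)
        n_excl: dict[str, int] = {}
        for g in groups:
            gi = labels == g
            mask = exclude_outliers(f[gi], z=outlier_z)
            keep[gi] = mask
            n_excl[g] = int(gi.sum() - mask.sum())
        samples = [f[(labels == g) & keep] for g in groups]
        flagged = any(len(s) < 2 for s in samples)
        gmeans = {
            g: float(s.mean()) if len(s) else math.nan for g, s in zip(groups, samples)
        }
        if flagged:
            anova_p = math.nan
            posthoc: dict[tuple[str, str], float] = {}
        else:
            _, anova_p = stats.f_oneway(*samples)
            posthoc = {}
            for i in range(len(groups)):
                for j in range(i + 1, len(groups)):
                    _, pp = stats.ttest_ind(samples[i], samples[j], equal_var=False)
                    posthoc[(groups[i], groups[j])] = float(pp)
        r_ir = p_ir = r_r2 = p_r2 = math.nan
        if keep.sum() >= 3:
            r_ir, p_ir = stats.pearsonr(f[keep], ir[keep])
            r_r2, p_r2 = stats.pearsonr(f[keep], r2[keep])
        out.append(
            DirectionStats(
                direction=d,
                group_means=gmeans,
                anova_p=float(anova_p) if np.isfinite(anova_p) else math.nan,
                posthoc_p=posthoc,
                one_sample_t=float(t1),
                one_sample_p=float(p1),
                pearson_r_ir=float(r_ir),
                pearson_p_ir=float(p_ir),
                pearson_r_r2=float(r_r2),
                pearson_p_r2=float(p_r2),
                n_excluded=n_excl,
                significant=bool(np.isfinite(anova_p) and anova_p < threshold),
                flagged=flagged,
            )
        )
    return out
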