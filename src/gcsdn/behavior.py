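"""Behavioral strategy profiling and clustering.

Each buyer's bargaining record reduces to two numbers: the information
revelation coefficient (IR) — the OLS slope of the suggested price on the
item's private value over the stable late phase of the game — and the R^2 of
that regression.  Buyers cluster into three strategy groups in (IR, R^2)
space: strategists (negative IR, high fit: systematic inversion of the
truth), incrementalists (high positive IR, high fit: truth anchoring) and
conservatives (IR near zero: uninformative suggestions).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

__all__ = ["BehavioralProfile", "behavioral_profile", "cluster_groups", "ClusterReport"]

GROUP_NAMES = ("conservative", "incrementalist", "strategist")


@dataclass(frozen=True)
class BehavioralProfile:
    """One buyer's (IR, R^2) summary over the analysis window."""

    subject_id: str
    ir: float
    r2: float
    trials_used: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.r2 <= 1.0 + 1e-12:
            raise ValueError("r2 must lie in [0, 1]")


def behavioral_profile(trials, last_n: int = 30, subject_id: str = "") -> BehavioralProfile:
    """OLS of suggestion on value over the last ``last_n`` trials.

    Only the late trials enter because behavior stabilizes over the game.  A
    constant suggestion stream (zero variance in the response, hence zero
    variance in the fitted values) is assigned R^2 = 0 by convention, keeping
    the feature space total; zero variance in the *values* leaves the slope
    undefined and raises.
    """
    window = list(trials)[-last_n:]
    if len(window) < 3:
        raise ValueError("need at least 3 trials in the window")
    v = np.array([t.value for t in window], dtype=float)
    s = np.array([t.suggestion for t in window], dtype=float)
    if np.allclose(v.var(), 0.0):
        raise ValueError("zero variance in item values within the window")
    vc = v - v.mean()
    slope = float(vc @ (s - s.mean()) / (vc @ vc))
    if np.allclose(s.var(), 0.0):
        return BehavioralProfile(subject_id, ir=slope, r2=0.0, trials_used=len(window))
    pred = s.mean() + slope * vc
    ss_res = float(np.sum((s - pred) ** 2))
    ss_tot = float(np.sum((s - s.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    return BehavioralProfile(subject_id, ir=slope, r2=max(r2, 0.0), trials_used=len(window))


@dataclass(frozen=True)
class ClusterReport:
    """Cluster assignment with named centroids."""

    labels: tuple[str, ...]  # per profile, in input order
    centroids: dict[str, tuple[float, float]]  # name -> (ir, r2)
    inertia: float


def _name_centroids(centers: np.ndarray) -> dict[int, str]:
    """Map k-means centroids to strategy names.

    Most-negative-IR centroid -> strategist; highest-IR centroid ->
    incrementalist; any remaining -> conservative.  Ties break lexicographic
    on (ir, r2) coordinates (logged).
    """
    k = centers.shape[0]
    order = sorted(range(k), key=lambda i: (centers[i, 0], centers[i, 1]))
    if len(order) != len(set(order)):  # pragma: no cover - defensive
        logger.warning("centroid tie broken lexicographically")
    names: dict[int, str] = {}
    if k == 1:
        names[order[0]] = "conservative"
        return names
    names[order[0]] = "strategist"
    names[order[-1]] = "incrementalist"
    for i in order[1:-1]:
        names[i] = "conservative"
    return names


def cluster_groups(
    profiles: Sequence[BehavioralProfile], k: int = 3, seed: int = 0, n_restarts: int = 50
) -> ClusterReport:
    """K-means on raw (IR, R^2) pairs — no feature scaling, both are order-1.

    ``n_restarts`` seeded initializations are run and the best inertia kept,
    which also makes the labeling invariant to subject order.
    """
    if len(profiles) < k:
        raise ValueError("need at least k profiles")
    x = np.array([[p.ir, p.r2] for p in profiles])
    if np.unique(x, axis=0).shape[0] < k:
        raise ValueError("fewer than k distinct (ir, r2) points")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    idx = km.fit_predict(x)
    names = _name_centroids(km.cluster_centers_)
    labels = tuple(names[i] for i in idx)
    centroids = {
        names[i]: (float(km.cluster_centers_[i, 0]), float(km.cluster_centers_[i, 1]))
        for i in range(k)
    }
    return ClusterReport(labels=labels, centroids=centroids, inertia=float(km.inertia_))
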