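"""End-to-end orchestration: simulate -> preprocess -> SDN -> connectivity ->
behavior -> group statistics -> classification, from one config.

Every stage draws its seed deterministically from the master seed, writes its
table under the output directory, and is skipped on re-run when ``resume`` is
set and its output already exists, so a finished run is reproducible at the
checksum level.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import behavior as beh
from . import classify as clf
from .arbekk import CausalityMatrix, connectivity_matrix, direction_order
from .group_stats import activation_index, direction_tests
from .io import write_subject
from .preprocess import (
    events_from_trials,
    fourier_hrf_basis,
    remove_evoked_and_detrend,
    segment_trials,
)
from .sdn import sdn_test
from .simulate import default_cohort_design, simulate_cohort

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "ResultsBundle", "run_pipeline", "stage_seed"]


@dataclass(frozen=True)
class PipelineConfig:
    """All knobs of one pipeline run."""

    out_dir: str = "gcsdn_run"
    master_seed: int = 0
    # cohort
    n_conservative: int = 28
    n_incrementalist: int = 32
    n_strategist: int = 16
    n_trials: int = 60
    strategist_boost: float = 0.6
    # preprocessing
    basis_order: int = 4
    basis_window_s: float = 32.0
    min_segment_len: int = 3
    # behavior / analysis window (behavior stabilizes over the game, so only
    # the last_n_trials enter the behavioral regression, the activation index
    # and the connectivity segmentation)
    last_n_trials: int = 30
    # model
    p: int = 1
    q: int = 1
    n_restarts: int = 5
    null_correction: str = "surrogate"
    # statistics
    alpha: float = 0.05
    outlier_z: float = 2.7
    # classifier
    svm_cost: float = 10.0
    # bookkeeping
    write_subjects: bool = False
    resume: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")

    @property
    def n_directions(self) -> int:
        return 20  # 5 regions, ordered pairs

    @property
    def per_direction_threshold(self) -> float:
        return self.alpha / self.n_directions

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        return cls(**data)


def stage_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage seed: CRC-32 of the stage name mixed with the master."""
    return (zlib.crc32(stage.encode()) ^ (master_seed * 2654435761)) % (2**31)


@dataclass
class ResultsBundle:
    """Paths of all emitted tables plus the manifest."""

    out_dir: Path
    tables: dict[str, Path]
    manifest: Path

    def checksum(self, name: str) -> str:
        return hashlib.sha256(self.tables[name].read_bytes()).hexdigest()


def _write_tsv(path: Path, header: Sequence[str], rows: Sequence[Sequence]) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(repr(v) if isinstance(v, float) else str(v) for v in row) + "\n")


def run_pipeline(config: PipelineConfig) -> ResultsBundle:
    """Execute every stage in order and return the emitted artifact paths."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables: dict[str, Path] = {}

    # --- simulate -----------------------------------------------------------
    design = default_cohort_design(config.strategist_boost)
    design = dataclasses.replace(
        design,
        groups=tuple(
            dataclasses.replace(g, n_subjects=n)
            for g, n in zip(
                design.groups,
                (config.n_conservative, config.n_incrementalist, config.n_strategist),
            )
        ),
    )
    sim_seed = stage_seed(config.master_seed, "simulate")
    logger.info("simulate: %d subjects, seed %d", design.n_subjects, sim_seed)
    subjects = simulate_cohort(design, seed=sim_seed, n_trials=config.n_trials)
    if config.write_subjects:
        for s in subjects:
            write_subject(s, out / "subjects")

    regions = subjects[0].regions
    basis = fourier_hrf_basis(config.basis_order, config.basis_window_s, subjects[0].tr_s)

    # --- preprocess + activation + SDN + connectivity ----------------------
    conn_path = out / "connectivity.tsv"
    sdn_path = out / "sdn.tsv"
    act_path = out / "activation.tsv"
    matrices: list[CausalityMatrix] = []
    if config.resume and conn_path.exists() and sdn_path.exists() and act_path.exists():
        logger.info("resume: loading cached connectivity from %s", conn_path)
        matrices = _load_connectivity(conn_path, regions, [s.subject_id for s in subjects])
    else:
        sdn_rows = []
        act_rows = []
        conn_rows = []
        conn_seed = stage_seed(config.master_seed, "connectivity")
        for i, s in enumerate(subjects):
            events = events_from_trials(s.trials)
            residual = remove_evoked_and_detrend(s.series, events, s.tr_s, basis)
            # causal inference pools every trial's onset-to-choice segment:
            # the latent networks are stationary over the game, and the noisy
            # per-direction fits need all ~240 usable scans
            segments = segment_trials(
                residual, events, s.tr_s, config.min_segment_len,
                regions=regions, subject_id=s.subject_id,
            )
            res = sdn_test(
                [residual[:, j] for j in range(len(regions))], "ar",
                order=config.p, pooled=True,
            )
            sdn_rows.append(
                (s.subject_id, res.model_kind, res.pairs_used, res.correlation, res.p_value)
            )
            act = activation_index(
                s.series, events, regions, s.tr_s, config.last_n_trials, s.subject_id
            )
            act_rows.append((s.subject_id, *(act.values[r] for r in regions)))
            m = connectivity_matrix(
                segments, p=config.p, q=config.q,
                n_restarts=config.n_restarts, seed=conn_seed + i,
                null_correction=config.null_correction,
            )
            matrices.append(m)
            for d, t in direction_order(regions):
                conn_rows.append((s.subject_id, d, t, m.f[(d, t)], m.converged[(d, t)]))
        _write_tsv(sdn_path, ["subject", "model", "pairs_used", "correlation", "p_value"], sdn_rows)
        _write_tsv(act_path, ["subject", *regions], act_rows)
        _write_tsv(conn_path, ["subject", "driver", "target", "F", "converged"], conn_rows)
    tables["sdn"] = sdn_path
    tables["activation"] = act_path
    tables["connectivity"] = conn_path

    # --- behavior -----------------------------------------------------------
    profiles = [
        beh.behavioral_profile(s.trials, config.last_n_trials, s.subject_id)
        for s in subjects
    ]
    report = beh.cluster_groups(
        profiles, k=3, seed=stage_seed(config.master_seed, "cluster")
    )
    beh_path = out / "behavior.tsv"
    _write_tsv(
        beh_path,
        ["subject", "ir", "r2", "cluster", "group_truth"],
        [
            (p.subject_id, p.ir, p.r2, lab, s.group_truth)
            for p, lab, s in zip(profiles, report.labels, subjects)
        ],
    )
    tables["behavior"] = beh_path

    # --- group statistics ---------------------------------------------------
    labels = list(report.labels)
    dstats = direction_tests(
        matrices, labels, profiles, alpha=config.alpha, outlier_z=config.outlier_z
    )
    groups = sorted(set(labels))
    stats_path = out / "direction_stats.tsv"
    _write_tsv(
        stats_path,
        ["driver", "target", *(f"mean_{g}" for g in groups), "anova_p",
         "one_sample_p", "pearson_r_ir", "pearson_p_ir", "pearson_r_r2",
         "pearson_p_r2", "significant"],
        [
            (d.direction[0], d.direction[1],
             *(d.group_means.get(g, float("nan")) for g in groups),
             d.anova_p, d.one_sample_p, d.pearson_r_ir, d.pearson_p_ir,
             d.pearson_r_r2, d.pearson_p_r2, d.significant)
            for d in dstats
        ],
    )
    tables["direction_stats"] = stats_path

    # --- classification -----------------------------------------------------
    acts = [
        activation_index(
            s.series, events_from_trials(s.trials), regions, s.tr_s,
            config.last_n_trials, s.subject_id,
        )
        for s in subjects
    ]
    y = [1 if lab == "strategist" else 0 for lab in labels]
    feature_sets = clf.build_feature_sets(acts, matrices, regions)
    reports = {
        kind: clf.loo_svm(fs, y, cost=config.svm_cost)
        for kind, fs in feature_sets.items()
    }
    base = reports["activation5"]
    comb = reports["combined25"]
    comb.nri, comb.nri_z, comb.nri_p = clf.nri(base.probabilities, comb.probabilities, y)
    comb.idi, comb.idi_z, comb.idi_p = clf.idi(base.probabilities, comb.probabilities, y)
    clf_path = out / "classification.json"
    with open(clf_path, "w", newline="\n") as fh:
        json.dump(
            {
                kind: {
                    "accuracy": r.accuracy,
                    "auc": r.auc,
                    "nri": r.nri, "nri_p": r.nri_p,
                    "idi": r.idi, "idi_p": r.idi_p,
                }
                for kind, r in reports.items()
            },
            fh, indent=1, sort_keys=True, allow_nan=True,
        )
        fh.write("\n")
    tables["classification"] = clf_path

    # --- manifest -----------------------------------------------------------
    manifest_path = out / "manifest.json"
    manifest = {
        "config": dataclasses.asdict(config),
        "per_direction_threshold": config.per_direction_threshold,
        "n_subjects": len(subjects),
        "checksums": {
            name: hashlib.sha256(path.read_bytes()).hexdigest()
            for name, path in sorted(tables.items())
        },
    }
    import numpy as _np
    manifest["versions"] = {"numpy": _np.__version__}
    with open(manifest_path, "w", newline="\n") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return ResultsBundle(out_dir=out, tables=tables, manifest=manifest_path)


def _load_connectivity(
    path: Path, regions: tuple[str, ...], subject_ids: list[str]
) -> list[CausalityMatrix]:
    rows = [ln.split("\t") for ln in path.read_text().strip().split("\n")[1:]]
    by_subject: dict[str, dict] = {sid: {"f": {}, "conv": {}} for sid in subject_ids}
    for sid, d, t, f, conv in rows:
        by_subject[sid]["f"][(d, t)] = float(f)
        by_subject[sid]["conv"][(d, t)] = conv == "True"
    return [
        CausalityMatrix(sid, regions, by_subject[sid]["f"], by_subject[sid]["conv"])
        for sid in subject_ids
    ]
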