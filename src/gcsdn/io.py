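"""TSV/JSON serialization of subjects and results.

Series are written as TSV with a ``time_s`` column plus one column per ROI;
events as TSV with one row per trial; subject metadata (ground-truth group,
network, seed) as a JSON sidecar.  Floats are serialized with full round-trip
precision so a write-then-read is the identity and re-runs are
checksum-stable.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .simulate import BargainTrial, NetworkSpec, SubjectRecord

__all__ = ["write_subject", "read_subject"]

_EVENT_COLUMNS = ["trial", "onset_s", "choice_s", "keypress_s", "value", "suggestion", "iti_s"]


def _fmt(x: float) -> str:
    return repr(float(x))


def _network_to_json(net: NetworkSpec) -> dict:
    return {
        "regions": list(net.regions),
        "mean_coeffs": [[d, t, v] for (d, t), v in sorted(net.mean_coeffs.items())],
        "self_coeffs": {r: v for r, v in sorted(net.self_coeffs.items())},
        "var_coeffs": [[d, t, v] for (d, t), v in sorted(net.var_coeffs.items())],
        "base_noise": {r: v for r, v in sorted(net.base_noise.items())},
        "baseline_offset": net.baseline_offset,
    }


def _network_from_json(obj: dict) -> NetworkSpec:
    return NetworkSpec(
        regions=tuple(obj["regions"]),
        mean_coeffs={(d, t): v for d, t, v in obj["mean_coeffs"]},
        self_coeffs=dict(obj["self_coeffs"]),
        var_coeffs={(d, t): v for d, t, v in obj["var_coeffs"]},
        base_noise=dict(obj["base_noise"]),
        baseline_offset=obj["baseline_offset"],
    )


def write_subject(record: SubjectRecord, directory: str | Path) -> dict[str, Path]:
    """Write one subject's series, events and metadata; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sid = record.subject_id
    series_path = directory / f"{sid}_series.tsv"
    events_path = directory / f"{sid}_events.tsv"
    meta_path = directory / f"{sid}_meta.json"

    regions = record.regions
    with open(series_path, "w", newline="\n") as fh:
        fh.write("time_s\t" + "\t".join(regions) + "\n")
        for i, row in enumerate(record.series):
            fh.write("\t".join([_fmt(i * record.tr_s)] + [_fmt(v) for v in row]) + "\n")

    with open(events_path, "w", newline="\n") as fh:
        fh.write("\t".join(_EVENT_COLUMNS) + "\n")
        for t in record.trials:
            fh.write(
                "\t".join(
                    [
                        str(t.index),
                        _fmt(t.onset_s),
                        _fmt(t.choice_s),
                        _fmt(t.keypress_s),
                        str(t.value),
                        str(t.suggestion),
                        _fmt(t.iti_s),
                    ]
                )
                + "\n"
            )

    meta = {
        "subject_id": sid,
        "group_truth": record.group_truth,
        "rng_seed": record.rng_seed,
        "tr_s": record.tr_s,
        "network_truth": _network_to_json(record.network_truth),
    }
    with open(meta_path, "w", newline="\n") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return {"series": series_path, "events": events_path, "meta": meta_path}


class SubjectParseError(ValueError):
    """Malformed subject file, with file and line context."""


def _read_table(path: Path, required: list[str]) -> tuple[list[str], list[list[str]]]:
    text = path.read_text()
    lines = [ln for ln in text.replace("\r\n", "\n").replace("\r", "\n").split("\n") if ln]
    header = lines[0].split("\t")
    for col in required:
        if col not in header:
            raise SubjectParseError(f"{path}: missing required column {col!r} (line 1)")
    rows = []
    for i, ln in enumerate(lines[1:], start=2):
        parts = ln.split("\t")
        if len(parts) != len(header):
            raise SubjectParseError(f"{path}: wrong field count at line {i}")
        rows.append(parts)
    return header, rows


def read_subject(directory: str | Path, subject_id: str) -> SubjectRecord:
    """Read a subject written by :func:`write_subject` (identity round-trip)."""
    directory = Path(directory)
    series_path = directory / f"{subject_id}_series.tsv"
    events_path = directory / f"{subject_id}_events.tsv"
    meta_path = directory / f"{subject_id}_meta.json"
    meta = json.loads(meta_path.read_text())
    net = _network_from_json(meta["network_truth"])

    header, rows = _read_table(series_path, ["time_s"] + list(net.regions))
    col = {name: header.index(name) for name in header}
    series = np.array(
        [[float(r[col[region]]) for region in net.regions] for r in rows]
    )

    _, ev_rows = _read_table(events_path, _EVENT_COLUMNS)
    trials = []
    for i, r in enumerate(ev_rows, start=2):
        try:
            trials.append(
                BargainTrial(
                    index=int(r[0]),
                    onset_s=float(r[1]),
                    choice_s=float(r[2]),
                    keypress_s=float(r[3]),
                    value=int(r[4]),
                    suggestion=int(r[5]),
                    iti_s=float(r[6]),
                )
            )
        except ValueError as exc:
            raise SubjectParseError(f"{events_path}: line {i}: {exc}") from exc

    return SubjectRecord(
        subject_id=meta["subject_id"],
        group_truth=meta["group_truth"],
        trials=trials,
        series=series,
        network_truth=net,
        rng_seed=meta["rng_seed"],
        tr_s=meta["tr_s"],
    )
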