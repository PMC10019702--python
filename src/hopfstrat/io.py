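"""Plain-text I/O: TSV matrices with JSON sidecars, record CSVs, manifests."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .fitting import MonteCarloRecord, SubtypeSolution
from .oscillator import ModelParameters, StateTrajectory
from .signals import FCMatrix, RegionalTimeSeries

__all__ = [
    "write_timeseries", "read_timeseries",
    "write_fc", "read_fc",
    "write_records", "read_records",
    "write_solution", "write_trajectory",
]


def _labels(n: int) -> list[str]:
    return [f"region_{i:03d}" for i in range(n)]


def _write_matrix(path: Path, values: np.ndarray, row_labels: list[str]) -> None:
    with path.open("w") as fh:
        for label, row in zip(row_labels, values):
            fh.write(label + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


def _read_matrix(path: Path) -> tuple[np.ndarray, list[str]]:
    labels, rows = [], []
    with path.open() as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            labels.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    return np.asarray(rows, dtype=float), labels


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_timeseries(ts: RegionalTimeSeries, path: str | Path) -> None:
    path = Path(path)
    _write_matrix(path, ts.values, _labels(ts.n_regions))
    _sidecar(path).write_text(json.dumps(
        {"sample_interval": ts.sample_interval, "subject_id": ts.subject_id}))


def read_timeseries(path: str | Path) -> RegionalTimeSeries:
    path = Path(path)
    values, _ = _read_matrix(path)
    meta = json.loads(_sidecar(path).read_text())
    return RegionalTimeSeries(values, meta["sample_interval"], meta.get("subject_id"))


def write_fc(fc: FCMatrix, path: str | Path) -> None:
    path = Path(path)
    _write_matrix(path, fc.values, _labels(fc.n_regions))
    _sidecar(path).write_text(json.dumps(
        {"space": fc.space, "provenance": fc.provenance}, default=str))


def read_fc(path: str | Path) -> FCMatrix:
    path = Path(path)
    values, _ = _read_matrix(path)
    meta = json.loads(_sidecar(path).read_text())
    return FCMatrix(values, meta["space"], meta.get("provenance") or {})


def write_trajectory(traj: StateTrajectory, prefix: str | Path) -> None:
    """Region-by-time TSVs for Re{z}, Im{z} and omega, plus a JSON sidecar."""
    prefix = Path(prefix)
    labels = _labels(traj.z.shape[0])
    _write_matrix(prefix.with_suffix(".real.tsv"), traj.z.real, labels)
    _write_matrix(prefix.with_suffix(".imag.tsv"), traj.z.imag, labels)
    _write_matrix(prefix.with_suffix(".omega.tsv"), traj.omega, labels)
    meta = {"sample_interval": traj.sample_interval,
            "times": traj.times.tolist(),
            "params": traj.params.as_tuple() if traj.params else None}
    prefix.with_suffix(".json").write_text(json.dumps(meta))


def write_records(records: Sequence[MonteCarloRecord], path: str | Path) -> None:
    rows = [
        {"iteration": r.iteration, "threshold": r.threshold,
         "A": r.best_params.A, "G": r.best_params.G,
         "F": r.best_params.F, "M": r.best_params.M,
         "similarity": r.best_similarity,
         "selected_subjects": ";".join(r.selected_subjects)}
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_records(path: str | Path, beta: float = 0.02) -> list[MonteCarloRecord]:
    df = pd.read_csv(path)
    return [
        MonteCarloRecord(
            iteration=int(r.iteration), threshold=float(r.threshold),
            selected_subjects=str(r.selected_subjects).split(";"),
            best_params=ModelParameters(r.A, r.G, r.F, r.M, beta),
            best_similarity=float(r.similarity))
        for r in df.itertuples()
    ]


def write_solution(solution: SubtypeSolution, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {
        "params_dep1": solution.params_dep1.as_tuple(),
        "params_dep2": solution.params_dep2.as_tuple(),
        "metastability": {"DEP1": solution.metastability_dep1,
                          "DEP2": solution.metastability_dep2},
        "synchrony": {"DEP1": solution.synchrony_dep1,
                      "DEP2": solution.synchrony_dep2},
        "mode_counts": solution.mode_counts,
        "label_rule": solution.label_rule,
    }
    (out_dir / "subtype_solution.json").write_text(json.dumps(payload, indent=2))
    write_fc(solution.fc_dep1, out_dir / "fc_dep1.tsv")
    write_fc(solution.fc_dep2, out_dir / "fc_dep2.tsv")
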