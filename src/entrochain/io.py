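"""Delimited-text readers/writers and run configuration.

Matrix files are CSV/TSV with flattened state labels in the first row and
first column; trajectories are CSV with day/macro/micro columns; numeric
series are single-column CSV with an optional timestamp column.  All readers
validate shape eagerly and report the offending row, so silently truncated
files fail loudly.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import MatrixParseError


def _sniff_delimiter(path) -> str:
    text = Path(path).read_text()
    return "\t" if "\t" in text.splitlines()[0] else ","


def read_matrix_csv(path):
    """Read a labelled square matrix; returns (flat_labels, raw ndarray).

    Tolerant of surrounding whitespace; rejects non-square layouts, ragged
    rows and label disagreements with row/column context in the message.
    """
    path = Path(path)
    delim = _sniff_delimiter(path)
    with path.open(newline="") as fh:
        rows = [[c.strip() for c in r] for r in csv.reader(fh, delimiter=delim)
                if any(c.strip() for c in r)]
    if len(rows) < 2:
        raise MatrixParseError(f"{path}: no data rows")
    header = rows[0][1:]
    n = len(header)
    labels, data = [], []
    for ln, row in enumerate(rows[1:], start=2):
        if len(row) != n + 1:
            raise MatrixParseError(
                f"{path}: line {ln} has {len(row) - 1} values, expected {n}"
            )
        labels.append(row[0])
        try:
            data.append([float(c) for c in row[1:]])
        except ValueError as e:
            raise MatrixParseError(f"{path}: line {ln}: {e}") from None
    if len(labels) != n:
        raise MatrixParseError(
            f"{path}: {len(labels)} rows for {n} columns (matrix must be square)"
        )
    if labels != header:
        raise MatrixParseError(f"{path}: row labels differ from column labels")
    return tuple(labels), np.asarray(data, dtype=float)


def write_matrix_csv(path, labels, P, decimals: int = 6, delimiter=","):
    path = Path(path)
    P = np.asarray(P)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter)
        w.writerow(["state", *labels])
        for lab, row in zip(labels, P):
            w.writerow([lab, *[f"{v:.{decimals}f}" for v in row]])


def read_trajectory_csv(path):
    """Trajectory CSV with columns day, macro, micro (extra columns kept)."""
    df = pd.read_csv(path)
    missing = {"day", "macro", "micro"} - set(df.columns)
    if missing:
        raise MatrixParseError(f"{path}: missing column(s) {sorted(missing)}")
    from .simulate import Trajectory

    return Trajectory.from_frame(df)


def write_trajectory_csv(path, traj, start_date=None):
    traj.to_frame(start_date=start_date).to_csv(path, index=False)


def read_series_csv(path, column=None):
    """Single numeric or symbol column; optional timestamp column is ignored."""
    df = pd.read_csv(path)
    if column is None:
        candidates = [c for c in df.columns
                      if c.lower() not in ("date", "timestamp", "time", "day")]
        if not candidates:
            raise MatrixParseError(f"{path}: no data column found")
        column = candidates[0]
    return df[column].to_numpy()


def write_json_report(path, payload: dict, config=None, seed=None):
    """Canonical machine-readable output: payload + provenance envelope."""
    from . import __version__

    record = {
        "package": "entrochain",
        "version": __version__,
        "seed": seed,
        "config": asdict(config) if isinstance(config, RunConfig) else config,
        **payload,
    }
    Path(path).write_text(json.dumps(record, indent=2, sort_keys=True,
                                     default=_json_default) + "\n")
    return record


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        v = float(o)
        return v if np.isfinite(v) else None
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


@dataclass
class RunConfig:
    """Reproducible-run settings shared by the CLI subcommands."""

    seed: int = 0
    T_values: tuple = (15, 30, 90)
    step: int = 1
    n_windows: int = 200
    pseudo_count: float = 0.0
    aggregate: str = "windows"
    method: str = "cusum"
    threshold: float | None = None
    alpha: float = 0.05
    n_permutations: int = 1000
    mixing_epsilon: float = 0.25
    out_dir: str = "."
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        self.T_values = tuple(int(t) for t in self.T_values)
        if any(t < 2 for t in self.T_values):
            raise ValueError("all T values must be >= 2")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {k: v for k, v in data.items() if k in known}
        extras = {k: v for k, v in data.items() if k not in known}
        cfg = cls(**kwargs)
        cfg.extras.update(extras)
        return cfg
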