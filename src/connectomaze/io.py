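"""Delimited-text interfaces for every pipeline table.

All writers emit a header comment line naming the producing stage, a hash of
the resolved configuration and the seed, so any output file can be traced to
the run that made it.  Readers skip comment lines, recover metadata (e.g.
the sampling interval of a time-series file) and fail loudly on malformed
input with the offending line number.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from dataclasses import asdict, is_dataclass
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .behavior import TrialLog, TrialRecord
from .catfish import CellRecord
from .connectome import BrainGraph, ConnectivityMatrix
from .types import NuisanceSet, RoiTimeSeriesSet

__all__ = [
    "ParseError", "config_hash",
    "write_timeseries", "read_timeseries",
    "write_confounds", "read_confounds",
    "write_matrix", "read_matrix",
    "write_edge_list",
    "write_trial_log", "read_trial_log",
    "write_cell_table", "read_cell_table",
    "write_table", "read_table",
]

SEP = "\t"


class ParseError(ValueError):
    """Malformed input file; message names the file and line."""


def config_hash(config: Any) -> str:
    """Short stable hash of a configuration object (dataclass or mapping)."""
    if is_dataclass(config) and not isinstance(config, type):
        config = asdict(config)
    payload = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _header(stage: str, seed: int | None = None, cfg_hash: str = "", **extra) -> str:
    fields = [f"stage={stage}"]
    if cfg_hash:
        fields.append(f"config_hash={cfg_hash}")
    if seed is not None:
        fields.append(f"seed={seed}")
    fields += [f"{k}={v}" for k, v in extra.items()]
    return "# connectomaze " + " ".join(fields) + "\n"


def _read_lines(path: str | Path) -> tuple[list[str], dict[str, str]]:
    """Non-comment lines plus metadata parsed from comment headers."""
    meta: dict[str, str] = {}
    lines = []
    for raw in Path(path).read_text().splitlines():
        if raw.startswith("#"):
            for token in raw.lstrip("# ").split():
                if "=" in token:
                    k, v = token.split("=", 1)
                    meta[k] = v
            continue
        if raw.strip():
            lines.append(raw)
    return lines, meta


def _frame_from_lines(lines: list[str], path: str | Path) -> pd.DataFrame:
    if not lines:
        raise ParseError(f"{path}: no data rows")
    n_cols = len(lines[0].split(SEP))
    for lineno, line in enumerate(lines, start=1):
        if len(line.split(SEP)) != n_cols:
            raise ParseError(
                f"{path}: line {lineno} has {len(line.split(SEP))} fields, expected {n_cols}"
            )
    # round_trip parsing keeps 17-significant-digit floats bit-exact;
    # "NA" is a field sentinel (trial logs), "nan" a numeric NaN (matrices)
    return pd.read_csv(_io.StringIO("\n".join(lines)), sep=SEP,
                       float_precision="round_trip",
                       keep_default_na=False, na_values=["nan"])


# -- ROI time series --------------------------------------------------------

def write_timeseries(series: RoiTimeSeriesSet, path: str | Path,
                     stage: str = "simulate", seed: int | None = None,
                     cfg_hash: str = "") -> None:
    """Rows = volumes, columns = ROIs (header = labels with _L/_R suffixes);
    the sampling interval travels in the header comment."""
    with open(path, "w") as fh:
        fh.write(_header(stage, seed, cfg_hash, dt=series.dt))
        fh.write(SEP.join(series.roi_labels) + "\n")
        np.savetxt(fh, series.signals.T, delimiter=SEP, fmt="%.17g")


def read_timeseries(path: str | Path) -> RoiTimeSeriesSet:
    lines, meta = _read_lines(path)
    if "dt" not in meta:
        raise ParseError(f"{path}: missing dt metadata in header comment")
    if not lines:
        raise ParseError(f"{path}: no data")
    labels = lines[0].split(SEP)
    df = _frame_from_lines(lines, path)
    return RoiTimeSeriesSet(signals=df.to_numpy().T, roi_labels=labels,
                            dt=float(meta["dt"]))


def write_confounds(confounds: NuisanceSet, path: str | Path,
                    stage: str = "simulate", seed: int | None = None,
                    cfg_hash: str = "") -> None:
    with open(path, "w") as fh:
        fh.write(_header(stage, seed, cfg_hash))
        fh.write(SEP.join(confounds.names) + "\n")
        np.savetxt(fh, confounds.regressors.T, delimiter=SEP, fmt="%.17g")


def read_confounds(path: str | Path) -> NuisanceSet:
    lines, _ = _read_lines(path)
    if not lines:
        raise ParseError(f"{path}: no data")
    names = lines[0].split(SEP)
    df = _frame_from_lines(lines, path)
    return NuisanceSet(regressors=df.to_numpy().T, names=names)


# -- matrices and graphs ----------------------------------------------------

def write_matrix(cm: ConnectivityMatrix, path: str | Path,
                 stage: str = "graph", seed: int | None = None,
                 cfg_hash: str = "") -> None:
    """Full symmetric z matrix with an ROI-label header row."""
    with open(path, "w") as fh:
        fh.write(_header(stage, seed, cfg_hash))
        fh.write(SEP.join(cm.roi_labels) + "\n")
        np.savetxt(fh, cm.z_values, delimiter=SEP, fmt="%.17g")


def read_matrix(path: str | Path) -> ConnectivityMatrix:
    lines, _ = _read_lines(path)
    if not lines:
        raise ParseError(f"{path}: no data")
    labels = lines[0].split(SEP)
    values = _frame_from_lines(lines, path).to_numpy()
    if values.shape != (len(labels), len(labels)):
        raise ParseError(
            f"{path}: matrix shape {values.shape} does not match {len(labels)} labels"
        )
    return ConnectivityMatrix(z_values=values, roi_labels=labels)


def write_edge_list(graph: BrainGraph, path: str | Path, min_weight: float = 0.0,
                    stage: str = "graph", seed: int | None = None,
                    cfg_hash: str = "") -> None:
    """Visualization export: one row per retained edge with a weight column.

    ``min_weight`` applies the undirected display threshold (e.g. 0.3)."""
    ii, jj = np.nonzero(np.triu(graph.weights, 1))
    with open(path, "w") as fh:
        fh.write(_header(stage, seed, cfg_hash, density=graph.density,
                         min_weight=min_weight))
        fh.write(SEP.join(["source", "target", "weight"]) + "\n")
        for i, j in zip(ii, jj):
            w = graph.weights[i, j]
            if w >= min_weight:
                fh.write(f"{graph.roi_labels[i]}{SEP}{graph.roi_labels[j]}{SEP}{w:.17g}\n")


# -- trial logs -------------------------------------------------------------

def write_trial_log(log: TrialLog, path: str | Path, stage: str = "simulate",
                    seed: int | None = None, cfg_hash: str = "") -> None:
    with open(path, "w") as fh:
        fh.write(_header(stage, seed, cfg_hash))
        fh.write(SEP.join(["day", "kind", "turn", "side", "correct"]) + "\n")
        for r in log:
            side = r.side if r.side is not None else "NA"
            correct = {True: "1", False: "0", None: "NA"}[r.correct]
            fh.write(SEP.join([str(r.day), r.kind, r.turn, side, correct]) + "\n")


def read_trial_log(path: str | Path) -> TrialLog:
    lines, _ = _read_lines(path)
    df = _frame_from_lines(lines, path)
    expected = ["day", "kind", "turn", "side", "correct"]
    if list(df.columns) != expected:
        raise ParseError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    records = []
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        try:
            side = None if str(row.side) == "NA" else str(row.side)
            correct = None if str(row.correct) == "NA" else bool(int(row.correct))
            records.append(TrialRecord(day=int(row.day), kind=str(row.kind),
                                       turn=str(row.turn), side=side, correct=correct))
        except (ValueError, TypeError) as exc:
            raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    return TrialLog(records)


# -- catFISH cell tables ----------------------------------------------------

def write_cell_table(cells: Sequence[CellRecord], path: str | Path,
                     stage: str = "simulate", seed: int | None = None,
                     cfg_hash: str = "") -> None:
    """One row per cell; per-plane foci/coverage lists are semicolon-joined."""
    cols = ["cell_id", "region", "hemisphere", "rat_id", "image_id", "n_planes",
            "first_plane", "last_plane", "edge_cut", "foci", "coverage"]
    with open(path, "w") as fh:
        fh.write(_header(stage, seed, cfg_hash))
        fh.write(SEP.join(cols) + "\n")
        for c in cells:
            fh.write(SEP.join([
                c.cell_id, c.region, c.hemisphere, c.rat_id, c.image_id,
                str(c.n_planes_in_stack),
                str(c.visible_plane_range[0]), str(c.visible_plane_range[1]),
                "1" if c.edge_cut else "0",
                ";".join(str(int(v)) for v in c.foci_per_plane),
                ";".join(f"{v:.17g}" for v in c.coverage_per_plane),
            ]) + "\n")


def read_cell_table(path: str | Path) -> list[CellRecord]:
    lines, _ = _read_lines(path)
    df = _frame_from_lines(lines, path)
    cells = []
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        try:
            cells.append(CellRecord(
                cell_id=str(row.cell_id),
                n_planes_in_stack=int(row.n_planes),
                foci_per_plane=np.array([int(v) for v in str(row.foci).split(";")]),
                coverage_per_plane=np.array([float(v) for v in str(row.coverage).split(";")]),
                visible_plane_range=(int(row.first_plane), int(row.last_plane)),
                edge_cut=bool(int(row.edge_cut)),
                region=str(row.region), hemisphere=str(row.hemisphere),
                rat_id=str(row.rat_id), image_id=str(row.image_id),
            ))
        except (ValueError, TypeError) as exc:
            raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    return cells


# -- generic tables ---------------------------------------------------------

def write_table(df: pd.DataFrame, path: str | Path, stage: str,
                seed: int | None = None, cfg_hash: str = "") -> None:
    with open(path, "w") as fh:
        fh.write(_header(stage, seed, cfg_hash))
        df.to_csv(fh, sep=SEP, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    lines, _ = _read_lines(path)
    return _frame_from_lines(lines, path)
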