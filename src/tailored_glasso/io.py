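"""File round-tripping: delimited matrices, edge lists, run reports, configs.

All writes are atomic (temp file + rename) so an interrupted run never leaves
a truncated output behind.  Delimiters are auto-detected on read (tab vs
comma); writes are always tab-separated.
"""

from __future__ import annotations

import json
import os
import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import DataMatrix, GraphStructure, graph_from_precision
from .tailored import PriorWeights, TailoredResult

__all__ = [
    "RunConfig",
    "read_matrix",
    "write_matrix",
    "write_edge_list",
    "read_edge_list",
    "run_report",
]


@dataclass
class RunConfig:
    """Defaults for a fitting run; mirrors the CLI flags and the YAML config."""

    beta: float = 0.05
    gamma: float = 0.6
    k_max: float = 80.0
    k_steps: int = 41
    seed: int = 0
    solver_tol: float = 1e-4
    solver_max_iter: int = 100
    n_subsamples: int = 20
    n_lambda: int = 20
    lambda_min_ratio: float = 0.1
    standardize: bool = True
    adjust_sparsity: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _atomic_write(path: str | Path, text: str) -> None:
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent or Path("."), suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _read_table(path: str | Path) -> pd.DataFrame:
    # sniff tab vs comma, then parse with correctly-rounded float conversion
    # so that write -> read round trips are bit-exact
    with open(path) as fh:
        first = fh.readline()
    sep = "\t" if "\t" in first else ","
    return pd.read_csv(path, sep=sep, index_col=None, float_precision="round_trip")


def read_matrix(path: str | Path, kind: str = "data"):
    """Read a delimited matrix as the requested kind.

    kind='data'      -> DataMatrix (rows = samples; optional header row)
    kind='weights'   -> PriorWeights (square, symmetric, entries in [0, 1])
    kind='precision' -> ndarray (square, symmetric)

    Square matrices may carry row labels in the first column; mild asymmetry
    (<= 1e-8) is symmetrized, anything larger is an error.
    """
    if kind not in {"data", "weights", "precision"}:
        raise ValueError(f"unknown matrix kind {kind!r}")
    df = _read_table(path)
    if kind == "data":
        vals = df.to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise ValueError(f"{path}: data matrix contains NaN values")
        names = [str(c) for c in df.columns]
        constant = np.flatnonzero(vals.std(axis=0) == 0.0)
        if constant.size:
            raise ValueError(
                f"{path}: zero-variance column(s) {[names[j] for j in constant]}; "
                "the graphical lasso does not allow constant variables"
            )
        return DataMatrix(vals, names)

    # square kinds: tolerate a leading label column
    if df.shape[1] == df.shape[0] + 1:
        df = df.set_index(df.columns[0])
    try:
        M = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric entries in matrix") from exc
    if M.shape[0] != M.shape[1]:
        raise ValueError(f"{path}: expected a square matrix, got {M.shape}")
    if np.isnan(M).any():
        raise ValueError(f"{path}: matrix contains NaN values")
    asym = float(np.max(np.abs(M - M.T)))
    if asym > 1e-8:
        raise ValueError(f"{path}: matrix is asymmetric (max |M - M'| = {asym:.3e})")
    M = 0.5 * (M + M.T)
    if kind == "weights":
        bad = np.argwhere((M < 0) | (M > 1))
        if bad.size:
            i, j = bad[0]
            raise ValueError(
                f"{path}: weight entry ({i}, {j}) = {M[i, j]} outside [0, 1]"
            )
        np.fill_diagonal(M, 0.0)
        return PriorWeights(M)
    return M


def write_matrix(M: np.ndarray, path: str | Path,
                 labels: list[str] | None = None) -> None:
    """Write a p x p matrix as TSV with row and column labels."""
    M = np.asarray(M)
    p = M.shape[0]
    labels = labels or [f"V{j + 1}" for j in range(p)]
    df = pd.DataFrame(M, index=labels, columns=labels)
    # 17 significant digits: float64 survives the text round trip exactly
    _atomic_write(path, df.to_csv(sep="\t", index_label="", float_format="%.17g"))


def write_edge_list(graph: GraphStructure, names: list[str],
                    path: str | Path) -> None:
    """One row per edge, two columns of node names, sorted deterministically."""
    if len(names) != graph.p:
        raise ValueError(f"{len(names)} names for {graph.p} nodes")
    if len(set(names)) != len(names):
        raise ValueError("duplicate node names")
    lines = ["node1\tnode2"]
    for i, j in sorted(graph.edges):
        lines.append(f"{names[i]}\t{names[j]}")
    _atomic_write(path, "\n".join(lines) + "\n")


def read_edge_list(path: str | Path, names: list[str]) -> GraphStructure:
    df = pd.read_csv(path, sep="\t")
    index = {name: k for k, name in enumerate(names)}
    edges = set()
    for a, b in zip(df.iloc[:, 0], df.iloc[:, 1]):
        edges.add((index[str(a)], index[str(b)]))
    return GraphStructure(p=len(names), edges=frozenset(edges), node_names=list(names))


def run_report(result: TailoredResult | list, path: str | Path,
               config: RunConfig | None = None,
               extra: dict | None = None) -> dict:
    """Write a machine-readable JSON run report; returns the report dict.

    For a tailored fit this records k_opt, w0, the penalties, the eBIC path
    and the penalty-budget check; for benchmark records, the per-method means.
    """
    report: dict = {"software_version": __version__}
    if config is not None:
        report["config"] = {k: getattr(config, k)
                            for k in config.__dataclass_fields__}
    if isinstance(result, TailoredResult):
        p = result.theta_hat.shape[0]
        budget = result.lambda_k * float(np.abs(result.penalty_matrix.P).sum())
        report.update(
            {
                "k_opt": result.k_opt,
                "w0": result.w0,
                "lambda": result.lambda_,
                "lambda_k": result.lambda_k,
                "k_grid": result.k_grid.tolist(),
                "ebic_path": result.ebic_path.tolist(),
                "sparsity": graph_from_precision(result.theta_hat).sparsity,
                "adjusted_to_target_edges": result.adjusted,
                "target_n_edges": result.target_n_edges,
                "penalty_budget_ratio": budget / (result.lambda_ * p * p)
                if not result.adjusted else None,
            }
        )
    else:
        report["records"] = [
            {k: getattr(rec, k) for k in rec.__dataclass_fields__}
            for rec in result
        ]
    if extra:
        report.update(extra)
    _atomic_write(path, json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
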