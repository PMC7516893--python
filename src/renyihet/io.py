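"""Delimited-text readers and writers for the library's input formats.

Formats (all plain text, tab- or comma-delimited, auto-detected):

* abundance/probability tables — rows = subsystems, columns = states,
  optional header row of state labels and first column of subsystem
  labels; counts are normalized row-wise to probabilities;
* square distance/similarity matrices with matching row/column labels;
* Gaussian-posterior sets — columns ``id, mu_1..mu_nz`` then either
  ``logvar_1..logvar_nz`` or ``cov_11..cov_nznz``, optional ``weight``.

Writers emit deterministic column order at full float precision, so a run
is byte-reproducible from its configuration.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import SubsystemEnsemble, ValidationError
from .functional import DistanceMatrix, SimilarityMatrix
from .representational import GaussianComponentSet

__all__ = [
    "read_abundance_table",
    "read_matrix",
    "read_gaussian_set",
    "write_gaussian_set",
    "emit_results",
]

_SYM_IO_TOL = 1e-6


def _sniff_delimiter(path) -> str:
    first = Path(path).read_text().splitlines()[0]
    return "\t" if first.count("\t") >= first.count(",") else ","


def _read_table(path) -> pd.DataFrame:
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, header=None, dtype=str, comment="#")
    # header row present iff the first data cell of row 0 is non-numeric
    def _numeric(s):
        try:
            float(s)
            return True
        except (TypeError, ValueError):
            return False

    has_header = not _numeric(df.iloc[0, -1])
    if has_header:
        df.columns = df.iloc[0]
        df = df.iloc[1:].reset_index(drop=True)
    has_index = not df.iloc[:, 0].map(_numeric).all()
    if has_index:
        df = df.set_index(df.columns[0])
    return df.astype(float)


def read_abundance_table(path, weights_path=None) -> SubsystemEnsemble:
    """Read a counts/probability table; rows are normalized to probabilities.

    Ragged rows, negative entries and zero-sum rows are rejected with the
    offending row named.  Missing weights default to uniform.
    """
    df = _read_table(path)
    X = df.to_numpy(dtype=float)
    if np.isnan(X).any():
        bad = int(np.argwhere(np.isnan(X).any(axis=1))[0, 0])
        raise ValidationError(f"row {bad} of {path} is ragged or non-numeric")
    if (X < 0).any():
        bad = int(np.argwhere((X < 0).any(axis=1))[0, 0])
        raise ValidationError(f"row {bad} of {path} has negative entries")
    sums = X.sum(axis=1)
    if (sums <= 0).any():
        bad = int(np.argwhere(sums <= 0)[0, 0])
        raise ValidationError(f"row {bad} of {path} sums to zero")
    P = X / sums[:, None]
    w = None
    if weights_path is not None:
        w = np.loadtxt(weights_path, dtype=float).ravel()
    return SubsystemEnsemble(P, w)


def read_matrix(path, kind: str = "distance"):
    """Read a square matrix as a DistanceMatrix or SimilarityMatrix.

    Asymmetry up to 1e-6 is symmetrized with a warning; beyond that, or a
    kind-inconsistent diagonal, is rejected.
    """
    import logging

    df = _read_table(path)
    M = df.to_numpy(dtype=float)
    if M.shape[0] != M.shape[1]:
        raise ValidationError(f"matrix in {path} is not square: {M.shape}")
    asym = np.abs(M - M.T).max()
    if asym > _SYM_IO_TOL:
        raise ValidationError(f"matrix in {path} asymmetric beyond tolerance ({asym:g})")
    if asym > 0:
        logging.getLogger(__name__).warning(
            "symmetrizing matrix from %s (max asymmetry %g)", path, asym
        )
        M = 0.5 * (M + M.T)
    if kind == "distance":
        if np.abs(np.diag(M)).max() > _SYM_IO_TOL:
            raise ValidationError(f"distance matrix in {path} has a nonzero diagonal")
        np.fill_diagonal(M, 0.0)
        return DistanceMatrix(M)
    if kind == "similarity":
        if np.abs(np.diag(M) - 1.0).max() > _SYM_IO_TOL:
            raise ValidationError(f"similarity matrix in {path} diagonal is not 1")
        np.fill_diagonal(M, 1.0)
        return SimilarityMatrix(M)
    raise ValueError(f"unknown matrix kind {kind!r}")


def read_gaussian_set(path) -> GaussianComponentSet:
    """Read a Gaussian-posterior table (id, mu_*, logvar_* or cov_*, weight)."""
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, comment="#")
    mu_cols = sorted(
        (c for c in df.columns if c.startswith("mu_")), key=lambda c: int(c[3:])
    )
    if not mu_cols:
        raise ValidationError(f"no mu_* columns found in {path}")
    nz = len(mu_cols)
    mu = df[mu_cols].to_numpy(dtype=float)
    w = df["weight"].to_numpy(dtype=float) if "weight" in df.columns else None
    logvar_cols = sorted(
        (c for c in df.columns if c.startswith("logvar_")), key=lambda c: int(c[7:])
    )
    if logvar_cols:
        if len(logvar_cols) != nz:
            raise ValidationError(f"expected {nz} logvar_* columns in {path}")
        return GaussianComponentSet.from_logvar(
            mu, df[logvar_cols].to_numpy(dtype=float), w
        )
    cov_cols = [f"cov_{i + 1}{j + 1}" for i in range(nz) for j in range(nz)]
    missing = [c for c in cov_cols if c not in df.columns]
    if missing:
        raise ValidationError(f"missing covariance columns in {path}: {missing}")
    Sigma = df[cov_cols].to_numpy(dtype=float).reshape(-1, nz, nz)
    return GaussianComponentSet(mu, Sigma, w)


def write_gaussian_set(g: GaussianComponentSet, path, sep: str = "\t") -> None:
    """Write a component set in the full-covariance column layout."""
    nz = g.nz
    cols = {"id": np.arange(g.N)}
    for j in range(nz):
        cols[f"mu_{j + 1}"] = g.mu[:, j]
    for i in range(nz):
        for j in range(nz):
            cols[f"cov_{i + 1}{j + 1}"] = g.Sigma[:, i, j]
    cols["weight"] = g.w
    pd.DataFrame(cols).to_csv(path, sep=sep, index=False, float_format="%.17g")


def emit_results(table: pd.DataFrame, path, format: str = "tsv", meta: dict | None = None):
    """Write a tidy results table deterministically (17 significant digits).

    ``meta`` (seed, configuration) is embedded in JSON output and logged
    for TSV output.
    """
    import logging

    path = Path(path)
    if meta:
        logging.getLogger(__name__).info("emit_results meta: %s", meta)
    if format == "tsv":
        table.to_csv(path, sep="\t", index=False, float_format="%.17g")
    elif format == "json":
        payload = {"meta": meta or {}, "records": json.loads(table.to_json(orient="records"))}
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")
    return path
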