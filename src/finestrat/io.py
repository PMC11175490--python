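"""CSV readers and writers for stratified samples and populations.

Sample files carry one row per sampled unit with columns
``stratum,N_i,x_i,y[,pi]`` (header required); when ``pi`` is absent it
defaults to n_i/N_i computed from the rows of each stratum.  Population
files carry ``stratum,x_i,y`` with N_i inferred by row count.  Stratum order
in files is never trusted: strata are always re-sorted by their score x.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import SampledStratum, StratifiedPopulation, StratifiedSample, Stratum
from .exceptions import ParseError, SchemaError

__all__ = [
    "read_sample_csv",
    "write_sample_csv",
    "read_population_csv",
]

SAMPLE_COLUMNS = ("stratum", "N_i", "x_i", "y")
POPULATION_COLUMNS = ("stratum", "x_i", "y")


def _check_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {', '.join(missing)}")


def _numeric(df: pd.DataFrame, column: str, path) -> np.ndarray:
    values = pd.to_numeric(df[column], errors="coerce")
    bad = values.isna() & df[column].notna()
    if bad.any() or values.isna().any():
        row = int(np.nonzero((values.isna()).to_numpy())[0][0])
        raise ParseError(
            f"{path}: non-numeric value {df[column].iloc[row]!r} in column "
            f"{column!r} at data row {row + 1}"
        )
    return values.to_numpy(dtype=float)


def _constant_per_stratum(values: np.ndarray, groups: np.ndarray, column: str, path):
    for sid in np.unique(groups):
        vals = np.unique(values[groups == sid])
        if vals.size != 1:
            raise SchemaError(
                f"{path}: column {column!r} is not constant within stratum {sid!r}"
            )


def read_sample_csv(path) -> StratifiedSample:
    """Read a stratified sample from ``stratum,N_i,x_i,y[,pi]`` CSV."""
    df = pd.read_csv(path)
    _check_columns(df, SAMPLE_COLUMNS, path)
    stratum = df["stratum"].to_numpy()
    N = _numeric(df, "N_i", path)
    x = _numeric(df, "x_i", path)
    y = _numeric(df, "y", path)
    pi = _numeric(df, "pi", path) if "pi" in df.columns else None
    _constant_per_stratum(N, stratum, "N_i", path)
    _constant_per_stratum(x, stratum, "x_i", path)

    strata = []
    for sid in pd.unique(stratum):
        mask = stratum == sid
        N_i = N[mask][0]
        if N_i < 1 or N_i != int(N_i):
            raise SchemaError(f"{path}: N_i must be a positive integer (stratum {sid!r})")
        n_i = int(mask.sum())
        pi_i = pi[mask] if pi is not None else np.full(n_i, n_i / N_i)
        strata.append(
            SampledStratum(
                id=sid,
                x=float(x[mask][0]),
                population_size=int(N_i),
                y=y[mask],
                pi=pi_i,
            )
        )
    return StratifiedSample(strata)


def write_sample_csv(sample: StratifiedSample, path) -> None:
    """Write a sample back to the ``stratum,N_i,x_i,y,pi`` layout."""
    rows = []
    for s in sample.strata:
        for y_k, pi_k in zip(s.y, s.pi):
            rows.append(
                {"stratum": s.id, "N_i": s.population_size, "x_i": s.x, "y": y_k, "pi": pi_k}
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_population_csv(path) -> StratifiedPopulation:
    """Read a full population from ``stratum,x_i,y`` CSV (N_i by count)."""
    df = pd.read_csv(path)
    _check_columns(df, POPULATION_COLUMNS, path)
    stratum = df["stratum"].to_numpy()
    x = _numeric(df, "x_i", path)
    y = _numeric(df, "y", path)
    _constant_per_stratum(x, stratum, "x_i", path)
    strata = [
        Stratum(id=sid, x=float(x[stratum == sid][0]), y=y[stratum == sid])
        for sid in pd.unique(stratum)
    ]
    return StratifiedPopulation(strata)
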