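"""Readers and writers for feature tables, distance matrices and results.

Feature tables are delimited text (TSV/CSV) with a header row of feature
ids and sample ids in the first column; an orientation flag accepts
features-as-rows files.  Distance matrices come either as a square
labelled TSV or in the lower-triangular whitespace dialect (first line
the sample count, then one row per sample: id followed by distances to
all preceding samples).  Metadata is a TSV/CSV keyed by sample id in the
first column.  Floats are serialized with 17 significant digits so
write-then-read round trips are exact.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .comparators import ComparatorResult
from .dissimilarity import DistanceMatrix, FeatureTable
from .dth import DTHResult

__all__ = [
    "read_feature_table",
    "write_feature_table",
    "read_distance_matrix",
    "write_distance_matrix",
    "read_metadata",
    "write_result_json",
    "result_pairs_frame",
    "write_result_tsv",
]

_FLOAT_FMT = "%.17g"


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_feature_table(path, orientation: str = "samples-as-rows") -> FeatureTable:
    """Read a delimited feature table.

    Parameters
    ----------
    path : str or Path
    orientation : {'samples-as-rows', 'features-as-rows'}
        With ``features-as-rows`` the file is transposed after reading.

    Raises
    ------
    ValueError
        Duplicate ids, missing values or non-numeric cells (reported
        with their row/column coordinates).
    """
    path = Path(path)
    if orientation not in ("samples-as-rows", "features-as-rows"):
        raise ValueError("orientation must be 'samples-as-rows' or 'features-as-rows'")
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype=str,
                     keep_default_na=False)
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate id {dup!r} in first column of {path}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"duplicate id {dup!r} in header of {path}")
    # locate bad cells first, then convert via strtod for exact round trips
    bad = df.apply(pd.to_numeric, errors="coerce").isna().to_numpy()
    if bad.any():
        i, j = np.argwhere(bad)[0]
        cell = df.iat[i, j]
        raise ValueError(
            f"non-numeric or missing value {cell!r} at row {df.index[i]!r}, "
            f"column {df.columns[j]!r} of {path}"
        )
    values = np.vectorize(float, otypes=[float])(df.to_numpy())
    sample_ids, feature_ids = df.index, df.columns
    if orientation == "features-as-rows":
        values = values.T
        sample_ids, feature_ids = feature_ids, sample_ids
    return FeatureTable(values, sample_ids=sample_ids, feature_ids=feature_ids)


def write_feature_table(table: FeatureTable, path) -> None:
    path = Path(path)
    df = pd.DataFrame(table.values, index=list(table.sample_ids),
                      columns=list(table.feature_ids))
    df.to_csv(path, sep=_sep_for(path), float_format=_FLOAT_FMT)


def _read_triangular(path: Path) -> tuple[np.ndarray, list[str]]:
    with open(path) as fh:
        tokens_lines = [line.split() for line in fh if line.strip()]
    if not tokens_lines:
        raise ValueError(f"{path} is empty")
    try:
        n = int(tokens_lines[0][0])
    except ValueError:
        raise ValueError(f"first line of triangular file {path} must be the "
                         "sample count") from None
    if len(tokens_lines) - 1 != n:
        raise ValueError(f"triangular file {path} declares {n} samples but has "
                         f"{len(tokens_lines) - 1} rows")
    ids, M = [], np.zeros((n, n))
    for i, toks in enumerate(tokens_lines[1:]):
        if len(toks) != i + 1:
            raise ValueError(
                f"row {i + 1} of {path} has {len(toks) - 1} distance(s); "
                f"expected {i} (id followed by distances to preceding samples)"
            )
        ids.append(toks[0])
        row = [float(t) for t in toks[1:]]
        M[i, :i] = row
        M[:i, i] = row
    return M, ids


def read_distance_matrix(path, dialect: str = "square") -> DistanceMatrix:
    """Read a distance matrix from square TSV or lower-triangular text.

    Square input must have matching row and column ids, a diagonal of
    zeros (tolerance 1e-12) and no negative entries.  Asymmetry above
    1e-8 is an error; below that the matrix is symmetrized with a
    warning.
    """
    path = Path(path)
    if dialect == "triangular":
        M, ids = _read_triangular(path)
    elif dialect == "square":
        df = pd.read_csv(path, sep=_sep_for(path), index_col=0,
                         float_precision="round_trip")
        ids = [str(i) for i in df.index]
        cols = [str(c) for c in df.columns]
        if ids != cols:
            raise ValueError(f"row ids and column ids of {path} do not match")
        M = df.to_numpy(dtype=float)
    else:
        raise ValueError("dialect must be 'square' or 'triangular'")

    if M.shape[0] != M.shape[1]:
        raise ValueError(f"{path} is not square")
    asym = float(np.max(np.abs(M - M.T))) if M.size else 0.0
    if asym > 1e-8:
        raise ValueError(f"{path}: matrix is asymmetric (max |D - D.T| = {asym:.3g})")
    if asym > 0:
        warnings.warn(f"{path}: symmetrizing matrix (max asymmetry {asym:.3g})",
                      stacklevel=2)
        M = 0.5 * (M + M.T)
    if np.any(np.abs(np.diag(M)) > 1e-12):
        raise ValueError(f"{path}: diagonal entries must be zero")
    np.fill_diagonal(M, 0.0)
    if np.any(M < 0):
        raise ValueError(f"{path}: negative distances are not allowed")
    return DistanceMatrix(M, ids)


def write_distance_matrix(D: DistanceMatrix, path) -> None:
    path = Path(path)
    df = pd.DataFrame(D.values, index=list(D.sample_ids),
                      columns=list(D.sample_ids))
    df.to_csv(path, sep=_sep_for(path), float_format=_FLOAT_FMT)


def read_metadata(path) -> pd.DataFrame:
    """Metadata table keyed by sample id (first column)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate sample id {dup!r} in {path}")
    return df


def write_result_json(results, path) -> None:
    """Serialize one result or a {name: result} mapping to JSON.

    P-values appear both at full precision and rounded to 4 digits for
    quick reading.
    """
    def enrich(r):
        d = r.to_dict()
        d["p_value_rounded"] = round(d["p_value"], 4)
        return d

    if isinstance(results, (DTHResult, ComparatorResult)):
        payload = enrich(results)
    else:
        payload = {name: enrich(r) for name, r in results.items()}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def result_pairs_frame(result: DTHResult) -> pd.DataFrame:
    """Flat per-pair statistics of a DTH result."""
    rows = []
    for (a, b) in result.pairs:
        rows.append({
            "group1": a, "group2": b,
            "K0": result.K0[(a, b)], "W0": result.W0[(a, b)],
            "p0K": result.p0K[(a, b)], "p0W": result.p0W[(a, b)],
            "m0": result.m0[(a, b)], "p0m": result.p0m[(a, b)],
        })
    return pd.DataFrame(rows)


def write_result_tsv(result: DTHResult, path) -> None:
    result_pairs_frame(result).to_csv(path, sep="\t", index=False,
                                      float_format=_FLOAT_FMT)
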