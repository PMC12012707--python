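"""Reading and writing datasets as delimited text.

A dataset is a numeric matrix (rows = observations, CSV or TSV,
delimiter auto-detected) plus a label file with one integer per row:
values 1..K are observed class labels, 0 (or the token ``NA``) means
unlabeled.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd


class ParseError(ValueError):
    """A file failed validation; the message names the offending line."""


def _sniff_delimiter(path: Path) -> str:
    with open(path, newline="") as fh:
        sample = fh.read(8192)
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t;").delimiter
    except csv.Error:
        return ","


def read_matrix(path: str | Path) -> np.ndarray:
    """Read a delimited numeric matrix; raises ParseError on bad cells."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    delim = _sniff_delimiter(path)
    try:
        df = pd.read_csv(path, sep=delim, header=None, dtype=float)
    except (ValueError, pd.errors.ParserError) as err:
        raise ParseError(f"{path}: non-numeric or malformed cell ({err})") from err
    return df.to_numpy()


def read_labels(path: str | Path, K: int | None = None) -> np.ndarray:
    """Read one label per line; 'NA' (any case) maps to 0 (unlabeled)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    labels = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tok = line.strip()
            if not tok:
                continue
            if tok.upper() == "NA":
                labels.append(0)
                continue
            try:
                val = int(tok)
            except ValueError as err:
                raise ParseError(f"{path}:{lineno}: not an integer: {tok!r}") from err
            if val < 0 or (K is not None and val > K):
                raise ParseError(
                    f"{path}:{lineno}: label {val} outside {{0..{K or 'K'}}}"
                )
            labels.append(val)
    return np.asarray(labels, dtype=int)


def read_dataset(
    matrix_path: str | Path, labels_path: str | Path, K: int | None = None
) -> tuple[np.ndarray, np.ndarray, int]:
    """Read (X, y, K); K is inferred as max(y) unless given."""
    X = read_matrix(matrix_path)
    y = read_labels(labels_path, K)
    if y.shape[0] != X.shape[0]:
        raise ParseError(
            f"row-count mismatch: {X.shape[0]} matrix rows vs {y.shape[0]} labels"
        )
    if K is None:
        K = int(y.max())
        if K < 2:
            raise ParseError(
                "cannot infer the number of classes from the labels; pass K"
            )
    return X, y, K


def write_matrix(path: str | Path, X: np.ndarray) -> None:
    pd.DataFrame(np.asarray(X)).to_csv(path, header=False, index=False)


def write_labels(path: str | Path, y: np.ndarray) -> None:
    np.savetxt(path, np.asarray(y, dtype=int), fmt="%d")


def standardize_columns(X: np.ndarray, center: bool = False) -> np.ndarray:
    """Scale each column to unit sample variance (no centering by default).

    Raises on zero-variance columns, listing them 1-based; remove such
    columns (they carry no class information) before standardizing.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    sd = X.std(axis=0, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        cols = ", ".join(str(j + 1) for j in bad)
        raise ValueError(f"zero-variance column(s): {cols}")
    out = X / sd
    if center:
        out = out - out.mean(axis=0)
    return out
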