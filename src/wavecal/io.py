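"""Reading and writing spectral matrices and result tables.

CSV (comma-separated, period decimal, optional single header row) and
MATLAB MAT files (numeric 2-D variables, e.g. the public corn NIR benchmark)
are supported.  Matrices are normalised to samples-in-rows orientation.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io

__all__ = ["read_matrix", "write_matrix", "load_dataset", "write_report"]


class ParseError(ValueError):
    """Raised when an input file cannot be interpreted as a spectral matrix."""


def _read_csv_matrix(path: Path, header: str | bool) -> tuple[np.ndarray, np.ndarray | None]:
    try:
        df = pd.read_csv(path, header=None, float_precision="round_trip")
    except (pd.errors.ParserError, UnicodeDecodeError) as err:
        raise ParseError(f"{path}: ragged or unreadable CSV ({err})") from err
    axis = None
    first = df.iloc[0]
    first_is_text = first.map(lambda v: isinstance(v, str)).any()
    # header: "auto" drops a non-numeric first row; True treats the first row
    # as the channel axis even when it is numeric (wavelengths).
    if header is True or (header == "auto" and first_is_text):
        try:
            axis = first.astype(float).to_numpy()
        except (TypeError, ValueError):
            axis = None
        df = df.iloc[1:]
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as err:
        bad = df.map(lambda v: isinstance(v, str)).any()
        cols = list(np.nonzero(bad.to_numpy())[0]) if hasattr(bad, "to_numpy") else []
        raise ParseError(f"{path}: non-numeric cells in column(s) {cols}") from err
    return values, axis


def read_matrix(
    path,
    fmt: str | None = None,
    orientation: str = "rows",
    variable: str | None = None,
    header: str | bool = "auto",
) -> tuple[np.ndarray, np.ndarray | None]:
    """Read a spectral matrix; returns (samples x channels array, axis|None).

    ``orientation`` declares how the file stores samples (``"rows"`` or
    ``"columns"``); the result is always samples-in-rows.  For MAT files
    ``variable`` names the matrix to load.  ``header`` controls the CSV
    first-row interpretation: ``"auto"``, ``True`` (channel axis) or ``False``.
    """
    path = Path(path)
    if fmt is None:
        fmt = "mat" if path.suffix.lower() == ".mat" else "csv"
    if fmt == "csv":
        values, axis = _read_csv_matrix(path, header)
    elif fmt == "mat":
        try:
            contents = scipy.io.loadmat(path)
        except (ValueError, OSError, NotImplementedError) as err:
            raise ParseError(f"{path}: unreadable MAT file ({err})") from err
        numeric = {
            k: np.asarray(v)
            for k, v in contents.items()
            if not k.startswith("__") and np.issubdtype(np.asarray(v).dtype, np.number)
        }
        if variable is None:
            if len(numeric) != 1:
                raise ParseError(
                    f"{path}: specify a variable; available numeric 2-D variables: "
                    f"{sorted(numeric)}"
                )
            variable = next(iter(numeric))
        if variable not in numeric:
            raise ParseError(f"{path}: no numeric variable {variable!r}; has {sorted(numeric)}")
        values = np.atleast_2d(numeric[variable].astype(float))
        axis = None
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if orientation == "columns":
        values = values.T
    elif orientation != "rows":
        raise ValueError(f"orientation must be 'rows' or 'columns', got {orientation!r}")
    if not np.all(np.isfinite(values)):
        raise ParseError(f"{path}: matrix contains missing or non-finite values")
    return values, axis


def write_matrix(path, X: np.ndarray, channel_axis=None) -> None:
    """Write a samples-in-rows matrix as CSV (full float precision)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    df = pd.DataFrame(X)
    if channel_axis is not None:
        df.columns = [repr(float(c)) for c in channel_axis]
        df.to_csv(path, index=False, float_format="%.17g")
    else:
        df.to_csv(path, index=False, header=False, float_format="%.17g")


def load_dataset(spectra_path, y_path=None, y_column=None, orientation="rows", variable=None):
    """Load spectra plus reference values into a :class:`SpectralDataset`.

    ``y_path`` points at a one-column file; alternatively ``y_column`` names
    (or indexes, 0-based) the column of the spectra file holding y.
    """
    from .model import SpectralDataset

    X, axis = read_matrix(spectra_path, orientation=orientation, variable=variable)
    if y_path is not None:
        y, _ = read_matrix(y_path, orientation="rows")
        y = y.ravel()
    elif y_column is not None:
        col = int(y_column)
        y = X[:, col]
        X = np.delete(X, col, axis=1)
        if axis is not None:
            axis = np.delete(axis, col)
    else:
        raise ValueError("provide y_path or y_column")
    return SpectralDataset(X, y, channel_axis=axis)


def write_report(path, rows: list[dict]) -> None:
    """Write a calibration report table (one row per wavelet/model)."""
    columns = ["wavelet", "n_factors", "rmsec", "selected_a", "r_c", "rmsep", "r_p"]
    df = pd.DataFrame(rows)
    for c in columns:
        if c not in df.columns:
            df[c] = np.nan
    df[columns].to_csv(path, index=False, float_format="%.6g")
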