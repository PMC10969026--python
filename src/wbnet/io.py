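"""Delimited-text file formats.

All matrices travel as tab-separated text with region labels in the
first row and first column; time series as tab-separated text with a
time column and one column per region.  Formatting is deterministic so
identical inputs yield byte-identical files, and values are printed
with enough digits for the text round trip to be loss-free at double
precision (17 significant digits for time series, 9 for matrices).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import numpy.typing as npt

from .connectivity import CouplingSweepResult
from .integrator import RegionTimeSeries

__all__ = [
    "MatrixParseError",
    "read_matrix",
    "write_matrix",
    "read_timeseries",
    "write_timeseries",
    "write_sweep",
]

_DELIM = "\t"


class MatrixParseError(ValueError):
    """A labeled-matrix file violates the format contract."""


def _fallback_labels(n: int) -> list[str]:
    return [f"R{i + 1:03d}" for i in range(n)]


def write_matrix(
    matrix: npt.NDArray[np.float64],
    labels: list[str] | tuple[str, ...],
    path: str | Path,
    fmt: str = "%.9g",
) -> None:
    """Write a labeled square matrix as tab-separated text."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"matrix must be square, got shape {m.shape}")
    n = m.shape[0]
    labels = list(labels) if labels else _fallback_labels(n)
    if len(labels) != n:
        raise ValueError(f"{len(labels)} labels for a {n}x{n} matrix")
    lines = ["" + _DELIM + _DELIM.join(labels)]
    for lab, row in zip(labels, m):
        lines.append(lab + _DELIM + _DELIM.join(fmt % v for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_matrix(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Read a labeled square matrix written by :func:`write_matrix`.

    Validates squareness, row/column label agreement and numeric cells;
    parse errors name the offending row and column.
    """
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines:
        raise MatrixParseError(f"{path}: empty file")
    header = lines[0].split(_DELIM)
    col_labels = header[1:]
    n = len(col_labels)
    if len(lines) - 1 != n:
        raise MatrixParseError(
            f"{path}: non-square body ({len(lines) - 1} rows, {n} columns)"
        )
    m = np.empty((n, n))
    row_labels = []
    for r, line in enumerate(lines[1:]):
        cells = line.split(_DELIM)
        if len(cells) != n + 1:
            raise MatrixParseError(
                f"{path}: row {r + 1} has {len(cells) - 1} cells, expected {n}"
            )
        row_labels.append(cells[0])
        for c, cell in enumerate(cells[1:]):
            try:
                m[r, c] = float(cell)
            except ValueError:
                raise MatrixParseError(
                    f"{path}: non-numeric cell at row {r + 1}, column {c + 1}: {cell!r}"
                ) from None
    if row_labels != col_labels:
        raise MatrixParseError(f"{path}: row labels do not match column labels")
    return m, row_labels


def write_timeseries(series: RegionTimeSeries, path: str | Path) -> None:
    """Tab-separated series: time column, then one column per region,
    printed with full double precision."""
    lines = ["time" + _DELIM + _DELIM.join(series.labels)]
    times = series.times
    for k in range(series.n_samples):
        lines.append(
            "%.17g" % times[k]
            + _DELIM
            + _DELIM.join("%.17g" % v for v in series.values[:, k])
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_timeseries(path: str | Path) -> RegionTimeSeries:
    """Read a series written by :func:`write_timeseries`."""
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    if len(lines) < 3:
        raise MatrixParseError(f"{path}: need a header and at least two samples")
    labels = lines[0].split(_DELIM)[1:]
    body = np.array([[float(c) for c in ln.split(_DELIM)] for ln in lines[1:]])
    times, values = body[:, 0], body[:, 1:].T
    dt = np.diff(times)
    if not np.allclose(dt, dt[0], rtol=1e-6):
        raise MatrixParseError(f"{path}: non-uniform sampling grid")
    return RegionTimeSeries(
        values=values, fs=1.0 / dt.mean(), t0=times[0], labels=tuple(labels)
    )


def write_sweep(
    result: CouplingSweepResult,
    tsv_path: str | Path,
    json_path: str | Path | None = None,
    seed: int | None = None,
) -> None:
    """Sweep curve as two-column text (C, PCC) plus a JSON summary."""
    lines = ["C" + _DELIM + "PCC"]
    for c, p in zip(result.c_values, result.pcc_values):
        lines.append("%.9g%s%.9g" % (c, _DELIM, p))
    Path(tsv_path).write_text("\n".join(lines) + "\n")
    if json_path is not None:
        summary = {
            "best_c": result.best_c,
            "best_pcc": result.best_pcc,
            "grid": result.c_values.tolist(),
            "pcc": result.pcc_values.tolist(),
            "seed": seed,
        }
        Path(json_path).write_text(json.dumps(summary, indent=2) + "\n")
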