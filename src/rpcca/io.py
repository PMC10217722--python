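"""Delimited-matrix I/O and run configuration.

The method consumes generic numeric matrices with rows as observations and
columns as variables; files are plain delimited text (CSV/TSV) with an
optional header line.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError

__all__ = ["RunConfig", "read_matrix", "write_matrix", "load_config_file"]


@dataclass
class RunConfig:
    """Validated configuration for a model-fitting run."""

    x_path: str = ""
    y_path: str = ""
    delimiter: str = ","
    header: bool = True
    tau: float = 0.3
    n_pairs: int = 1
    alpha: float = 0.05
    permutations: int = 1000
    seed: int = 0
    restarts: int = 10
    output_dir: str = "."

    def validate(self):
        problems = []
        if self.tau < 0:
            problems.append("tau: must be nonnegative")
        if self.n_pairs < 1:
            problems.append("n_pairs: must be a positive integer")
        if not 0 < self.alpha < 1:
            problems.append("alpha: must lie in (0, 1)")
        if self.permutations < 1:
            problems.append("permutations: must be a positive integer")
        if self.restarts < 1:
            problems.append("restarts: must be a positive integer")
        if len(self.delimiter) != 1:
            problems.append("delimiter: must be a single character")
        if problems:
            raise ParseError("invalid configuration: " + "; ".join(problems))
        return self


def load_config_file(path) -> dict:
    """Read a flat ``key = value`` configuration file into a dict.

    Unknown keys raise; values are coerced to the :class:`RunConfig` field
    types.  Lines starting with ``#`` and blank lines are ignored.
    """
    known = {f.name: f.type for f in fields(RunConfig)}
    out = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ParseError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, _, value = (s.strip() for s in line.partition("="))
        if key not in known:
            raise ParseError(f"{path}:{lineno}: unknown configuration key {key!r}")
        typ = known[key]
        try:
            if typ == "bool":
                out[key] = value.lower() in ("1", "true", "yes")
            elif typ == "int":
                out[key] = int(value)
            elif typ == "float":
                out[key] = float(value)
            else:
                out[key] = value
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: bad value for {key}: {value!r}") from exc
    return out


def _scan_for_bad_cell(path, delimiter, skip_header):
    """Locate the first ragged or non-numeric line for a helpful message."""
    width = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if skip_header and lineno == 1:
                continue
            cells = raw.rstrip("\n").split(delimiter)
            if width is None:
                width = len(cells)
            if len(cells) != width:
                return lineno, f"expected {width} columns, found {len(cells)}"
            for cell in cells:
                try:
                    float(cell)
                except ValueError:
                    return lineno, f"non-numeric cell {cell.strip()!r}"
    return None, None


def read_matrix(path, delimiter: str = ",", header: bool = True):
    """Read an observations-by-variables numeric matrix from delimited text.

    Returns ``(matrix, labels)``; labels are synthesized as ``col1..colk``
    when ``header`` is False.  Ragged rows, non-numeric cells, or an empty
    file raise :class:`ParseError` naming the offending line.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: file not found")
    try:
        df = pd.read_csv(
            path, sep=delimiter, header=0 if header else None, float_precision="round_trip"
        )
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty file") from exc
    except pd.errors.ParserError as exc:
        lineno, why = _scan_for_bad_cell(path, delimiter, header)
        where = f"line {lineno}: {why}" if lineno else str(exc)
        raise ParseError(f"{path}: {where}") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ParseError(f"{path}: no data rows")
    try:
        matrix = df.to_numpy(dtype=float)
    except ValueError as exc:
        lineno, why = _scan_for_bad_cell(path, delimiter, header)
        where = f"line {lineno}: {why}" if lineno else str(exc)
        raise ParseError(f"{path}: {where}") from exc
    if not np.all(np.isfinite(matrix)):
        bad = int(np.argwhere(~np.isfinite(matrix))[0, 0]) + 1 + (1 if header else 0)
        raise ParseError(f"{path}: line {bad}: missing or non-finite value")
    labels = (
        [str(c) for c in df.columns]
        if header
        else [f"col{i + 1}" for i in range(df.shape[1])]
    )
    return matrix, labels


def write_matrix(path, matrix, labels=None, delimiter: str = ","):
    """Write a numeric matrix as delimited text.

    Values use the shortest decimal representation that round-trips
    exactly, so ``read_matrix`` recovers them bit-for-bit.
    """
    matrix = np.asarray(matrix)
    if labels is None:
        labels = [f"col{i + 1}" for i in range(matrix.shape[1])]
    df = pd.DataFrame(matrix, columns=list(labels))
    df.to_csv(path, sep=delimiter, index=False)
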