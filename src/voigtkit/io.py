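"""Delimited-text readers and JSON result envelopes.

Spectra, trajectories and PDFs travel as plain whitespace- or
tab-delimited text with ``#`` comment headers (there is no binding
standard for QENS ASCII exports; the header records units and the full
parameterization).  Results are machine-readable JSON envelopes carrying
the tool version, the resolved configuration (including defaulted values
and the seed), the payload, and any structured warnings, so every run can
be reproduced from its own output.
"""

from __future__ import annotations

import json
import warnings as _warnings
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = ["XYTable", "ResultEnvelope", "read_xy", "write_result",
           "read_result", "write_xy"]

SCHEMA_VERSION = 1


@dataclass
class XYTable:
    """1–3 numeric columns: abscissa, optional values, optional errors."""

    x: np.ndarray
    y: np.ndarray | None = None
    err: np.ndarray | None = None
    warnings: list[str] = field(default_factory=list)

    @property
    def n_cols(self) -> int:
        return 1 + (self.y is not None) + (self.err is not None)


def read_xy(path, expected_cols: int | None = None) -> XYTable:
    """Read a delimited text table of 1–3 numeric columns.

    ``#`` comments and blank lines are skipped.  A malformed numeric field
    raises with the offending line number; rows containing NaN are
    rejected the same way.  A non-increasing abscissa is sorted with a
    recorded warning (multi-column input only).
    """
    rows: list[list[float]] = []
    ncol = None
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            fields = line.replace(",", " ").split()
            try:
                vals = [float(f) for f in fields]
            except ValueError as exc:
                raise ValueError(
                    f"{path}: malformed numeric field on line {lineno}: {raw!r}"
                ) from exc
            if any(not np.isfinite(v) for v in vals):
                raise ValueError(f"{path}: non-finite value on line {lineno}")
            if ncol is None:
                ncol = len(vals)
                if not 1 <= ncol <= 3:
                    raise ValueError(f"{path}: expected 1-3 columns, got {ncol}")
            elif len(vals) != ncol:
                raise ValueError(
                    f"{path}: inconsistent column count on line {lineno}"
                )
            rows.append(vals)
    if not rows:
        raise ValueError(f"{path}: no data rows")
    if expected_cols is not None and ncol != expected_cols:
        raise ValueError(f"{path}: expected {expected_cols} columns, found {ncol}")
    arr = np.asarray(rows, dtype=float)
    warn: list[str] = []
    if ncol >= 2 and not np.all(np.diff(arr[:, 0]) > 0):
        order = np.argsort(arr[:, 0], kind="stable")
        arr = arr[order]
        msg = f"{path}: abscissa was not strictly increasing; sorted"
        warn.append(msg)
        _warnings.warn(msg)
    return XYTable(
        x=arr[:, 0],
        y=arr[:, 1] if ncol >= 2 else None,
        err=arr[:, 2] if ncol >= 3 else None,
        warnings=warn,
    )


def write_xy(path, columns, header: str = "") -> None:
    """Write numeric columns as tab-delimited text with a ``#`` header."""
    arr = np.column_stack([np.asarray(c, dtype=float) for c in columns])
    with open(path, "w", encoding="utf-8") as fh:
        for line in header.splitlines():
            fh.write(f"# {line}\n")
        for row in arr:
            fh.write("\t".join(f"{v:.10g}" for v in row) + "\n")


@dataclass
class ResultEnvelope:
    """Schema-versioned, machine-readable result of one command run."""

    command: str
    config: dict
    results: dict
    warnings: list[str] = field(default_factory=list)
    tool_version: str = ""
    schema_version: int = SCHEMA_VERSION

    def to_dict(self) -> dict:
        return asdict(self)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and obj == float("inf"):
        return "inf"
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def write_result(envelope: ResultEnvelope, path) -> None:
    """Serialize an envelope to JSON (round-trips losslessly)."""
    if not envelope.tool_version:
        from . import __version__
        envelope.tool_version = __version__
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(envelope.to_dict(), fh, indent=2, sort_keys=True,
                  default=_jsonable)
        fh.write("\n")


def read_result(path) -> ResultEnvelope:
    with open(path, "r", encoding="utf-8") as fh:
        d = json.load(fh)
    return ResultEnvelope(
        command=d["command"], config=d["config"], results=d["results"],
        warnings=d.get("warnings", []),
        tool_version=d.get("tool_version", ""),
        schema_version=d.get("schema_version", SCHEMA_VERSION),
    )
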