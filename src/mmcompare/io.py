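"""Readers, report assembly and layout rendering shared by the CLI."""

from __future__ import annotations

import json
import math
from importlib import resources
from typing import Any, Sequence

import numpy as np
import pandas as pd

from mmcompare.multi import GroupingLayout, PerformanceMatrix
from mmcompare.roc import ScoreSet

__all__ = [
    "make_report",
    "read_performance_matrix",
    "read_score_table",
    "render_layout",
    "report_to_json",
    "validate_report",
]

FLOAT_SIGNIFICANT_DIGITS = 6


def _read_table(path: str) -> pd.DataFrame:
    # sep=None sniffs comma/tab/semicolon
    df = pd.read_csv(path, sep=None, engine="python")
    if df.empty:
        raise ValueError(f"{path}: empty table")
    return df


def read_score_table(
    path: str,
    label_col: str,
    method_cols: Sequence[str],
    truthy: tuple = (1, "1", True, "true", "active"),
) -> list[ScoreSet]:
    """Read a per-compound score table into one ScoreSet per method column.

    The label column must be coded 1=active / 0=inactive (or one of the
    configurable truthy strings).  Rows stay aligned across methods.
    """
    df = _read_table(path)
    missing = [c for c in [label_col, *method_cols] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    raw = df[label_col]
    labels = raw.map(lambda v: v in truthy or str(v).lower() in {str(t).lower() for t in truthy})
    known = raw.map(lambda v: str(v).lower() in {"0", "1", "true", "false", "active", "inactive"})
    if not known.all():
        bad = sorted(set(raw[~known].astype(str)))
        raise ValueError(f"{path}: labels outside 0/1 coding: {bad}")
    sets = []
    for col in method_cols:
        scores = pd.to_numeric(df[col], errors="raise").to_numpy(dtype=float)
        sets.append(
            ScoreSet(
                tuple(scores[labels.to_numpy()]),
                tuple(scores[~labels.to_numpy()]),
                method_id=str(col),
            )
        )
    return sets


def read_performance_matrix(path: str, transpose: bool = False) -> PerformanceMatrix:
    """Read a matrix file: first column system labels, remaining columns methods.

    ``transpose=True`` for files written the other way around (first column
    method labels, remaining columns systems).
    """
    df = _read_table(path)
    index = df.iloc[:, 0].astype(str)
    if index.duplicated().any():
        raise ValueError(f"{path}: duplicate labels in first column")
    body = df.iloc[:, 1:]
    if body.isna().any().any():
        cells = [
            f"({index[i]}, {col})"
            for i in range(len(df))
            for col in body.columns
            if pd.isna(body.iloc[i][col])
        ]
        raise ValueError(f"{path}: missing cells {cells}")
    values = body.to_numpy(dtype=float)
    if transpose:
        methods, systems = tuple(index), tuple(map(str, body.columns))
        grid = values
    else:
        systems, methods = tuple(index), tuple(map(str, body.columns))
        grid = values.T
    return PerformanceMatrix(methods, systems, grid)


def _round_sig(x: float, sig: int) -> float:
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))


def _jsonify(obj: Any, sig: int) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonify(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v, sig) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonify(obj.tolist(), sig)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return _round_sig(v, sig) if math.isfinite(v) else str(v)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def make_report(
    operation: str,
    *,
    estimates: dict[str, float] | None = None,
    intervals: dict[str, Any] | None = None,
    statistics: dict[str, Any] | None = None,
    verdicts: dict[str, Any] | None = None,
    warnings: Sequence[str] = (),
    inputs: dict[str, Any] | None = None,
    seed: int | None = None,
) -> dict[str, Any]:
    """Assemble the standard machine-readable comparison report."""
    from mmcompare import __version__

    return {
        "tool": "mmcompare",
        "version": __version__,
        "operation": operation,
        "inputs": inputs or {},
        "estimates": estimates or {},
        "intervals": intervals or {},
        "statistics": statistics or {},
        "verdicts": verdicts or {},
        "warnings": list(warnings),
        "seed": seed,
    }


def report_to_json(report: dict[str, Any], sig: int = FLOAT_SIGNIFICANT_DIGITS) -> str:
    """Serialize with floats at a fixed number of significant digits."""
    return json.dumps(_jsonify(report, sig), indent=2, sort_keys=True)


def _load_schema() -> dict[str, Any]:
    with resources.files("mmcompare").joinpath("report_schema.json").open() as fh:
        return json.load(fh)


_TYPE_MAP = {
    "object": dict,
    "array": list,
    "string": str,
    "number": (int, float),
    "integer": int,
    "boolean": bool,
    "null": type(None),
}


def validate_report(report: dict[str, Any]) -> None:
    """Check a report against the published schema (required keys + types).

    Intentionally small: this validates the subset of JSON Schema the
    shipped schema file actually uses, so no external validator is needed.
    """
    schema = _load_schema()
    for key in schema.get("required", []):
        if key not in report:
            raise ValueError(f"report missing required field {key!r}")
    for key, spec in schema.get("properties", {}).items():
        if key not in report:
            continue
        expected = spec.get("type")
        if expected is None:
            continue
        types = expected if isinstance(expected, list) else [expected]
        ok = any(isinstance(report[key], _TYPE_MAP[t]) for t in types)
        # bool is an int subclass; don't let it satisfy "number"
        if isinstance(report[key], bool) and "boolean" not in types:
            ok = False
        if not ok:
            raise ValueError(f"report field {key!r} has wrong type")


def render_layout(gl: GroupingLayout, format: str = "text") -> str:
    """Render a grouping layout as deterministic text or SVG."""
    if format == "text":
        return _render_text(gl)
    if format == "svg":
        return _render_svg(gl)
    raise ValueError("format must be 'text' or 'svg'")


def _render_text(gl: GroupingLayout) -> str:
    lines = []
    for ci, col in enumerate(gl.columns, start=1):
        members = ", ".join(f"{m} ({gl.means[m]:.3f})" for m in col)
        lines.append(f"column {ci}: {members}")
    for a, b in gl.edges:
        lines.append(f"equivalent across columns: {a} ~ {b}")
    return "\n".join(lines) + "\n"


def _render_svg(gl: GroupingLayout) -> str:
    """Hand-built SVG: one circle per method, columns left to right, dotted
    lines for cross-column equivalences.  Byte-stable for a fixed layout."""
    r = 32
    dx, dy = 110, 90
    pad = 60
    pos: dict[str, tuple[int, int]] = {}
    for ci, col in enumerate(gl.columns):
        for ri, label in enumerate(col):
            pos[label] = (pad + ci * dx, pad + ri * dy)
    width = pad * 2 + dx * max(len(gl.columns) - 1, 0)
    height = pad * 2 + dy * (max((len(c) for c in gl.columns), default=1) - 1)
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" height="{height}" '
        f'viewBox="0 0 {width} {height}">'
    ]
    for a, b in gl.edges:
        (x1, y1), (x2, y2) = pos[a], pos[b]
        parts.append(
            f'<line x1="{x1}" y1="{y1}" x2="{x2}" y2="{y2}" '
            'stroke="black" stroke-dasharray="6,5" stroke-width="1.5"/>'
        )
    for label, (x, y) in pos.items():
        mean = gl.means[label]
        parts.append(
            f'<circle cx="{x}" cy="{y}" r="{r}" fill="white" stroke="black" stroke-width="2"/>'
        )
        parts.append(
            f'<text x="{x}" y="{y - 4}" text-anchor="middle" font-size="14" '
            f'font-family="sans-serif">{label}</text>'
        )
        parts.append(
            f'<text x="{x}" y="{y + 14}" text-anchor="middle" font-size="11" '
            f'font-family="sans-serif">{mean:.3f}</text>'
        )
    parts.append("</svg>")
    return "\n".join(parts) + "\n"
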