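"""TSV/JSON file dialects for curves, traces and reports.

All instrument-like data travel as plain TSV with units baked into the
column names (lengths nm, forces pN, concentrations nM); metadata rides in
a sidecar JSON next to the data file. Extensions are stored as total nm;
per-bp values are always derived, never stored. Reports are versioned JSON
with deterministic key order.
"""

from __future__ import annotations

import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .afm import Annotation, Trace2D
from .polymer import ForceExtensionCurve
from .titration import TitrationSeries

__all__ = [
    "ParseError",
    "read_curve",
    "write_curve",
    "read_traces",
    "write_traces",
    "read_titration",
    "write_titration",
    "write_report",
]

SCHEMA_VERSION = "1"

CURVE_COLUMNS = ["extension_nm", "force_pN"]
TRACE_COLUMNS = ["molecule_id", "point_index", "x_nm", "y_nm"]
ANNOTATION_COLUMNS = ["molecule_id", "kind", "start_index", "end_index"]
TITRATION_COLUMNS = ["conc_nM", "value", "sigma", "N"]


class ParseError(ValueError):
    """Malformed input file; the message names the file, row and field."""


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def _read_tsv(path: Path, columns: list[str]) -> pd.DataFrame:
    if not path.exists():
        raise ParseError(f"{path}: file not found")
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:
        raise ParseError(f"{path}: unreadable TSV ({exc})") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    return df


def _numeric(df: pd.DataFrame, path: Path, col: str) -> np.ndarray:
    converted = pd.to_numeric(df[col], errors="coerce")
    bad = converted.isna() & df[col].notna()
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ParseError(
            f"{path}: non-numeric value {df[col].iloc[row]!r} in column "
            f"{col!r} at data row {row + 1}"
        )
    if converted.isna().any():
        row = int(np.flatnonzero(converted.isna())[0])
        raise ParseError(f"{path}: empty cell in column {col!r} at data row {row + 1}")
    return converted.to_numpy(dtype=float)


def read_curve(path) -> ForceExtensionCurve:
    """Read a force-extension curve TSV plus its metadata sidecar JSON."""
    path = Path(path)
    df = _read_tsv(path, CURVE_COLUMNS)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise ParseError(f"{sidecar}: missing metadata sidecar for {path.name}")
    try:
        meta = json.loads(sidecar.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{sidecar}: invalid JSON ({exc})") from exc
    for key in ("n_bp",):
        if key not in meta:
            raise ParseError(f"{sidecar}: missing required field {key!r}")
    extension = _numeric(df, path, "extension_nm")
    force = _numeric(df, path, "force_pN")
    if "n_rows" in meta and int(meta["n_rows"]) != len(df):
        raise ParseError(
            f"{path}: row count {len(df)} disagrees with sidecar n_rows="
            f"{meta['n_rows']} (truncated file?)"
        )
    return ForceExtensionCurve(
        extension=extension,
        force=force,
        n_bp=int(meta["n_bp"]),
        concentration=float(meta.get("concentration_nM", 0.0)),
        pulling_rate=float(meta.get("pulling_rate_nm_s", float("nan"))),
        direction=str(meta.get("direction", "extend")),
    )


def write_curve(curve: ForceExtensionCurve, path) -> None:
    """Write a curve as TSV plus sidecar JSON (with a row-count checksum)."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "extension_nm": [f"{v:.9g}" for v in curve.extension],
            "force_pN": [f"{v:.9g}" for v in curve.force],
        }
    )
    df.to_csv(path, sep="\t", index=False)
    meta = {
        "n_bp": int(curve.n_bp),
        "concentration_nM": float(curve.concentration),
        "pulling_rate_nm_s": None
        if np.isnan(curve.pulling_rate)
        else float(curve.pulling_rate),
        "direction": curve.direction,
        "n_rows": int(curve.extension.size),
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


def read_traces(path, annotations_path=None, n_bp: int = 4361) -> list[Trace2D]:
    """Read traced molecules (and optional annotations) grouped by molecule id."""
    path = Path(path)
    df = _read_tsv(path, TRACE_COLUMNS)
    df["point_index"] = _numeric(df, path, "point_index").astype(int)
    df["x_nm"] = _numeric(df, path, "x_nm")
    df["y_nm"] = _numeric(df, path, "y_nm")

    ann_by_id: dict[str, list[Annotation]] = {}
    if annotations_path is not None:
        apath = Path(annotations_path)
        adf = _read_tsv(apath, ANNOTATION_COLUMNS)
        adf["start_index"] = _numeric(adf, apath, "start_index").astype(int)
        adf["end_index"] = _numeric(adf, apath, "end_index").astype(int)
        known = set(df["molecule_id"])
        for _, row in adf.iterrows():
            if row["molecule_id"] not in known:
                raise ParseError(
                    f"{apath}: annotation references unknown molecule "
                    f"{row['molecule_id']!r}"
                )
            ann_by_id.setdefault(row["molecule_id"], []).append(
                Annotation(
                    kind=row["kind"],
                    start_index=int(row["start_index"]),
                    end_index=int(row["end_index"]),
                )
            )
    traces = []
    for mol_id, grp in df.groupby("molecule_id", sort=True):
        grp = grp.sort_values("point_index")
        traces.append(
            Trace2D(
                molecule_id=str(mol_id),
                points=grp[["x_nm", "y_nm"]].to_numpy(),
                n_bp=n_bp,
                annotations=ann_by_id.get(mol_id, []),
            )
        )
    return traces


def write_traces(traces: list[Trace2D], path, annotations_path=None) -> None:
    """Write traces as TSV (and their annotations, when a path is given)."""
    rows = []
    for t in traces:
        for i, (x, y) in enumerate(t.points):
            rows.append((t.molecule_id, i, f"{x:.9g}", f"{y:.9g}"))
    pd.DataFrame(rows, columns=TRACE_COLUMNS).to_csv(Path(path), sep="\t", index=False)
    if annotations_path is not None:
        arows = [
            (t.molecule_id, a.kind, a.start_index, a.end_index)
            for t in traces
            for a in t.annotations
        ]
        pd.DataFrame(arows, columns=ANNOTATION_COLUMNS).to_csv(
            Path(annotations_path), sep="\t", index=False
        )


def read_titration(path, observable: str) -> TitrationSeries:
    """Read a titration table TSV (conc_nM, value, sigma, N)."""
    path = Path(path)
    df = _read_tsv(path, TITRATION_COLUMNS)
    pts = np.column_stack([_numeric(df, path, c) for c in TITRATION_COLUMNS])
    return TitrationSeries(observable=observable, points=pts)


def write_titration(series: TitrationSeries, path) -> None:
    pd.DataFrame(series.points, columns=TITRATION_COLUMNS).to_csv(
        Path(path), sep="\t", index=False
    )


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if obj is None or isinstance(obj, (bool, int, float, str)):
        return obj
    raise TypeError(f"cannot serialise {type(obj).__name__} into a report")


def write_report(results: dict, path, seed: int | None = None, config: dict | None = None) -> dict:
    """Write a versioned JSON analysis report; returns the document written.

    The document carries tool and schema versions, the seed, an echo of the
    configuration, and the per-analysis result blocks; keys are sorted so
    identical runs produce identical files (up to the timestamp).
    """
    doc = {
        "tool_version": __version__,
        "schema_version": SCHEMA_VERSION,
        "created": datetime.now(timezone.utc).isoformat(),
        "seed": seed,
        "config_echo": _jsonable(config or {}),
        "results": _jsonable(results),
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    return doc
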