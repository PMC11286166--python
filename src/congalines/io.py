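"""Readers and writers for the package's on-disk formats.

Formats (all plain text, metres and degrees unless the column name says mm):

* point maps — CSV with header
  ``id,x_m,y_m[,taxon,frond_length_mm,frond_width_mm,stem_length_mm,stem_width_mm,orientation_deg]``
* discs — CSV ``id,cx_m,cy_m,a_m,b_m,azimuth_deg``
* windows — GeoJSON Polygon; first ring exterior, subsequent rings holes,
  coordinates in metres (local metric grid, no projection support)
* scan tables — TSV ``r_mm observed model expected p_upper p_lower direction
  significant``
* results — JSON with deterministic key ordering

The deposited survey maps live in bespoke figshare layouts; converting them
to this CSV/GeoJSON schema is a one-off reshaping step left to a small user
script.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import SchemaError, UnsupportedGeometryError
from .surfaces import SurfaceMap, Window

__all__ = [
    "RunConfig",
    "read_point_map",
    "read_window",
    "read_discs",
    "write_scan_tsv",
    "write_json",
    "write_run_log",
]

_POINT_REQUIRED = ["id", "x_m", "y_m"]
_MARK_COLUMNS = [
    "taxon",
    "frond_length_mm",
    "frond_width_mm",
    "stem_length_mm",
    "stem_width_mm",
    "orientation_deg",
]


@dataclass
class RunConfig:
    """Run settings; all interface lengths in mm, converted to metres on use."""

    theta_deg: float = 30.0
    r_min_mm: float = 5.0
    r_max_mm: float = 50.0
    step_mm: float = 1.0
    alpha: float = 0.05
    gof_m: int = 99
    bandwidth_mm: float | None = None
    contrast_q: float = 0.25
    contrast_p: float = 2.0
    n_sims: int = 500
    seed: int = 0
    bonferroni: bool = False

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def read_point_map(path, window: Window | None = None) -> SurfaceMap:
    """Read a specimen point map CSV into a SurfaceMap.

    When no window is supplied, the points' bounding box (padded by 1% of its
    diagonal) is used so the surface is self-contained; pass the surveyed
    window for any real analysis, since the mapped area enters every
    expectation.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - surface file/line context
        raise SchemaError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = [c for c in _POINT_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    for col in ("x_m", "y_m"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if df[col].isna().any() or bad.any():
            row = int(np.argmax((df[col].isna() | bad).to_numpy()))
            raise SchemaError(
                f"{path}: non-numeric {col} at data row {row + 1}"
            )
    pts = df[["x_m", "y_m"]].to_numpy(dtype=float)
    if len(pts) != len(np.unique(pts, axis=0)):
        import warnings

        warnings.warn(f"{path}: duplicate coordinates present", stacklevel=2)
    marks = {}
    for col in _MARK_COLUMNS:
        if col in df.columns:
            vals = df[col].to_numpy()
            if col == "orientation_deg":
                vals = np.asarray(vals, dtype=float) % 360.0
            marks[col] = vals
    if window is None:
        if len(pts) == 0:
            raise SchemaError(f"{path}: empty point map and no window given")
        lo = pts.min(axis=0)
        hi = pts.max(axis=0)
        pad = max(float(np.hypot(*(hi - lo))) * 0.01, 1e-6)
        lo, hi = lo - pad, hi + pad
        window = Window(
            np.array([[lo[0], lo[1]], [hi[0], lo[1]], [hi[0], hi[1]], [lo[0], hi[1]]])
        )
    return SurfaceMap(points=pts, window=window, marks=marks)


def read_discs(path) -> np.ndarray:
    """Read a disc-ellipse CSV: columns id,cx_m,cy_m,a_m,b_m,azimuth_deg."""
    path = Path(path)
    df = pd.read_csv(path)
    need = ["cx_m", "cy_m", "a_m", "b_m", "azimuth_deg"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    return df[need].to_numpy(dtype=float)


def _rings_of(geom: dict, path) -> list:
    if geom.get("type") != "Polygon":
        raise UnsupportedGeometryError(
            f"{path}: unsupported GeoJSON geometry {geom.get('type')!r}; "
            "only Polygon is accepted"
        )
    rings = geom.get("coordinates") or []
    if not rings:
        raise SchemaError(f"{path}: Polygon with no rings")
    return rings


def read_window(path) -> Window:
    """Read a GeoJSON Polygon window (first ring exterior, rest holes)."""
    path = Path(path)
    try:
        with open(path) as fh:
            data = json.load(fh)
    except FileNotFoundError:
        raise SchemaError(f"{path}: window file not found") from None
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: invalid JSON ({exc})") from exc
    geom = data
    if data.get("type") == "Feature":
        geom = data["geometry"]
    elif data.get("type") == "FeatureCollection":
        feats = data.get("features") or []
        if len(feats) != 1:
            raise SchemaError(
                f"{path}: expected exactly one feature, got {len(feats)}"
            )
        geom = feats[0]["geometry"]
    rings = _rings_of(geom, path)
    ext = np.asarray(rings[0], dtype=float)
    holes = tuple(np.asarray(r, dtype=float) for r in rings[1:])
    # GeoJSON rings repeat the first vertex; Window wants open rings
    if len(ext) > 3 and np.allclose(ext[0], ext[-1]):
        ext = ext[:-1]
    holes = tuple(
        h[:-1] if len(h) > 3 and np.allclose(h[0], h[-1]) else h for h in holes
    )
    return Window(ext, holes)


def write_window(window: Window, path) -> None:
    """Write a window as a GeoJSON Polygon."""
    rings = [np.vstack([window.exterior, window.exterior[:1]]).tolist()]
    for h in window.holes:
        rings.append(np.vstack([h, h[:1]]).tolist())
    with open(path, "w") as fh:
        json.dump({"type": "Polygon", "coordinates": rings}, fh, indent=2)


def write_point_map(surface: SurfaceMap, path) -> None:
    """Write a SurfaceMap's points (and marks) to the point-map CSV schema."""
    df = pd.DataFrame(
        {
            "id": np.arange(surface.n),
            "x_m": surface.points[:, 0],
            "y_m": surface.points[:, 1],
        }
    )
    for col, vals in surface.marks.items():
        df[col] = vals
    df.to_csv(path, index=False, float_format="%.6f")


def scan_to_frame(result) -> pd.DataFrame:
    """SignificanceScan rows as a DataFrame in the TSV column order."""
    return pd.DataFrame(
        {
            "r_mm": [row.r_mm for row in result.rows],
            "observed": [row.observed for row in result.rows],
            "model": [row.model for row in result.rows],
            "expected": [row.expected for row in result.rows],
            "p_upper": [row.p_upper for row in result.rows],
            "p_lower": [row.p_lower for row in result.rows],
            "direction": [row.direction for row in result.rows],
            "significant": [row.significant for row in result.rows],
        }
    )


def write_scan_tsv(result, path) -> None:
    scan_to_frame(result).to_csv(path, sep="\t", index=False, float_format="%.6g")


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (frozenset, set)):
        return sorted(_jsonable(x) for x in obj)
    if isinstance(obj, (list, tuple)):
        return [_jsonable(x) for x in obj]
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    return obj


def write_json(obj, path) -> None:
    """JSON writer with deterministic key order and numpy-safe encoding."""
    with open(path, "w") as fh:
        json.dump(_jsonable(obj), fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_run_log(path, seed, config=None, extra=None) -> None:
    """Record what a run needs to be replayed: seed, config, version."""
    from . import __version__

    log = {"seed": seed, "congalines_version": __version__}
    if config is not None:
        log["config"] = _jsonable(config)
    if extra:
        log.update(_jsonable(extra))
    write_json(log, path)
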