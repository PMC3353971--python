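"""Readers and writers for point patterns, regions, curves and masks.

Formats are deliberately plain: CSV with a mandatory header and '.' decimal
separator, JSON with 17 significant digits (so round-trips are bit-exact on
the decimal representation), YAML for run configuration, and multi-page TIFF
z-stacks for segmented-nucleus masks.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np

from .fstat import Envelope, FCurve
from .geometry import HalfAxisParams, PiecewiseEllipsoidRegion, Region, VoxelMaskRegion
from .processes import PointPattern

__all__ = [
    "read_point_pattern",
    "write_point_pattern",
    "read_region_params",
    "write_region_params",
    "read_mask_region",
    "write_curve_csv",
    "write_envelope_csv",
    "write_curve_json",
    "write_envelope_json",
]

_FLOAT_FMT = "%.17g"


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("csv", "json"):
        return suffix
    raise ValueError(f"cannot infer format from {path.name!r}; pass fmt=")


def write_point_pattern(pattern: PointPattern, path, fmt: str | None = None) -> None:
    """Write a pattern as x,y,z CSV (header required) or JSON."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    pts = pattern.points
    if fmt == "csv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["x", "y", "z"])
            for row in pts:
                writer.writerow([_FLOAT_FMT % v for v in row])
    elif fmt == "json":
        payload = {"points": [[float(_FLOAT_FMT % v) for v in row] for row in pts]}
        path.write_text(json.dumps(payload), encoding="utf-8")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_point_pattern(path, region: Region, fmt: str | None = None) -> PointPattern:
    """Read a pattern from CSV (columns x,y,z) or JSON and attach its region.

    Malformed rows raise with the offending line number; non-finite
    coordinates are rejected.
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "csv":
        rows: list[list[float]] = []
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.reader(fh)
            try:
                header = next(reader)
            except StopIteration:
                raise ValueError(f"{path.name}: empty file") from None
            cols = [h.strip().lower() for h in header]
            if cols[:3] != ["x", "y", "z"]:
                raise ValueError(f"{path.name}: header must be x,y,z, got {header}")
            for lineno, row in enumerate(reader, start=2):
                if not row or all(not c.strip() for c in row):
                    continue
                if len(row) < 3:
                    raise ValueError(f"{path.name}:{lineno}: expected 3 columns")
                try:
                    vals = [float(c) for c in row[:3]]
                except ValueError as exc:
                    raise ValueError(f"{path.name}:{lineno}: {exc}") from None
                rows.append(vals)
        if not rows:
            raise ValueError(f"{path.name}: no data rows")
        pts = np.asarray(rows)
    elif fmt == "json":
        payload = json.loads(path.read_text(encoding="utf-8"))
        pts = np.asarray(payload["points"], dtype=float)
        if pts.size == 0:
            raise ValueError(f"{path.name}: no points")
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if not np.isfinite(pts).all():
        raise ValueError(f"{path.name}: non-finite coordinate")
    return PointPattern(pts, region)


def write_region_params(params: HalfAxisParams, path) -> None:
    Path(path).write_text(json.dumps(params.to_dict(), indent=2), encoding="utf-8")


def read_region_params(path) -> PiecewiseEllipsoidRegion:
    """Read piecewise-ellipsoid semi-axis parameters from JSON."""
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    return PiecewiseEllipsoidRegion(HalfAxisParams.from_dict(payload))


def read_mask_region(path, spacing: tuple[float, float, float]) -> VoxelMaskRegion:
    """Read a binary/label TIFF z-stack as a region with physical units.

    ``spacing`` gives micrometres per voxel along (x, y, z); it must be
    fully specified since confocal stacks are typically anisotropic.
    """
    import tifffile

    if spacing is None or len(tuple(spacing)) != 3:
        raise ValueError("spacing must be three values (sx, sy, sz)")
    stack = tifffile.imread(str(path))
    if stack.ndim == 2:
        stack = stack[None]
    return VoxelMaskRegion(stack > 0, spacing)


def write_curve_csv(curve: FCurve, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["r", "value"])
        for r, v in zip(curve.r, curve.values):
            writer.writerow([_FLOAT_FMT % r, _FLOAT_FMT % v])


def write_envelope_csv(env: Envelope, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["r", "lower", "upper"])
        for r, lo, hi in zip(env.r, env.lower, env.upper):
            writer.writerow([_FLOAT_FMT % r, _FLOAT_FMT % lo, _FLOAT_FMT % hi])


def write_curve_json(curve: FCurve, path, metadata: dict | None = None) -> None:
    """Curve as JSON with optional provenance metadata (n_ref, seed, ...)."""
    payload = {
        "r": [float(_FLOAT_FMT % v) for v in curve.r],
        "values": [float(_FLOAT_FMT % v) for v in curve.values],
        "metadata": metadata or {},
    }
    Path(path).write_text(json.dumps(payload), encoding="utf-8")


def write_envelope_json(env: Envelope, path, metadata: dict | None = None) -> None:
    payload = {
        "r": [float(_FLOAT_FMT % v) for v in env.r],
        "lower": [float(_FLOAT_FMT % v) for v in env.lower],
        "upper": [float(_FLOAT_FMT % v) for v in env.upper],
        "level": env.level,
        "n_null": env.n_null,
        "metadata": metadata or {},
    }
    Path(path).write_text(json.dumps(payload), encoding="utf-8")
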