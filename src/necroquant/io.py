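"""File I/O: TIFF stacks, ROI files, and tidy CSV tables.

ROI files are JSON: a top-level ``rois`` object mapping ROI names to either
``{"type": "polygon", "vertices": [[row, col], ...]}`` or
``{"type": "annulus", "outer": [[row, col], ...], "inner": [...]}``.
All tables are UTF-8 CSV; times are minutes post-first embryonic division.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .geometry import AnnulusROI, Polygon

__all__ = ["read_stack", "read_rois", "write_rois", "measure_rois"]


def read_stack(path) -> np.ndarray:
    """Read a single- or multi-page TIFF as a (T, H, W) float array."""
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None, ...]
    if arr.ndim != 3:
        raise ValueError(f"expected a 2-D image or a stack of them, got shape {arr.shape}")
    return arr.astype(float)


def read_rois(path) -> dict[str, Polygon | AnnulusROI]:
    """Load named ROIs from a JSON file."""
    data = json.loads(Path(path).read_text())
    rois: dict[str, Polygon | AnnulusROI] = {}
    for name, spec in data["rois"].items():
        kind = spec.get("type", "polygon")
        if kind == "polygon":
            rois[name] = Polygon(np.asarray(spec["vertices"], dtype=float))
        elif kind == "annulus":
            rois[name] = AnnulusROI(
                outer=Polygon(np.asarray(spec["outer"], dtype=float)),
                inner=Polygon(np.asarray(spec["inner"], dtype=float)),
            )
        else:
            raise ValueError(f"unknown ROI type {kind!r} for {name!r}")
    return rois


def write_rois(rois: dict[str, Polygon | AnnulusROI], path) -> None:
    out = {}
    for name, roi in rois.items():
        if isinstance(roi, AnnulusROI):
            out[name] = {
                "type": "annulus",
                "outer": roi.outer.vertices.tolist(),
                "inner": roi.inner.vertices.tolist(),
            }
        else:
            out[name] = {"type": "polygon", "vertices": roi.vertices.tolist()}
    Path(path).write_text(json.dumps({"schema_version": 1, "rois": out}, indent=2))


def measure_rois(stack: np.ndarray, rois: dict[str, Polygon | AnnulusROI]) -> pd.DataFrame:
    """Measure every ROI on every frame; one row per (frame, ROI).

    Polygons report total signal, pixel area, and unit intensity; annuli
    report the ring unit intensity with the ring pixel area.
    """
    from .quantify import annulus_unit_intensity, measure_region

    rows = []
    for t in range(stack.shape[0]):
        frame = stack[t]
        for name, roi in rois.items():
            if isinstance(roi, AnnulusROI):
                ups = annulus_unit_intensity(frame, roi)
                outer = measure_region(frame, roi.outer)
                inner = measure_region(frame, roi.inner)
                rows.append(
                    {"frame": t, "roi": name, "kind": "annulus",
                     "total_signal": outer.total_signal - inner.total_signal,
                     "area_px": outer.area - inner.area, "unit_intensity": ups}
                )
            else:
                m = measure_region(frame, roi)
                rows.append(
                    {"frame": t, "roi": name, "kind": "polygon",
                     "total_signal": m.total_signal, "area_px": m.area,
                     "unit_intensity": m.unit_intensity}
                )
    return pd.DataFrame(rows)
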