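"""Defaunation summaries within overlay masks and administrative zones.

Masks: intact forest (IF), wilderness areas (WA, human footprint <= 2),
protected areas (IUCN I-IV), or arbitrary boolean grids. Thresholding is
strict at DI > 0.1 (defaunated) and DI > 0.7, non-strict at HF <= 2.
Cell-based confidence intervals treat cells as independent (no spatial
autocorrelation adjustment; documented limitation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .raster import Raster

__all__ = ["DEFAUNATED_THRESHOLD", "WILDERNESS_HF_MAX", "OverlayMask",
           "OverlaySummary", "area_fraction", "zonal_summary",
           "wilderness_mask", "summarize_mask"]

DEFAUNATED_THRESHOLD = 0.1   # DI strictly above => defaunated
WILDERNESS_HF_MAX = 2.0      # HF <= 2 => wilderness


@dataclass
class OverlayMask:
    name: str
    mask: np.ndarray            # boolean grid
    provenance: str = ""        # e.g. "IF", "WA(HF<=2)", "PA(IUCN I-IV)"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)


@dataclass
class OverlaySummary:
    name: str
    total_area_km2: float
    defaunated_area_km2: float
    defaunated_fraction: float
    intact_fraction: float
    mean_di: float
    ci_halfwidth: float
    n_cells: int

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "name", "total_area_km2", "defaunated_area_km2",
            "defaunated_fraction", "intact_fraction", "mean_di",
            "ci_halfwidth", "n_cells")}


def area_fraction(di: Raster, mask: np.ndarray | None = None,
                  threshold: float = DEFAUNATED_THRESHOLD
                  ) -> tuple[float, float]:
    """(area km², fraction) of valid masked cells with DI strictly above
    ``threshold``; area = cell count x cell area."""
    data = di.data
    if mask is None:
        mask = np.ones(di.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != di.shape:
        raise ValueError("mask geometry mismatch")
    valid = mask & np.isfinite(data)
    n = int(valid.sum())
    cell_area = di.cell_size ** 2
    if n == 0:
        return 0.0, 0.0
    above = int((data[valid] > threshold).sum())
    return above * cell_area, above / n


def summarize_mask(di: Raster, mask: OverlayMask,
                   threshold: float = DEFAUNATED_THRESHOLD) -> OverlaySummary:
    data = di.data
    if mask.mask.shape != di.shape:
        raise ValueError("mask geometry mismatch")
    valid = mask.mask & np.isfinite(data)
    n = int(valid.sum())
    cell_area = di.cell_size ** 2
    if n == 0:
        return OverlaySummary(mask.name, 0.0, 0.0, np.nan, np.nan, np.nan,
                              np.nan, 0)
    vals = data[valid]
    area_above, frac_above = area_fraction(di, mask.mask, threshold)
    sd = float(np.std(vals, ddof=1)) if n > 1 else np.nan
    ci = 1.96 * sd / np.sqrt(n) if n > 1 else np.nan
    return OverlaySummary(
        name=mask.name,
        total_area_km2=n * cell_area,
        defaunated_area_km2=area_above,
        defaunated_fraction=frac_above,
        intact_fraction=1.0 - frac_above,
        mean_di=float(np.mean(vals)),
        ci_halfwidth=float(ci) if np.isfinite(ci) else np.nan,
        n_cells=n,
    )


def zonal_summary(di: Raster, zones: np.ndarray) -> dict:
    """Per-zone mean DI with a 95% normal CI across cells.

    ``zones`` is a categorical grid (country codes etc.); NaN zone cells are
    ignored. Zones with no valid DI cells are reported with NaN statistics;
    single-cell zones are flagged as degenerate.
    """
    zones = np.asarray(zones)
    if zones.shape != di.shape:
        raise ValueError("zone grid geometry mismatch")
    data = di.data
    out = {}
    zvals = zones[~_is_nan(zones)]
    for z in np.unique(zvals):
        sel = (zones == z) & np.isfinite(data)
        n = int(sel.sum())
        if n == 0:
            out[z] = {"mean_di": np.nan, "ci_halfwidth": np.nan, "n_cells": 0,
                      "degenerate": True}
            continue
        vals = data[sel]
        mean = float(np.mean(vals))
        if n > 1:
            ci = float(1.96 * np.std(vals, ddof=1) / np.sqrt(n))
            degenerate = False
        else:
            ci = np.nan
            degenerate = True
        out[z] = {"mean_di": mean, "ci_halfwidth": ci, "n_cells": n,
                  "degenerate": degenerate}
    return out


def _is_nan(arr: np.ndarray) -> np.ndarray:
    if np.issubdtype(arr.dtype, np.floating):
        return np.isnan(arr)
    return np.zeros(arr.shape, dtype=bool)


def wilderness_mask(hf: Raster, hf_max: float = WILDERNESS_HF_MAX) -> OverlayMask:
    """Wilderness = human footprint <= 2 (non-strict at the boundary)."""
    mask = np.isfinite(hf.data) & (hf.data <= hf_max)
    return OverlayMask(name="wilderness", mask=mask,
                       provenance=f"WA(HF<={hf_max:g})")
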