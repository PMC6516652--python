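"""Covariate conditioning and gridded predictor layers.

Covers z-standardization (fitting uses standardized covariates for model
selection, projections use unstandardized refits), the pairwise collinearity
screen, temporal interpolation of travel time between its two endpoint maps,
livestock biomass conversion, and the distance-to-nearest-settlement layer on
a planar equal-area grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .raster import Raster

__all__ = [
    "StandardizationStats",
    "PredictorStack",
    "standardize",
    "unstandardize",
    "collinearity_screen",
    "interpolate_travel_time",
    "livestock_biomass",
    "distance_to_nearest_settlement",
    "load_settlements",
]


@dataclass
class StandardizationStats:
    """Per-variable mean/sd computed on the fitting records."""

    mean: dict[str, float]
    sd: dict[str, float]

    def __post_init__(self) -> None:
        for name, s in self.sd.items():
            if not s > 0:
                raise ValueError(f"standard deviation of {name!r} must be > 0")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, variables) -> "StandardizationStats":
        mean, sd = {}, {}
        for v in variables:
            x = np.asarray(df[v], dtype=float)
            s = float(np.std(x, ddof=1))
            if not s > 0:
                raise ValueError(f"variable {v!r} has zero variance")
            mean[v] = float(np.mean(x))
            sd[v] = s
        return cls(mean=mean, sd=sd)


def standardize(values, stats: StandardizationStats, variable: str):
    """(x - mean) / sd for one named variable."""
    if variable not in stats.sd:
        raise KeyError(f"no standardization stats for {variable!r}")
    return (np.asarray(values, dtype=float) - stats.mean[variable]) / stats.sd[variable]


def unstandardize(z, stats: StandardizationStats, variable: str):
    return np.asarray(z, dtype=float) * stats.sd[variable] + stats.mean[variable]


def collinearity_screen(df: pd.DataFrame, variables, threshold: float = 0.5):
    """All variable pairs with |Pearson r| >= threshold, |r| descending.

    The screen only flags; dropping a member of a flagged pair is a user
    decision (the empirical analysis dropped literacy, keeping stunting, at
    r = -0.59).
    """
    if len(df) < 3:
        raise ValueError("need at least 3 complete records")
    X = df[list(variables)].to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in screened variables")
    corr = np.corrcoef(X, rowvar=False)
    flagged = []
    for i in range(len(variables)):
        for j in range(i + 1, len(variables)):
            r = float(corr[i, j])
            if abs(r) >= threshold:
                flagged.append((variables[i], variables[j], r))
    flagged.sort(key=lambda t: -abs(t[2]))
    return flagged


def interpolate_travel_time(t_2000: float, t_2015: float, year: float) -> float:
    """Travel time at ``year``, linear between the 2000 and 2015 endpoint
    maps and clamped outside that window."""
    for name, t in (("t_2000", t_2000), ("t_2015", t_2015)):
        if not np.isfinite(t) or t < 0:
            raise ValueError(f"{name} must be finite and >= 0")
    if year <= 2000:
        return float(t_2000)
    if year >= 2015:
        return float(t_2015)
    w = (year - 2000) / 15.0
    return float(t_2000 + (t_2015 - t_2000) * w)


def livestock_biomass(densities: dict[str, float],
                      mean_weights: dict[str, float]) -> float:
    """Sum over livestock types of density (head/km^2) x mean weight (kg)."""
    total = 0.0
    for kind, dens in densities.items():
        if dens < 0:
            raise ValueError(f"negative density for {kind!r}")
        if kind not in mean_weights:
            raise KeyError(f"no mean weight for livestock type {kind!r}")
        w = mean_weights[kind]
        if w < 0:
            raise ValueError(f"negative mean weight for {kind!r}")
        total += dens * w
    return float(total)


@dataclass
class PredictorStack:
    """Named co-registered grid layers on a common equal-area grid."""

    layers: dict[str, Raster] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.check_aligned()

    def check_aligned(self) -> None:
        rasters = list(self.layers.values())
        for r in rasters[1:]:
            if not r.same_geometry(rasters[0]):
                raise ValueError("predictor layers are not co-registered")

    def __getitem__(self, name: str) -> Raster:
        return self.layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.layers.values())).shape

    @property
    def cell_size(self) -> float:
        return next(iter(self.layers.values())).cell_size

    @property
    def template(self) -> Raster:
        return next(iter(self.layers.values()))

    def valid_mask(self, names=None) -> np.ndarray:
        """Cells valid (non-nodata) in every requested layer."""
        names = self.names if names is None else names
        mask = np.ones(self.shape, dtype=bool)
        for n in names:
            mask &= self.layers[n].valid
        return mask

    def add(self, name: str, raster: Raster) -> None:
        if self.layers and not raster.same_geometry(self.template):
            raise ValueError(f"layer {name!r} is not aligned with the stack")
        self.layers[name] = raster


def distance_to_nearest_settlement(points: np.ndarray, template: Raster,
                                   exclude_urban: bool = True) -> Raster:
    """Euclidean distance (km) from each cell center to the nearest
    settlement point.

    ``points`` is an (m, 2) array of (x, y), or (m, 3) with an ``is_urban``
    flag in the third column; urban points are excluded as access points by
    default (rural settlements drive hunting access).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] == 0:
        raise ValueError("empty settlement point set")
    if pts.shape[1] == 3 and exclude_urban:
        pts = pts[pts[:, 2] == 0]
        if pts.shape[0] == 0:
            raise ValueError("all settlement points are urban")
    xs, ys = template.cell_centers()
    centers = np.column_stack([xs.ravel(), ys.ravel()])
    # all-pairs min; grids here are small enough for the dense route
    d2 = ((centers[:, None, :] - pts[None, :, :2]) ** 2).sum(axis=2)
    dist = np.sqrt(d2.min(axis=1)).reshape(template.shape)
    return template.copy_with(dist)


def load_settlements(path) -> np.ndarray:
    """Settlement CSV (x, y, is_urban) -> (m, 3) float array."""
    df = pd.read_csv(path)
    for col in ("x", "y"):
        if col not in df.columns:
            raise ValueError(f"settlement table missing column {col!r}")
    if "is_urban" not in df.columns:
        df["is_urban"] = 0
    return df[["x", "y", "is_urban"]].to_numpy(dtype=float)
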