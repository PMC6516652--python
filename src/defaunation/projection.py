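"""Gridded projection of the hurdle model to defaunation-index maps.

Per species: build cell-level covariates from the predictor stack plus the
species' traits, predict persistence probability and expected RR, and
combine them into DI_s = 1 - p_persist * min(exp(rr_hat), 1). Species maps
are averaged per cell into the composite DI (over all species, size classes,
or trophic guilds), and the per-cell fraction of species with DI_s > 0.7
defines hotspots (fraction >= 1/3).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hurdle import FittedHurdleStage, predict_stage
from .predictors import PredictorStack
from .raster import Raster

__all__ = [
    "SIZE_CLASSES", "GUILD_MAPS", "HOTSPOT_THRESHOLD", "HOTSPOT_FRACTION",
    "SpeciesLayer", "DefaunationMaps", "combine_hurdle", "project_species",
    "aggregate_di", "hotspot_fraction", "size_class", "build_maps",
    "species_coverage_percent",
]

logger = logging.getLogger(__name__)

#: body-mass classes (kg): small < 1, medium 1-20, large > 20
SIZE_CLASSES = {"small": (0.0, 1.0), "medium": (1.0, 20.0),
                "large": (20.0, np.inf)}
GUILD_MAPS = ("carnivore", "herbivore", "frugivore", "insectivore")
HOTSPOT_THRESHOLD = 0.7     # DI_s strictly above this counts toward hotspots
HOTSPOT_FRACTION = 1.0 / 3.0

#: body-mass span of the empirical records (kg); species outside are flagged
TRAINING_MASS_SPAN = (0.018, 3940.0)


@dataclass
class SpeciesLayer:
    """Range mask plus traits for one projected species."""

    species_id: str
    body_mass: float            # kg
    diet_guild: str
    range_mask: np.ndarray      # boolean grid, same geometry as the stack
    di: Raster | None = None    # filled by project_species

    def __post_init__(self) -> None:
        self.range_mask = np.asarray(self.range_mask, dtype=bool)
        if self.body_mass <= 0:
            raise ValueError("body_mass must be > 0")
        lo, hi = TRAINING_MASS_SPAN
        if not lo <= self.body_mass <= hi:
            logger.warning(
                "species %s body mass %.3g kg outside the training span "
                "[%.3g, %.3g]; projection extrapolates",
                self.species_id, self.body_mass, lo, hi)


def combine_hurdle(p_persist, rr_hat, cap_increase: bool = True):
    """DI_s from the two hurdle stages.

    DI_s = 1 - p_persist * min(exp(rr_hat), 1), clipped to [0, 1]:
    extirpation contributes total loss, persistence scales the conditional
    abundance ratio. With ``cap_increase`` (default) predicted abundance
    increases cannot produce negative defaunation; disabling the cap clips
    the result at 0 instead.
    """
    p = np.asarray(p_persist, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p_persist must be in [0, 1]")
    ratio = np.exp(np.asarray(rr_hat, dtype=float))
    if cap_increase:
        ratio = np.minimum(ratio, 1.0)
    return np.clip(1.0 - p * ratio, 0.0, 1.0)


def project_species(binomial: FittedHurdleStage, gaussian: FittedHurdleStage,
                    species: SpeciesLayer, stack: PredictorStack,
                    country_grid: np.ndarray | None = None,
                    cap_increase: bool = True) -> Raster:
    """DI_s grid for one species; cells outside the range mask (or nodata in
    any required covariate layer) are nodata."""
    needed = set()
    for f in (binomial, gaussian):
        for term in f.formula.terms:
            if term == "body_mass:distance_access":
                needed.add("distance_access")
            elif term not in {"body_mass", "diet_guild"}:
                needed.add(term)
    missing = sorted(t for t in needed if t not in stack)
    if missing:
        raise KeyError(f"predictor stack missing layer(s): {missing}")

    template = stack.template
    if species.range_mask.shape != template.shape:
        raise ValueError("range mask geometry mismatch")
    valid = stack.valid_mask(sorted(needed)) & species.range_mask
    out = np.full(template.shape, np.nan)
    if not valid.any():
        return template.copy_with(out)

    rows = {name: stack[name].data[valid] for name in needed}
    cov = pd.DataFrame(rows)
    cov["body_mass"] = species.body_mass
    cov["diet_guild"] = species.diet_guild
    cov["species_id"] = species.species_id
    if country_grid is not None:
        cg = np.asarray(country_grid)
        if cg.shape != template.shape:
            raise ValueError("country grid geometry mismatch")
        cov["country_id"] = cg[valid].astype(str)
    if "protected" in cov.columns:
        cov["protected"] = cov["protected"].astype(bool)

    p_persist = predict_stage(binomial, cov)
    rr_hat = predict_stage(gaussian, cov)
    out[valid] = combine_hurdle(p_persist, rr_hat, cap_increase)
    return template.copy_with(out)


def _stacked(layers: list[SpeciesLayer]) -> np.ndarray:
    grids = []
    for sp in layers:
        if sp.di is None:
            raise ValueError(f"species {sp.species_id} has no DI grid")
        grids.append(sp.di.data)
    arr = np.stack(grids) if grids else np.zeros((0, 1, 1))
    return arr


def aggregate_di(layers: list[SpeciesLayer],
                 subset=None) -> tuple[Raster, Raster]:
    """Cellwise mean DI over species passing ``subset`` (a predicate on
    SpeciesLayer), plus the species-count grid S; cells with S = 0 are
    nodata."""
    chosen = [sp for sp in layers if subset is None or subset(sp)]
    if not chosen:
        raise ValueError("no species pass the subset filter")
    # canonical order => results invariant to caller's species ordering
    chosen = sorted(chosen, key=lambda sp: sp.species_id)
    template = chosen[0].di
    for sp in chosen[1:]:
        if not sp.di.same_geometry(template):
            raise ValueError("species DI grids are not co-registered")
    arr = _stacked(chosen)
    count = np.isfinite(arr).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore"):
        mean = np.nansum(np.where(np.isfinite(arr), arr, 0.0), axis=0)
        mean = np.where(count > 0, mean / np.maximum(count, 1), np.nan)
    s_grid = np.where(count > 0, count, np.nan)
    return template.copy_with(mean), template.copy_with(s_grid)


def hotspot_fraction(layers: list[SpeciesLayer],
                     threshold: float = HOTSPOT_THRESHOLD,
                     hotspot_cut: float = HOTSPOT_FRACTION
                     ) -> tuple[Raster, Raster]:
    """Per-cell fraction of species with DI_s strictly above ``threshold``,
    and the hotspot mask (fraction >= 1/3, as 0/1 with nodata where S=0)."""
    if not layers:
        raise ValueError("no species layers")
    layers = sorted(layers, key=lambda sp: sp.species_id)
    template = layers[0].di
    arr = _stacked(layers)
    count = np.isfinite(arr).sum(axis=0).astype(float)
    above = (np.where(np.isfinite(arr), arr, -np.inf) > threshold).sum(axis=0)
    with np.errstate(invalid="ignore"):
        frac = np.where(count > 0, above / np.maximum(count, 1), np.nan)
    mask = np.where(count > 0, (frac >= hotspot_cut).astype(float), np.nan)
    return template.copy_with(frac), template.copy_with(mask)


def size_class(body_mass: float) -> str:
    """small < 1 kg, medium 1-20 kg (inclusive), large > 20 kg."""
    if body_mass < SIZE_CLASSES["small"][1]:
        return "small"
    if body_mass <= SIZE_CLASSES["medium"][1]:
        return "medium"
    return "large"


@dataclass
class DefaunationMaps:
    """All aggregated map products for one projection run."""

    composite: Raster
    species_count: Raster
    hotspot_frac: Raster
    hotspot_mask: Raster
    by_size: dict[str, Raster] = field(default_factory=dict)
    by_guild: dict[str, Raster] = field(default_factory=dict)
    species: list[SpeciesLayer] = field(default_factory=list)


def build_maps(binomial: FittedHurdleStage, gaussian: FittedHurdleStage,
               species: list[SpeciesLayer], stack: PredictorStack,
               country_grid: np.ndarray | None = None,
               cap_increase: bool = True) -> DefaunationMaps:
    """Project every species and aggregate composite / size / guild /
    hotspot maps."""
    for sp in species:
        sp.di = project_species(binomial, gaussian, sp, stack, country_grid,
                                cap_increase)
    composite, s_grid = aggregate_di(species)
    frac, mask = hotspot_fraction(species)
    by_size = {}
    for cls in SIZE_CLASSES:
        members = [sp for sp in species if size_class(sp.body_mass) == cls]
        if members:
            by_size[cls], _ = aggregate_di(members)
    by_guild = {}
    for guild in GUILD_MAPS:
        members = [sp for sp in species if sp.diet_guild == guild]
        if members:
            by_guild[guild], _ = aggregate_di(members)
    return DefaunationMaps(composite=composite, species_count=s_grid,
                           hotspot_frac=frac, hotspot_mask=mask,
                           by_size=by_size, by_guild=by_guild,
                           species=species)


def species_coverage_percent(n_observed: int, n_projected: int,
                             ndigits: int = 1) -> float:
    """Share (%) of projected species represented in the fitting database."""
    if n_projected <= 0:
        raise ValueError("n_projected must be > 0")
    return round(100.0 * n_observed / n_projected, ndigits)
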