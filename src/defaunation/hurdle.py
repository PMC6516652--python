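"""Two-stage hurdle mixed model for abundance ratios.

Stage 1 (binomial, logit link) models whether a population persists
(1 = not extirpated, 0 = extirpated); stage 2 (Gaussian) models the nonzero
log response ratios. Both stages carry crossed random intercepts for
country, study, and species. Model selection is by BIC on ML fits with
standardized covariates; the chosen formula is refit unstandardized (REML
for the Gaussian stage) for projection.

Body mass enters every design matrix as ln(kg): the empirical mass span
(0.018-3,940 kg) covers five orders of magnitude, and the mass x distance
interaction uses the same log scale.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mixed import MixedFit, fit_binomial_glmm, fit_lmm
from .predictors import StandardizationStats
from .ratio_db import DIET_GUILDS

__all__ = [
    "FIXED_TERMS", "RANDOM_FACTORS", "ModelFormula", "FittedHurdleStage",
    "SelectionTable", "build_design", "fit_binomial_stage",
    "fit_gaussian_stage", "bic", "select_stage", "select_models",
    "r2_marginal_conditional", "semipartial_r2", "predict_stage",
    "all_subset_formulas", "paper_best_formulas", "save_fit", "load_fit",
]

logger = logging.getLogger(__name__)

#: Fixed-effect terms the formula language understands.
FIXED_TERMS = (
    "distance_access", "hpd", "stunting", "travel_time", "livestock_biomass",
    "protected", "body_mass", "diet_guild", "body_mass:distance_access",
)
CONTINUOUS_TERMS = ("distance_access", "hpd", "stunting", "travel_time",
                    "livestock_biomass", "body_mass")
RANDOM_FACTORS = ("country", "study", "species")
_FACTOR_COLUMNS = {"country": "country_id", "study": "study_id",
                   "species": "species_id"}
_LOGISTIC_RESID_VAR = math.pi**2 / 3.0   # logit-link level-1 variance


@dataclass(frozen=True)
class ModelFormula:
    """Fixed terms + random-intercept factors for one hurdle stage."""

    stage: str                                  # "binomial" | "gaussian"
    terms: tuple[str, ...]
    random: tuple[str, ...] = RANDOM_FACTORS

    def __post_init__(self) -> None:
        if self.stage not in {"binomial", "gaussian"}:
            raise ValueError(f"unknown stage {self.stage!r}")
        for t in self.terms:
            if t not in FIXED_TERMS:
                raise ValueError(f"unknown term {t!r}")
        if len(set(self.terms)) != len(self.terms):
            raise ValueError("duplicate terms")
        if "body_mass:distance_access" in self.terms:
            if not {"body_mass", "distance_access"} <= set(self.terms):
                raise ValueError(
                    "interaction requires both main effects in the formula")
        for f in self.random:
            if f not in RANDOM_FACTORS:
                raise ValueError(f"unknown random factor {f!r}")

    def drop_term(self, term: str) -> "ModelFormula":
        if term not in self.terms:
            raise ValueError(f"term {term!r} not in formula")
        if term in {"body_mass", "distance_access"} \
                and "body_mass:distance_access" in self.terms:
            raise ValueError(
                f"cannot drop main effect {term!r} under its interaction")
        return ModelFormula(self.stage,
                            tuple(t for t in self.terms if t != term),
                            self.random)

    def describe(self) -> str:
        return f"{self.stage}: 1 + " + " + ".join(self.terms) if self.terms \
            else f"{self.stage}: 1"


def _continuous_value(df: pd.DataFrame, term: str) -> np.ndarray:
    if term == "body_mass":
        return np.log(np.asarray(df["body_mass"], dtype=float))
    return np.asarray(df[term], dtype=float)


def build_design(df: pd.DataFrame, terms, stats: StandardizationStats | None = None):
    """Design matrix (with intercept) for the given terms.

    ``stats`` holds z-standardization statistics keyed by term name
    (``body_mass`` stats refer to ln(kg)); interaction columns are products
    of the (standardized) main-effect columns.
    """
    n = len(df)
    needed = set()
    for t in terms:
        if t == "body_mass:distance_access":
            needed |= {"body_mass", "distance_access"}
        else:
            needed.add(t)
    missing = sorted(needed - set(df.columns))
    if missing:
        raise KeyError(f"missing covariate column(s): {missing}")
    cols, names = [np.ones(n)], ["(Intercept)"]
    main: dict[str, np.ndarray] = {}
    for term in terms:
        if term in CONTINUOUS_TERMS:
            x = _continuous_value(df, term)
            if stats is not None:
                x = (x - stats.mean[term]) / stats.sd[term]
            main[term] = x
            cols.append(x)
            names.append(term)
        elif term == "protected":
            cols.append(np.asarray(df["protected"]).astype(float))
            names.append("protected")
        elif term == "diet_guild":
            guilds = np.asarray(df["diet_guild"])
            for g in DIET_GUILDS[1:]:        # frugivore = reference level
                cols.append((guilds == g).astype(float))
                names.append(f"diet_guild[{g}]")
        elif term == "body_mass:distance_access":
            cols.append(main["body_mass"] * main["distance_access"])
            names.append("body_mass:distance_access")
        else:  # pragma: no cover - guarded by ModelFormula
            raise ValueError(f"unknown term {term!r}")
    return np.column_stack(cols), names


def compute_standardization(df: pd.DataFrame, terms) -> StandardizationStats:
    """Stats for the continuous terms of a formula (body mass on ln scale)."""
    mean, sd = {}, {}
    for term in terms:
        if term in CONTINUOUS_TERMS:
            x = _continuous_value(df, term)
            s = float(np.std(x, ddof=1))
            if not s > 0:
                raise ValueError(f"variable {term!r} has zero variance")
            mean[term], sd[term] = float(np.mean(x)), s
    return StandardizationStats(mean=mean, sd=sd)


@dataclass
class FittedHurdleStage:
    """A fitted hurdle stage: MixedFit plus formula/standardization context."""

    formula: ModelFormula
    fit: MixedFit
    feature_names: list[str]
    stats: StandardizationStats | None       # None => unstandardized fit
    _X: np.ndarray = field(repr=False, default=None)
    _df: pd.DataFrame = field(repr=False, default=None)

    @property
    def stage(self) -> str:
        return self.formula.stage

    @property
    def coefficients(self) -> dict[str, float]:
        return dict(zip(self.feature_names, self.fit.beta))

    @property
    def converged(self) -> bool:
        return self.fit.converged


def _factor_labels(df: pd.DataFrame, random) -> dict[str, np.ndarray]:
    return {f: np.asarray(df[_FACTOR_COLUMNS[f]]).astype(str) for f in random}


def _check_random(df: pd.DataFrame, random) -> None:
    for f in random:
        n_levels = df[_FACTOR_COLUMNS[f]].nunique()
        if n_levels < 2:
            logger.warning("random factor %r has %d level(s)", f, n_levels)


def fit_binomial_stage(
    df: pd.DataFrame,
    formula: ModelFormula,
    standardize: bool = True,
    var_fixed: dict[str, float] | None = None,
    nagq: int = 1,
) -> FittedHurdleStage:
    """Fit the persistence stage (outcome 1 = not extirpated, 0 = extirpated)
    on the full observation frame."""
    if formula.stage != "binomial":
        raise ValueError("formula is not for the binomial stage")
    y = 1.0 - np.asarray(df["extirpated"]).astype(float)
    stats = compute_standardization(df, formula.terms) if standardize else None
    X, names = build_design(df, formula.terms, stats)
    factors = _factor_labels(df, formula.random)
    _check_random(df, formula.random)
    fit = fit_binomial_glmm(y, X, factors, var_fixed=var_fixed, nagq=nagq,
                            feature_names=names)
    return FittedHurdleStage(formula, fit, names, stats, X, df)


def fit_gaussian_stage(
    df: pd.DataFrame,
    formula: ModelFormula,
    criterion: str = "REML",
    standardize: bool = True,
    var_fixed: dict[str, float] | None = None,
) -> FittedHurdleStage:
    """Fit the Gaussian stage through the nonzero log response ratios."""
    if formula.stage != "gaussian":
        raise ValueError("formula is not for the gaussian stage")
    nz = df.loc[~df["extirpated"].astype(bool)]
    rr = np.asarray(nz["rr"], dtype=float)
    if not np.isfinite(rr).all():
        raise ValueError("gaussian stage requires finite rr on all records")
    stats = compute_standardization(nz, formula.terms) if standardize else None
    X, names = build_design(nz, formula.terms, stats)
    factors = _factor_labels(nz, formula.random)
    _check_random(nz, formula.random)
    fit = fit_lmm(rr, X, factors, criterion=criterion, var_fixed=var_fixed,
                  feature_names=names)
    return FittedHurdleStage(formula, fit, names, stats, X, nz)


def bic(stage: FittedHurdleStage) -> float:
    """BIC = -2 logL + k ln(n); k counts fixed coefficients and variance
    components (residual variance included for the Gaussian stage)."""
    if stage.fit.family == "gaussian" and stage.fit.criterion != "ML":
        raise ValueError("BIC comparison across fixed effects requires ML fits")
    k = stage.fit.n_params
    return float(-2.0 * stage.fit.loglik + k * math.log(stage.fit.n_obs))


@dataclass
class SelectionTable:
    """BIC ranking over candidate formulas for one stage."""

    table: pd.DataFrame          # formula, k, bic, delta_bic, weight, supported
    best: ModelFormula
    fits: dict[int, FittedHurdleStage]   # index into candidate order


def select_stage(df: pd.DataFrame, candidates: list[ModelFormula],
                 delta_threshold: float = 2.0) -> SelectionTable:
    """Fit all candidates (ML, standardized), rank by BIC.

    Supported set: delta BIC <= 2. The designated best model is the supported
    model with the fewest parameters (ties broken by declaration order).
    """
    rows, fits = [], {}
    for i, f in enumerate(candidates):
        try:
            if f.stage == "binomial":
                st = fit_binomial_stage(df, f)
            else:
                st = fit_gaussian_stage(df, f, criterion="ML")
            if not st.converged:
                raise RuntimeError("non-convergent fit")
        except Exception as exc:   # noqa: BLE001 - candidates may fail freely
            logger.warning("candidate %d (%s) excluded: %s", i, f.describe(), exc)
            continue
        fits[i] = st
        rows.append({"index": i, "formula": f.describe(), "terms": f.terms,
                     "k": st.fit.n_params, "bic": bic(st)})
    if not rows:
        raise RuntimeError("no candidate converged")
    tab = pd.DataFrame(rows)
    tab["delta_bic"] = tab["bic"] - tab["bic"].min()
    rel = np.exp(-0.5 * tab["delta_bic"].to_numpy())
    tab["weight"] = rel / rel.sum()
    tab["supported"] = tab["delta_bic"] <= delta_threshold
    tab = tab.sort_values(["bic", "k", "index"], kind="stable").reset_index(drop=True)
    supported = tab[tab["supported"]]
    # fewest parameters among supported; declaration order breaks ties
    pick = supported.sort_values(["k", "index"], kind="stable").iloc[0]
    best = candidates[int(pick["index"])]
    return SelectionTable(table=tab, best=best, fits=fits)


def select_models(df: pd.DataFrame,
                  binomial_candidates: list[ModelFormula],
                  gaussian_candidates: list[ModelFormula],
                  delta_threshold: float = 2.0) -> dict:
    """BIC selection for both stages + unstandardized refits of the best
    formulas (REML for the Gaussian stage) for downstream prediction."""
    out = {}
    sel_b = select_stage(df, binomial_candidates, delta_threshold)
    sel_g = select_stage(df, gaussian_candidates, delta_threshold)
    out["binomial"] = {
        "selection": sel_b,
        "refit": fit_binomial_stage(df, sel_b.best, standardize=False),
    }
    out["gaussian"] = {
        "selection": sel_g,
        "refit": fit_gaussian_stage(df, sel_g.best, criterion="REML",
                                    standardize=False),
    }
    return out


def all_subset_formulas(stage: str, terms=None,
                        random: tuple[str, ...] = RANDOM_FACTORS,
                        include_interaction: bool = True) -> list[ModelFormula]:
    """All-subsets candidate list; the body_mass x distance interaction is
    added only on top of subsets containing both main effects."""
    terms = tuple(t for t in (terms or FIXED_TERMS)
                  if t != "body_mass:distance_access")
    out = []
    for r in range(len(terms) + 1):
        for combo in itertools.combinations(terms, r):
            out.append(ModelFormula(stage, combo, random))
            if include_interaction and {"body_mass", "distance_access"} <= set(combo):
                out.append(ModelFormula(
                    stage, combo + ("body_mass:distance_access",), random))
    return out


def paper_best_formulas() -> dict[str, ModelFormula]:
    """Default formulas mirroring the retained predictors of each best stage:
    binomial — distance, HPD, protection, body mass, stunting; gaussian —
    distance, body mass, their interaction, HPD."""
    return {
        "binomial": ModelFormula(
            "binomial",
            ("distance_access", "hpd", "protected", "body_mass", "stunting")),
        "gaussian": ModelFormula(
            "gaussian",
            ("distance_access", "body_mass", "body_mass:distance_access",
             "hpd")),
    }


def r2_marginal_conditional(stage: FittedHurdleStage) -> tuple[float, float]:
    """Variance-components R²: marginal (fixed only) and conditional
    (fixed + random); the binomial stage uses the logit-link level-1
    variance pi^2/3."""
    eta_f = stage._X @ stage.fit.beta
    var_f = float(np.var(eta_f))
    var_r = float(sum(stage.fit.vc.values()))
    var_e = stage.fit.sigma2 if stage.fit.family == "gaussian" \
        else _LOGISTIC_RESID_VAR
    denom = var_f + var_r + var_e
    return var_f / denom, (var_f + var_r) / denom


def semipartial_r2(stage: FittedHurdleStage, term: str) -> float:
    """Marginal-R² loss from refitting without ``term``."""
    reduced = stage.formula.drop_term(term)
    standardize = stage.stats is not None
    if stage.stage == "binomial":
        re_fit = fit_binomial_stage(stage._df, reduced, standardize=standardize)
    else:
        re_fit = fit_gaussian_stage(stage._df, reduced,
                                    criterion=stage.fit.criterion,
                                    standardize=standardize)
    full_m, _ = r2_marginal_conditional(stage)
    red_m, _ = r2_marginal_conditional(re_fit)
    return full_m - red_m


def predict_stage(stage: FittedHurdleStage, covariates: pd.DataFrame,
                  scale: str = "response") -> np.ndarray:
    """Predict from one fitted stage for new covariate rows.

    Random-intercept columns (``country_id``/``study_id``/``species_id``) are
    optional; known levels add their estimated intercept, unknown (or absent)
    levels contribute 0 (population-level prediction). ``scale="response"``
    returns probabilities for the binomial stage and expected RR for the
    Gaussian stage; ``scale="link"`` returns the linear predictor.
    """
    for term in stage.formula.terms:
        base = {"body_mass:distance_access": ("body_mass", "distance_access"),
                }.get(term, (term,))
        for b in base:
            if b not in covariates.columns:
                raise KeyError(f"missing covariate {b!r} for term {term!r}")
    X, _ = build_design(covariates, stage.formula.terms, stage.stats)
    eta = X @ stage.fit.beta
    for factor in stage.formula.random:
        col = _FACTOR_COLUMNS[factor]
        if col in covariates.columns:
            lookup = stage.fit.u_lookup(factor)
            eta = eta + np.array(
                [lookup.get(str(v), 0.0) for v in covariates[col]])
    if scale == "link" or stage.stage == "gaussian":
        return eta
    from scipy.special import expit
    return expit(eta)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_fit(stage: FittedHurdleStage, path) -> None:
    payload = {
        "formula": {"stage": stage.formula.stage,
                    "terms": list(stage.formula.terms),
                    "random": list(stage.formula.random)},
        "feature_names": stage.feature_names,
        "beta": stage.fit.beta.tolist(),
        "se": stage.fit.se.tolist(),
        "vc": stage.fit.vc,
        "sigma2": stage.fit.sigma2,
        "loglik": stage.fit.loglik,
        "n_obs": stage.fit.n_obs,
        "n_params": stage.fit.n_params,
        "criterion": stage.fit.criterion,
        "converged": stage.fit.converged,
        "family": stage.fit.family,
        "u": {f: {str(lvl): float(v)
                  for lvl, v in zip(stage.fit.levels[f], stage.fit.u[f])}
              for f in stage.fit.u},
        "standardization": (None if stage.stats is None else
                            {"mean": stage.stats.mean, "sd": stage.stats.sd}),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)


def load_fit(path) -> FittedHurdleStage:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    formula = ModelFormula(payload["formula"]["stage"],
                           tuple(payload["formula"]["terms"]),
                           tuple(payload["formula"]["random"]))
    levels = {f: np.array(list(d)) for f, d in payload["u"].items()}
    u = {f: np.array(list(d.values()), dtype=float)
         for f, d in payload["u"].items()}
    beta = np.asarray(payload["beta"], dtype=float)
    fit = MixedFit(
        beta=beta, se=np.asarray(payload["se"], dtype=float),
        vcov_beta=np.full((len(beta), len(beta)), np.nan),
        vc=payload["vc"], sigma2=payload["sigma2"], u=u, levels=levels,
        loglik=payload["loglik"], n_obs=payload["n_obs"],
        n_params=payload["n_params"], criterion=payload["criterion"],
        converged=payload["converged"], family=payload["family"])
    stats = payload["standardization"]
    stats = None if stats is None else StandardizationStats(**stats)
    return FittedHurdleStage(formula, fit, payload["feature_names"], stats)
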