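"""Cross-validated evaluation of the hurdle model.

Predictions are scored on the defaunation-index scale: observed DI is
1 - exp(rr) floored at 0 (extirpated -> 1), predicted DI combines both
stages (see :func:`defaunation.projection.combine_hurdle`). DI is cut into
three categories — low (DI <= 0.1), moderate (0.1 < DI <= 0.7), high
(DI > 0.7) — which mirror Biodiversity Intactness Index bands through the
complement DI = 1 - BII. Accuracy is one-vs-rest sensitivity/specificity
and balanced accuracy from the fold-pooled confusion matrix; pseudo-R² is
the squared Pearson correlation of pooled predicted vs observed DI (zeros,
i.e. extirpations, included).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hurdle import (ModelFormula, fit_binomial_stage, fit_gaussian_stage,
                     predict_stage)
from .projection import combine_hurdle

__all__ = [
    "CATEGORIES", "DI_LOW_MAX", "DI_HIGH_MIN", "bii_to_di", "observed_di",
    "assign_category", "kfold_split", "confusion_matrix",
    "metrics_from_confusion", "AccuracyReport", "evaluate",
]

logger = logging.getLogger(__name__)

CATEGORIES = ("low", "moderate", "high")
DI_LOW_MAX = 0.1    # low: DI <= 0.1
DI_HIGH_MIN = 0.7   # high: DI > 0.7


def bii_to_di(bii: float) -> float:
    """Complement mapping between a Biodiversity Intactness Index (fraction)
    and the defaunation index: DI = 1 - BII (a BII of 0.90 is DI 0.1)."""
    if not 0.0 <= bii <= 1.0:
        raise ValueError("BII must be a fraction in [0, 1]")
    return 1.0 - bii


def observed_di(extirpated, rr) -> np.ndarray:
    """Observed DI: extirpated -> 1, else max(0, 1 - exp(rr))."""
    extirpated = np.asarray(extirpated, dtype=bool)
    rr = np.asarray(rr, dtype=float)
    di = np.where(extirpated, 1.0, np.maximum(0.0, 1.0 - np.exp(rr)))
    return di


def assign_category(di) -> np.ndarray:
    """DI in [0,1] -> {'low','moderate','high'} (partition of [0, 1])."""
    di = np.asarray(di, dtype=float)
    out = np.where(di <= DI_LOW_MAX, "low",
                   np.where(di <= DI_HIGH_MIN, "moderate", "high"))
    return out.astype(object)


def kfold_split(df: pd.DataFrame, k: int = 5, seed: int = 0,
                grouping: str = "record"):
    """Deterministic k-fold partitions; with ``grouping="study"`` all records
    of a study land in the same fold."""
    n = len(df)
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    if grouping == "record":
        if n < k:
            raise ValueError("fewer records than folds")
        idx = rng.permutation(n)
        fold_of = np.empty(n, dtype=int)
        for f, chunk in enumerate(np.array_split(idx, k)):
            fold_of[chunk] = f
    elif grouping == "study":
        studies = df["study_id"].to_numpy()
        uniq = pd.unique(studies)
        if len(uniq) < k:
            raise ValueError("fewer studies than folds")
        perm = rng.permutation(len(uniq))
        study_fold = {}
        for f, chunk in enumerate(np.array_split(perm, k)):
            for j in chunk:
                study_fold[uniq[j]] = f
        fold_of = np.array([study_fold[s] for s in studies])
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    splits = []
    all_idx = np.arange(n)
    for f in range(k):
        test = all_idx[fold_of == f]
        train = all_idx[fold_of != f]
        splits.append((train, test))
    return splits


def confusion_matrix(observed, predicted) -> np.ndarray:
    """3x3 counts, rows = observed category, cols = predicted category."""
    cm = np.zeros((3, 3), dtype=int)
    oi = {c: i for i, c in enumerate(CATEGORIES)}
    for o, p in zip(observed, predicted):
        cm[oi[o], oi[p]] += 1
    return cm


def metrics_from_confusion(cm: np.ndarray) -> dict:
    """One-vs-rest sensitivity/specificity/balanced accuracy per category,
    plus unweighted macro-averages."""
    cm = np.asarray(cm, dtype=float)
    per = {}
    sens_list, spec_list = [], []
    for i, cat in enumerate(CATEGORIES):
        tp = cm[i, i]
        fn = cm[i, :].sum() - tp
        fp = cm[:, i].sum() - tp
        tn = cm.sum() - tp - fn - fp
        sens = tp / (tp + fn) if tp + fn > 0 else np.nan
        spec = tn / (tn + fp) if tn + fp > 0 else np.nan
        per[cat] = {"sensitivity": sens, "specificity": spec,
                    "balanced_accuracy": (sens + spec) / 2.0}
        sens_list.append(sens)
        spec_list.append(spec)
    overall_sens = float(np.nanmean(sens_list))
    overall_spec = float(np.nanmean(spec_list))
    return {
        "per_category": per,
        "overall_sensitivity": overall_sens,
        "overall_specificity": overall_spec,
        "overall_balanced_accuracy": (overall_sens + overall_spec) / 2.0,
    }


@dataclass
class AccuracyReport:
    confusion: np.ndarray
    metrics: dict
    pseudo_r2: float
    pseudo_r2_defined: bool
    n_folds_completed: int
    n_folds: int
    predicted_di: np.ndarray = field(repr=False, default=None)
    observed_di: np.ndarray = field(repr=False, default=None)

    @property
    def complete(self) -> bool:
        return self.n_folds_completed == self.n_folds

    def to_dict(self) -> dict:
        return {
            "confusion_matrix": self.confusion.tolist(),
            "categories": list(CATEGORIES),
            **self.metrics,
            "pseudo_r2": self.pseudo_r2,
            "pseudo_r2_defined": self.pseudo_r2_defined,
            "n_folds_completed": self.n_folds_completed,
            "n_folds": self.n_folds,
        }


def evaluate(df: pd.DataFrame, binomial_formula: ModelFormula,
             gaussian_formula: ModelFormula, k: int = 5, seed: int = 0,
             grouping: str = "record", cap_increase: bool = True) -> AccuracyReport:
    """k-fold cross-validation of the full hurdle model.

    Per fold: refit both stages on the training records (unstandardized —
    prediction does not depend on the covariate scaling), predict DI on the
    held-out records, categorize, and pool the confusion matrix over folds.
    """
    splits = kfold_split(df, k=k, seed=seed, grouping=grouping)
    obs_all, pred_all = [], []
    completed = 0
    for f, (train, test) in enumerate(splits):
        train_df, test_df = df.iloc[train], df.iloc[test]
        try:
            b = fit_binomial_stage(train_df, binomial_formula, standardize=False)
            g = fit_gaussian_stage(train_df, gaussian_formula,
                                   criterion="REML", standardize=False)
        except Exception as exc:   # noqa: BLE001
            warnings.warn(f"fold {f} fit failed and was skipped: {exc}",
                          stacklevel=2)
            continue
        p_persist = predict_stage(b, test_df)
        rr_hat = predict_stage(g, test_df)
        pred_all.append(combine_hurdle(p_persist, rr_hat, cap_increase))
        obs_all.append(observed_di(test_df["extirpated"], test_df["rr"]))
        completed += 1
    if completed == 0:
        raise RuntimeError("every cross-validation fold failed")
    pred = np.concatenate(pred_all)
    obs = np.concatenate(obs_all)
    cm = confusion_matrix(assign_category(obs), assign_category(pred))
    metrics = metrics_from_confusion(cm)
    if np.std(pred) == 0 or np.std(obs) == 0:
        pseudo_r2, defined = 0.0, False
    else:
        pseudo_r2 = float(np.corrcoef(pred, obs)[0, 1] ** 2)
        defined = True
    return AccuracyReport(confusion=cm, metrics=metrics, pseudo_r2=pseudo_r2,
                          pseudo_r2_defined=defined,
                          n_folds_completed=completed, n_folds=k,
                          predicted_di=pred, observed_di=obs)
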