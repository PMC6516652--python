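"""Multivariate environmental similarity surface (MESS).

Flags projection cells outside the covariate domain of the training data.
Univariate similarity follows the Elith et al. piecewise rule with f = the
percentage of reference values *strictly below* the evaluated value;
the surface takes the minimum over variables, and the argmin grid records
the most dissimilar variable per cell (ties -> first variable in declared
order). Negative similarity <=> at least one variable outside its reference
range; domain-restricted summaries mask cells with similarity < 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .predictors import PredictorStack
from .raster import Raster

__all__ = ["DEFAULT_MESS_VARIABLES", "MessResult", "mess_univariate",
           "mess_surface"]

#: socioeconomic variables screened by default
DEFAULT_MESS_VARIABLES = ("distance_access", "hpd", "stunting")


def mess_univariate(reference, p):
    """Similarity of value(s) ``p`` to a univariate reference sample.

    With f = % of reference strictly below p, min/max the reference range:
    f = 0   -> 100 * (p - min) / (max - min)
    0<f<=50 -> 2 f
    50<f<100-> 2 (100 - f)
    f = 100 -> 100 * (max - p) / (max - min)
    """
    ref = np.sort(np.asarray(reference, dtype=float))
    if ref.size == 0:
        raise ValueError("empty reference")
    lo, hi = ref[0], ref[-1]
    if hi <= lo:
        raise ValueError("constant reference: similarity undefined")
    p = np.asarray(p, dtype=float)
    f = 100.0 * np.searchsorted(ref, p, side="left") / ref.size
    span = hi - lo
    out = np.where(
        f == 0.0, 100.0 * (p - lo) / span,
        np.where(f <= 50.0, 2.0 * f,
                 np.where(f < 100.0, 2.0 * (100.0 - f),
                          100.0 * (hi - p) / span)))
    return out if out.ndim else float(out)


@dataclass
class MessResult:
    similarity: Raster          # min over variables, <= 100
    argmin_variable: Raster     # integer codes into `variables`
    variables: tuple[str, ...]

    def legend(self) -> dict[int, str]:
        return dict(enumerate(self.variables))

    def domain_mask(self) -> np.ndarray:
        """Cells inside the training domain (similarity >= 0)."""
        return self.similarity.data >= 0


def mess_surface(stack: PredictorStack, reference: pd.DataFrame,
                 variables=DEFAULT_MESS_VARIABLES) -> MessResult:
    """Per-cell minimum univariate similarity and its argmin variable.

    Nodata in any screened layer propagates to both output grids.
    """
    variables = tuple(variables)
    for v in variables:
        if v not in stack:
            raise KeyError(f"stack missing layer {v!r}")
        if v not in reference.columns:
            raise KeyError(f"reference missing variable {v!r}")
    template = stack.template
    valid = stack.valid_mask(list(variables))
    sims = np.full((len(variables),) + template.shape, np.nan)
    for i, v in enumerate(variables):
        sims[i, valid] = mess_univariate(reference[v].to_numpy(),
                                         stack[v].data[valid])
    similarity = np.full(template.shape, np.nan)
    argmin = np.full(template.shape, np.nan)
    if valid.any():
        block = sims[:, valid]
        idx = np.argmin(block, axis=0)        # ties -> first declared variable
        similarity[valid] = block[idx, np.arange(block.shape[1])]
        argmin[valid] = idx
    return MessResult(similarity=template.copy_with(similarity),
                      argmin_variable=template.copy_with(argmin),
                      variables=variables)
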