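"""Fit indices, nested likelihood-ratio comparisons and the 8-model grid.

Every constrained model is compared against the fully connected saturated
model (0 degrees of freedom) in the structural-equation-modeling style:
chi-squared = 2 * (ll_saturated - ll_model), df = k_saturated - k_model,
RMSEA = sqrt(max(chi2 - df, 0) / (df * (N - 1))) with N the pooled sample
size.  The default selection grid crosses the four constraint levels with
dense and sparse structures (eight models), and the chosen model is the
lowest-BIC fit among those with RMSEA < 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

from .fitting import (ConstraintLevel, FitOptions, MultigroupFit,
                      MultigroupModelSpec, Structure, fit_multigroup,
                      prune_edges)
from .panel import BinaryPanel

#: grid order: increasing constraints, dense before sparse at each level
GRID_LEVELS = (ConstraintLevel.SATURATED, ConstraintLevel.EQUAL_EDGES,
               ConstraintLevel.EQUAL_EDGES_THRESHOLDS,
               ConstraintLevel.EQUAL_ALL)

RMSEA_CUTOFF = 0.05


@dataclass
class FitIndices:
    aic: float
    bic: float
    chisq: float
    df: int
    p_chisq: float
    rmsea: float


def fit_indices(fit: MultigroupFit, saturated: MultigroupFit) -> FitIndices:
    """AIC/BIC and saturated-reference chi-squared, p and RMSEA."""
    if saturated.spec.constraint_level is not ConstraintLevel.SATURATED or \
            saturated.spec.structure is not Structure.DENSE:
        raise ValueError("reference must be the dense saturated fit")
    if fit.n_per_group != saturated.n_per_group:
        raise ValueError("fits come from different data")
    n_total = fit.n_total
    aic = -2 * fit.loglik + 2 * fit.k
    bic = -2 * fit.loglik + fit.k * np.log(n_total)
    chisq = max(2 * (saturated.loglik - fit.loglik), 0.0)
    df = saturated.k - fit.k
    if df < 0:
        raise ValueError("model has more parameters than the saturated fit")
    if df == 0:
        p = 1.0
        rmsea = 0.0
    else:
        p = float(chi2_dist.sf(chisq, df))
        rmsea = float(np.sqrt(max(chisq - df, 0.0) / (df * (n_total - 1))))
    return FitIndices(aic=float(aic), bic=float(bic), chisq=float(chisq),
                      df=int(df), p_chisq=p, rmsea=rmsea)


_LEVEL_ORDER = {lvl: i for i, lvl in enumerate(GRID_LEVELS)}


def _is_nested(restricted: MultigroupFit, general: MultigroupFit) -> bool:
    """Restricted's tied/zeroed parameter map must extend the general's."""
    if restricted.n_per_group != general.n_per_group:
        return False
    r_lvl = _LEVEL_ORDER[restricted.spec.constraint_level]
    g_lvl = _LEVEL_ORDER[general.spec.constraint_level]
    if r_lvl < g_lvl:
        return False
    r_mask, g_mask = restricted.edge_mask, general.edge_mask
    if np.any(r_mask & ~g_mask):  # restricted keeps an edge the general drops
        return False
    return restricted.k <= general.k


def nested_compare(fit_restricted: MultigroupFit,
                   fit_general: MultigroupFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of a restricted model against a nesting one."""
    if not _is_nested(fit_restricted, fit_general):
        raise ValueError("fits are not nested (restricted must constrain a "
                         "superset of the general model's ties)")
    lr = max(2 * (fit_general.loglik - fit_restricted.loglik), 0.0)
    df = fit_general.k - fit_restricted.k
    p = 1.0 if df == 0 else float(chi2_dist.sf(lr, df))
    return float(lr), int(df), p


@dataclass
class SelectionResult:
    table: pd.DataFrame
    fits: dict[tuple[ConstraintLevel, Structure], MultigroupFit]
    chosen: MultigroupModelSpec | None
    rmsea_pass: bool  # False when no model met the RMSEA cutoff


def select_model(panels: list[BinaryPanel],
                 sparse_alpha: float = 0.01,
                 options: FitOptions | None = None) -> SelectionResult:
    """Fit the selection grid and choose by BIC subject to RMSEA < 0.05.

    With two or more occasions the grid has the four constraint levels
    crossed with dense/sparse structures (eight models).  A single occasion
    degenerates to the two saturated structures (beta-level rows drop out).
    Non-convergent members are reported but excluded from the choice.
    """
    G = len(panels)
    levels = GRID_LEVELS if G >= 2 else (ConstraintLevel.SATURATED,)
    fits: dict[tuple[ConstraintLevel, Structure], MultigroupFit] = {}
    saturated = fit_multigroup(
        panels, MultigroupModelSpec(ConstraintLevel.SATURATED,
                                    Structure.DENSE,
                                    sparse_alpha=sparse_alpha), options)
    fits[(ConstraintLevel.SATURATED, Structure.DENSE)] = saturated
    for level in levels:
        dense_spec = MultigroupModelSpec(level, Structure.DENSE,
                                         sparse_alpha=sparse_alpha)
        if (level, Structure.DENSE) not in fits:
            fits[(level, Structure.DENSE)] = fit_multigroup(
                panels, dense_spec, options)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            sparse_spec = prune_edges(panels, dense_spec, options)
            fits[(level, Structure.SPARSE)] = fit_multigroup(
                panels, sparse_spec, options)

    rows = []
    for (level, structure), fit in fits.items():
        idx = fit_indices(fit, saturated)
        rows.append(dict(model=level.value, structure=structure.value,
                         k=fit.k, loglik=fit.loglik, aic=idx.aic,
                         bic=idx.bic, chisq=idx.chisq, df=idx.df,
                         p=idx.p_chisq, rmsea=idx.rmsea,
                         converged=fit.converged, chosen=False))
    table = pd.DataFrame(rows)

    ok = table[table.converged]
    passing = ok[ok.rmsea < RMSEA_CUTOFF]
    rmsea_pass = not passing.empty
    pool = passing if rmsea_pass else ok
    chosen = None
    if not pool.empty:
        best = pool.bic.idxmin()
        table.loc[best, "chosen"] = True
        key = (ConstraintLevel(table.loc[best, "model"]),
               Structure(table.loc[best, "structure"]))
        chosen = fits[key].spec
    if not rmsea_pass:
        warnings.warn("no model met the RMSEA < 0.05 cutoff; chose lowest "
                      "BIC overall", RuntimeWarning)
    return SelectionResult(table=table, fits=fits, chosen=chosen,
                           rmsea_pass=rmsea_pass)
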