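"""Performance metrics and the variability analysis.

Implements the effective percentage (fraction of pointwise extractions
whose orientation falls inside their region's admissible window), circular
angle-difference summaries (RMSE / mean / SD on minimal signed circular
differences), and the forward-stepwise ordinary-least-squares regression of
the per-location mean directional angle on the five ocular covariates,
selected by the Akaike information criterion and reported at p < 0.001.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .extraction import PointwiseExtraction
from .geometry import circ_diff
from .landmarks import COVARIATE_ORDER
from .preprocess import InputError
from .refmaps import RegionWindows


class UndefinedResultError(ValueError):
    """The requested statistic is undefined for the given input."""


class InsufficientDataError(ValueError):
    """Too few eyes (or observations) for the requested analysis."""


def effective_percentage(extractions: Sequence[PointwiseExtraction],
                         windows: RegionWindows) -> float:
    """Percentage of extractions whose theta lies in their region's window."""
    if len(extractions) == 0:
        raise UndefinedResultError("effective percentage of an empty extraction list")
    inside = sum(bool(windows.window_of(e.region_id).contains(e.theta))
                 for e in extractions)
    return 100.0 * inside / len(extractions)


@dataclass(frozen=True)
class AngleComparison:
    """Summary of paired circular angle differences (degrees)."""

    mean_diff: float
    sd_diff: float
    rmse: float
    n_points: int


def circular_rmse(a, b) -> AngleComparison:
    """RMSE / mean / SD of minimal signed circular differences a_i - b_i."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InputError("angle lists must be 1D and equally long")
    if a.size == 0:
        raise InputError("need at least one angle pair")
    d = circ_diff(a, b)
    return AngleComparison(mean_diff=float(d.mean()),
                           sd_diff=float(d.std(ddof=0)),
                           rmse=float(np.sqrt((d ** 2).mean())),
                           n_points=int(a.size))


# ---------------------------------------------------------------------------
# AIC forward stepwise


@dataclass
class StepwiseResult:
    """Outcome of the per-location forward-stepwise regression."""

    vf_index: int
    aic_selected: Tuple[str, ...]  # terms of the AIC-optimal model, in entry order
    selected: Tuple[str, ...]  # aic_selected terms also significant at p < p_threshold
    coefficients: Dict[str, float]
    p_values: Dict[str, float]
    r2: float
    aic_trace: List[float]
    n: int


def _aic(rss: float, n: int, k: int, aicc: bool = False) -> float:
    """Gaussian log-likelihood AIC = n ln(RSS/n) + 2k (k incl. intercept)."""
    rss = max(rss, n * 1e-24)  # guard exact fits
    a = n * math.log(rss / n) + 2.0 * k
    if aicc and n - k - 1 > 0:
        a += 2.0 * k * (k + 1) / (n - k - 1)
    return a


def aic_forward_stepwise(X: pd.DataFrame, y: np.ndarray, vf_index: int = 0,
                         p_threshold: float = 0.001, min_n: int = 20,
                         aicc: bool = False) -> StepwiseResult:
    """Forward stepwise OLS on the five ocular covariates, AIC-selected.

    Starting from the intercept-only model, the covariate giving the
    largest AIC decrease is added until no addition decreases the AIC
    (ties in AIC break by covariate order: onh_x, onh_y, onh_fo_angle,
    ellipticity, onh_area). Covariates are standardized internally, which
    leaves subset selection and p-values unchanged; reported coefficients
    are on the original scale. ``selected`` keeps only the AIC-model terms
    significant at ``p_threshold``, the inclusion rule of the final tables.
    """
    X = pd.DataFrame(X)
    missing = [c for c in COVARIATE_ORDER if c not in X.columns]
    if missing:
        raise InputError(f"missing covariates: {missing}")
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(y)
    X = X.loc[mask, list(COVARIATE_ORDER)]
    y = y[mask]
    n = int(y.size)
    if n < min_n:
        raise InsufficientDataError(f"need >= {min_n} eyes, got {n}")
    Xs = (X - X.mean()) / X.std(ddof=0).replace(0.0, 1.0)
    if not np.all(np.isfinite(Xs.to_numpy())):
        raise InputError("non-finite covariates")

    def rss_of(terms: List[str]) -> float:
        design = np.column_stack([np.ones(n)] + [Xs[t].to_numpy() for t in terms])
        beta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
        if rank < design.shape[1]:
            raise np.linalg.LinAlgError("rank-deficient design matrix")
        resid = y - design @ beta
        return float(resid @ resid)

    terms: List[str] = []
    cur_rss = rss_of(terms)
    cur_aic = _aic(cur_rss, n, 1, aicc)
    trace = [cur_aic]
    remaining = list(COVARIATE_ORDER)
    while remaining:
        if n <= len(terms) + 2:  # no residual degrees of freedom left
            break
        best_term, best_aic, best_rss = None, cur_aic, None
        for t in remaining:  # fixed order; strict < keeps the earliest on ties
            rss = rss_of(terms + [t])
            aic = _aic(rss, n, len(terms) + 2, aicc)
            if aic < best_aic - 1e-12:
                best_term, best_aic, best_rss = t, aic, rss
        if best_term is None:
            break
        terms.append(best_term)
        remaining.remove(best_term)
        cur_aic, cur_rss = best_aic, best_rss
        trace.append(cur_aic)

    # final OLS on the original scale for interpretable coefficients
    design = sm.add_constant(X[terms].to_numpy()) if terms else np.ones((n, 1))
    fit = sm.OLS(y, design).fit()
    names = ["intercept"] + terms
    coeffs = dict(zip(names, np.atleast_1d(fit.params)))
    pvals = dict(zip(names, np.nan_to_num(np.atleast_1d(fit.pvalues), nan=0.0)))
    r2 = float(fit.rsquared) if terms else 0.0
    significant = tuple(t for t in terms if pvals[t] < p_threshold)
    return StepwiseResult(vf_index=vf_index, aic_selected=tuple(terms),
                          selected=significant, coefficients=coeffs,
                          p_values=pvals, r2=r2, aic_trace=trace, n=n)


def variability_report(results: Sequence[StepwiseResult],
                       summaries: Optional[pd.DataFrame] = None,
                       p_threshold: float = 0.001):
    """Cohort tables of the variability analysis.

    Returns (per-location table with mean/SD/95% limit and the percentage of
    variation PV = 100 r2 explained by the AIC-optimal model, and the
    location x predictor incidence table with column totals). Locations
    whose intersection sets were empty never reach ``results`` and are
    absent from both tables; locations with no significant predictor are
    excluded from the incidence table, mirroring the significance rule.
    """
    rows = []
    for r in results:
        row = dict(vf_index=r.vf_index, n=r.n, pv=100.0 * r.r2)
        if summaries is not None and (summaries.vf_index == r.vf_index).any():
            s = summaries.loc[summaries.vf_index == r.vf_index].iloc[0]
            row.update(mean_deg=s.mean_deg, sd_deg=s.sd_deg,
                       limit95_deg=s.limit95_deg)
        rows.append(row)
    per_location = pd.DataFrame(rows)

    inc_rows = []
    for r in results:
        if not r.selected:
            continue
        inc_rows.append(dict(vf_index=r.vf_index,
                             **{c: int(c in r.selected) for c in COVARIATE_ORDER},
                             total=len(r.selected)))
    incidence = pd.DataFrame(inc_rows,
                             columns=["vf_index", *COVARIATE_ORDER, "total"])
    if len(incidence):
        totals = dict(vf_index=-1, total=int(incidence["total"].sum()),
                      **{c: int(incidence[c].sum()) for c in COVARIATE_ORDER})
        incidence = pd.concat([incidence, pd.DataFrame([totals])],
                              ignore_index=True)
    return per_location, incidence
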