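"""Shared statistical machinery: BH adjustment and the NB-GLM likelihood
ratio test used for differential expression, differential abundance and
differential peak accessibility.

The LRT fits a negative-binomial GLM with log link and a log-offset (library
size or replicate total), with the dispersion estimated once by moments from
the full-model Poisson fit. When the moment estimate is ~0 the model reduces
to Poisson. The test statistic is 2*(llf_full - llf_reduced) ~ chi2 on the
difference in model degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg q-values; NaN p-values propagate as NaN."""
    p = np.asarray(pvals, dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    q[ok] = out
    return q


@dataclass
class LRTResult:
    lrt_stat: float
    p: float
    dispersion: float
    converged: bool
    coef_full: Optional[np.ndarray] = None


def _fit(y, X, family, offset):
    model = sm.GLM(y, X, family=family, offset=offset)
    return model.fit(maxiter=100, tol=1e-9)


def nb_lrt(
    y: np.ndarray,
    X_full: np.ndarray,
    X_reduced: np.ndarray,
    offset: Optional[np.ndarray] = None,
) -> LRTResult:
    """LRT of the full vs reduced design for one count response.

    Degenerate fits (separation, non-convergence, all-zero response) are
    reported with ``converged=False`` and p=NaN rather than raised.
    """
    y = np.asarray(y, dtype=float)
    X_full = np.asarray(X_full, dtype=float)
    X_reduced = np.asarray(X_reduced, dtype=float)
    df = np.linalg.matrix_rank(X_full) - np.linalg.matrix_rank(X_reduced)
    if df <= 0:
        return LRTResult(0.0, 1.0, 0.0, True)
    if y.sum() == 0:
        return LRTResult(0.0, np.nan, 0.0, False)
    try:
        pois = _fit(y, X_full, sm.families.Poisson(), offset)
        mu = pois.fittedvalues
        # moment estimator: Var = mu + alpha mu^2
        alpha = float(np.sum((y - mu) ** 2 - mu) / np.sum(mu**2))
        alpha = min(max(alpha, 0.0), 10.0)
        if alpha < 1e-8:
            family = sm.families.Poisson()
        else:
            family = sm.families.NegativeBinomial(alpha=alpha)
        full = _fit(y, X_full, family, offset)
        red = _fit(y, X_reduced, family, offset)
    except Exception:
        return LRTResult(np.nan, np.nan, np.nan, False)
    stat = max(0.0, 2.0 * (full.llf - red.llf))
    p = float(sps.chi2.sf(stat, df))
    return LRTResult(float(stat), p, alpha, bool(full.converged and red.converged), np.asarray(full.params))
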