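"""RDM-level mediation analysis with the Sobel test.

Given three aligned vectors — independent variable (IV, e.g. a hand-
feature RDM triangle), mediator (Med, a model RDM triangle) and dependent
variable (DV, a brain RDM triangle averaged over regions and subjects
upstream) — two OLS regressions are fitted:

    Med = a * IV + e1
    DV  = b * Med + c * IV + e2

Intercepts are included (distance vectors are not naturally centered, and
forcing the fits through the origin would bias the slopes).  The indirect
effect a*b is tested with the Sobel statistic
``t = a*b / sqrt(b^2 se_a^2 + a^2 se_b^2)`` against a standard normal.
Complete mediation: the Sobel test is significant while the direct path c
is not, at the same alpha (default 0.001).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.stats import norm


@dataclass(frozen=True)
class MediationResult:
    a: float
    b: float
    c: float
    se_a: float
    se_b: float
    se_c: float
    sobel_t: float
    sobel_p: float
    p_c: float
    complete_mediation: bool
    resid_var_e1: float
    resid_var_e2: float
    standardized: bool


class CollinearityError(ValueError):
    """IV and mediator are (numerically) collinear; Eq. 7 is unidentifiable."""


def fit_mediation(
    iv: np.ndarray,
    med: np.ndarray,
    dv: np.ndarray,
    alpha: float = 0.001,
    standardize: bool = True,
    collinearity_tol: float = 1.0 - 1e-8,
) -> MediationResult:
    """Fit the two mediation regressions and run the Sobel test."""
    iv = np.asarray(iv, dtype=float).ravel()
    med = np.asarray(med, dtype=float).ravel()
    dv = np.asarray(dv, dtype=float).ravel()
    if not (len(iv) == len(med) == len(dv)):
        raise ValueError("iv, med and dv must have equal lengths")
    if len(iv) < 10:
        raise ValueError("need at least 10 observations")
    for name, v in (("iv", iv), ("med", med), ("dv", dv)):
        if v.std() == 0:
            raise ValueError(f"{name} has zero variance")
    r_im = np.corrcoef(iv, med)[0, 1]
    if abs(r_im) >= collinearity_tol:
        raise CollinearityError(
            f"|corr(iv, med)| = {abs(r_im):.10f}: the mediator is collinear "
            "with the independent variable"
        )
    if standardize:
        iv = (iv - iv.mean()) / iv.std(ddof=1)
        med = (med - med.mean()) / med.std(ddof=1)
        dv = (dv - dv.mean()) / dv.std(ddof=1)

    m1 = sm.OLS(med, sm.add_constant(iv)).fit()
    a, se_a = m1.params[1], m1.bse[1]
    X2 = sm.add_constant(np.column_stack([med, iv]))
    m2 = sm.OLS(dv, X2).fit()
    b, se_b = m2.params[1], m2.bse[1]
    c, se_c = m2.params[2], m2.bse[2]
    p_c = float(m2.pvalues[2])

    sobel_se = np.sqrt(b**2 * se_a**2 + a**2 * se_b**2)
    sobel_t = (a * b) / sobel_se
    sobel_p = float(2 * norm.sf(abs(sobel_t)))
    complete = bool(sobel_p < alpha and p_c >= alpha)
    return MediationResult(
        a=float(a),
        b=float(b),
        c=float(c),
        se_a=float(se_a),
        se_b=float(se_b),
        se_c=float(se_c),
        sobel_t=float(sobel_t),
        sobel_p=sobel_p,
        p_c=p_c,
        complete_mediation=complete,
        resid_var_e1=float(m1.resid.var(ddof=1)),
        resid_var_e2=float(m2.resid.var(ddof=1)),
        standardized=standardize,
    )
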