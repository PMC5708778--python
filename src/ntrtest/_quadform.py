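"""Tail probabilities of positive mixtures of chi-square(1) variables.

Used by the SKAT-family comparators: the score statistic Q is distributed
as sum_k lambda_k chi^2_1 under the null. The default approximation is the
Liu et al. moment-matching method (matching skewness, or kurtosis when the
skewness match is infeasible); ``imhof_pvalue`` numerically inverts the
characteristic function and serves as the more exact cross-check.
"""

from __future__ import annotations

import numpy as np
from scipy import integrate
from scipy import stats as sps

__all__ = ["liu_params", "liu_pvalue", "liu_quantile", "imhof_pvalue"]


def liu_params(lambdas: np.ndarray) -> dict:
    lam = np.asarray(lambdas, dtype=float)
    lam = lam[lam > 0]
    if lam.size == 0:
        raise ValueError("no positive eigenvalues")
    c1, c2, c3, c4 = (np.sum(lam ** k) for k in (1, 2, 3, 4))
    s1 = c3 / c2 ** 1.5
    s2 = c4 / c2 ** 2
    if s1 ** 2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1 ** 2 - s2))
        delta = s1 * a ** 3 - a ** 2
        df = a ** 2 - 2 * delta
    else:
        delta = 0.0
        df = 1.0 / s2
    return {"mu_q": c1, "sigma_q": np.sqrt(2 * c2), "df": df, "ncp": delta}


def liu_pvalue(q: float, lambdas: np.ndarray) -> float:
    """P(sum lambda_k chi2_1 > q) by Liu-style moment matching."""
    par = liu_params(lambdas)
    t_star = (q - par["mu_q"]) / par["sigma_q"]
    x = t_star * np.sqrt(2 * par["df"] + 4 * par["ncp"]) + par["df"] + par["ncp"]
    if par["ncp"] > 0:
        p = sps.ncx2.sf(x, par["df"], par["ncp"])
    else:
        p = sps.chi2.sf(x, par["df"])
    return float(min(max(p, 0.0), 1.0))


def liu_quantile(p_upper: float, lambdas: np.ndarray) -> float:
    """Quantile q with P(sum lambda_k chi2_1 > q) = p_upper (Liu scale)."""
    par = liu_params(lambdas)
    if par["ncp"] > 0:
        x = sps.ncx2.isf(p_upper, par["df"], par["ncp"])
    else:
        x = sps.chi2.isf(p_upper, par["df"])
    t_star = (x - par["df"] - par["ncp"]) / np.sqrt(2 * par["df"] + 4 * par["ncp"])
    return float(t_star * par["sigma_q"] + par["mu_q"])


def imhof_pvalue(q: float, lambdas: np.ndarray, limit: int = 200) -> float:
    """P(sum lambda_k chi2_1 > q) by Imhof's characteristic-function inversion."""
    lam = np.asarray(lambdas, dtype=float)
    lam = lam[lam != 0]

    def integrand(u: float) -> float:
        theta = 0.5 * np.sum(np.arctan(lam * u)) - 0.5 * q * u
        rho = np.prod((1.0 + (lam * u) ** 2) ** 0.25)
        return np.sin(theta) / (u * rho)

    val, _ = integrate.quad(integrand, 0, np.inf, limit=limit)
    return float(min(max(0.5 + val / np.pi, 0.0), 1.0))
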