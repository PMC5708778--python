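"""Comparator region tests: CMC, WSS, SKAT, SKAT-O and the single-variant
Cochran-Armitage trend test, under a uniform interface.

All take a :class:`RegionGenotypes` plus :class:`PhenotypeVector` and return
a :class:`ComparatorResult`. No covariates (intercept-only null models);
missing genotypes count as zero minor alleles, as in the NTR score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from ._quadform import imhof_pvalue, liu_pvalue, liu_quantile
from .containers import PhenotypeVector, RegionGenotypes
from .ntr import _case_group_counts, _group_genotypes, _weighted_midrank_sums

__all__ = [
    "ComparatorResult",
    "cmc_test",
    "wss_test",
    "skat_test",
    "skat_o_test",
    "trend_test",
    "run_comparator",
]


@dataclass
class ComparatorResult:
    method: str
    statistic: float
    p: float
    details: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0 or np.isnan(self.p)):
            raise ValueError("p-value outside [0, 1]")


def _genotype_matrix(region: RegionGenotypes) -> np.ndarray:
    """(N, L) float minor-allele counts with missing treated as 0."""
    return np.maximum(region.X, 0).T.astype(float)


def cmc_test(
    region: RegionGenotypes,
    phenotype: PhenotypeVector,
    maf_threshold: float = 0.01,
) -> ComparatorResult:
    """Combined multivariate and collapsing test.

    Variants with pooled MAF below ``maf_threshold`` are collapsed to a
    single carrier indicator; common variants enter individually. The joint
    association is a logistic likelihood-ratio test with one degree of
    freedom per retained predictor.
    """
    import statsmodels.api as sm

    phenotype.require_both_groups()
    G = _genotype_matrix(region)
    minor, total = region.allele_counts()
    maf = np.where(total > 0, minor / np.maximum(total, 1), 0.0)
    rare = maf < maf_threshold
    cols = []
    if rare.any():
        cols.append((G[:, rare].sum(axis=1) > 0).astype(float))
    for i in np.where(~rare)[0]:
        cols.append(G[:, i])
    P = np.column_stack(cols) if cols else np.empty((G.shape[0], 0))
    keep = [i for i in range(P.shape[1]) if np.ptp(P[:, i]) > 0]
    P = P[:, keep]
    if P.shape[1] == 0:
        return ComparatorResult("cmc", 0.0, 1.0, {"degenerate": True, "df": 0})
    y = phenotype.status.astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full = sm.GLM(y, sm.add_constant(P), family=sm.families.Binomial()).fit()
        null = sm.GLM(y, np.ones((y.size, 1)), family=sm.families.Binomial()).fit()
    lr = max(0.0, 2.0 * (full.llf - null.llf))
    df = P.shape[1]
    p = float(sps.chi2.sf(lr, df))
    return ComparatorResult("cmc", float(lr), p, {"df": df})


def wss_test(
    region: RegionGenotypes,
    phenotype: PhenotypeVector,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> ComparatorResult:
    """Madsen-Browning weighted-sum test.

    Weights derive from control allele frequencies, q_i = (m_i + 1) /
    (2 n_i^U + 2), w_i = sqrt(n_i q_i (1 - q_i)); rarer variants get larger
    contributions 1/w_i. The case rank sum of the per-individual weighted
    scores is standardized against label permutations, with the
    control-based weights recomputed under each permuted labelling (as in
    the original formulation); the p-value is one-sided (excess burden in
    cases).
    """
    phenotype.require_both_groups()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Xu, called2_u, sizes, inverse = _group_genotypes(region)
    minor_total, allele_total = region.allele_counts()
    n_called_ind = allele_total / 2.0  # individuals called per variant

    def _gamma(case_counts: np.ndarray) -> np.ndarray:
        """(M, U) weighted-sum scores from (M, U) per-group case counts."""
        a = case_counts @ Xu.T                      # case minor alleles
        t_ind = case_counts @ (called2_u / 2.0).T   # case called individuals
        ctrl_minor = minor_total[None, :] - a
        ctrl_n = n_called_ind[None, :] - t_ind
        q = (ctrl_minor + 1.0) / (2.0 * ctrl_n + 2.0)
        w = np.sqrt(n_called_ind[None, :] * q * (1.0 - q))
        return (1.0 / w) @ Xu

    # observed statistic through the same pipeline (one "permutation" row
    # holding the true labels)
    case_mask = phenotype.case_mask
    k_obs = np.bincount(inverse[case_mask], minlength=sizes.size)[None, :].astype(float)
    gamma_obs = _gamma(k_obs)
    r_obs = float(
        _weighted_midrank_sums(gamma_obs, sizes.astype(float), k_obs)[0]
    )
    K = _case_group_counts(sizes, phenotype.n_cases, n_perm, rng, exact=False)
    gammas = _gamma(K)
    sums = _weighted_midrank_sums(gammas, sizes.astype(float), K)
    m, s = sums.mean(), sums.std(ddof=1)
    if s == 0:
        return ComparatorResult("wss", 0.0, 1.0, {"degenerate": True})
    z = (r_obs - m) / s
    return ComparatorResult("wss", float(z), float(sps.norm.sf(z)), {"n_perm": n_perm})


def _skat_core(
    region: RegionGenotypes,
    phenotype: PhenotypeVector,
    weights_beta: tuple[float, float] = (1.0, 25.0),
) -> dict:
    """Shared pieces of SKAT / SKAT-O: weighted genotypes and score residuals."""
    phenotype.require_both_groups()
    G = _genotype_matrix(region)  # (N, L)
    n = G.shape[0]
    minor, total = region.allele_counts()
    maf = minor / np.maximum(total, 1)
    w = sps.beta.pdf(maf, weights_beta[0], weights_beta[1])
    Z = G * w[None, :]
    y = phenotype.status.astype(float)
    mu = y.mean()
    v = mu * (1.0 - mu)
    resid = y - mu
    U = Z.T @ resid  # (L,) weighted score vector
    # K = v * Z' (I - 11'/n) Z : the null covariance of U
    colsum = Z.sum(axis=0)
    K = v * (Z.T @ Z - np.outer(colsum, colsum) / n)
    return {"Z": Z, "resid": resid, "U": U, "K": K, "v": v, "n": n, "w": w}


def skat_test(
    region: RegionGenotypes,
    phenotype: PhenotypeVector,
    weights_beta: tuple[float, float] = (1.0, 25.0),
    method: str = "liu",
) -> ComparatorResult:
    """Sequence kernel association test with Beta(MAF; a, b) weights.

    Q = sum_i (w_i g_i'(y - ybar))^2 under an intercept-only logistic null;
    the null distribution is the eigenvalue mixture of chi-square(1)
    variables, approximated by Liu moment matching (``method='imhof'``
    switches to characteristic-function inversion).
    """
    core = _skat_core(region, phenotype, weights_beta)
    Q = float(core["U"] @ core["U"])
    lam = _positive_eigs(core["K"])
    if lam.size == 0:
        return ComparatorResult("skat", Q, 1.0, {"degenerate": True})
    if method == "imhof":
        p = imhof_pvalue(Q, lam)
    else:
        p = liu_pvalue(Q, lam)
    return ComparatorResult("skat", Q, p, {"lambdas": lam, "method": method})


def _positive_eigs(K: np.ndarray) -> np.ndarray:
    """Numerically positive eigenvalues of a symmetric PSD matrix."""
    lam = np.linalg.eigvalsh(K)
    top = lam.max() if lam.size else 0.0
    if top <= 0:
        return np.empty(0)
    return lam[lam > 1e-12 * top]


def _rho_half(rho: float, L: int) -> np.ndarray:
    """Symmetric square root of R_rho = (1 - rho) I + rho 11'."""
    J = np.full((L, L), 1.0 / L)
    return np.sqrt(1.0 - rho) * (np.eye(L) - J) + np.sqrt(1.0 - rho + L * rho) * J


def skat_o_test(
    region: RegionGenotypes,
    phenotype: PhenotypeVector,
    weights_beta: tuple[float, float] = (1.0, 25.0),
    rho_grid: np.ndarray | None = None,
    n_perm_fallback: int = 2000,
    seed: int | np.random.Generator | None = None,
) -> ComparatorResult:
    """Optimal unified test over Q_rho = (1-rho) Q_SKAT + rho Q_burden.

    Searches an 11-point rho grid in [0, 1]; the minimum per-rho p-value is
    calibrated by the one-dimensional mixture integration of the optimal
    test (Lee et al.), with Liu approximations for each component. If the
    integration fails numerically, a label-permutation fallback calibrates
    the minimum-p statistic directly.
    """
    if rho_grid is None:
        rho_grid = np.linspace(0.0, 1.0, 11)
    rho_grid = np.asarray(rho_grid, dtype=float)
    # rho = 1 makes R_rho singular; cap as in the reference algorithm
    rho_c = np.minimum(rho_grid, 0.999)
    core = _skat_core(region, phenotype, weights_beta)
    U, K = core["U"], core["K"]
    L = U.size
    q_skat = float(U @ U)
    q_burden = float(U.sum() ** 2)
    q_rho = (1.0 - rho_c) * q_skat + rho_c * q_burden

    lam_sets = []
    p_rho = np.empty(rho_c.size)
    for i, r in enumerate(rho_c):
        Rh = _rho_half(r, L)
        lam = _positive_eigs(Rh @ K @ Rh)
        if lam.size == 0:
            return ComparatorResult("skat_o", q_skat, 1.0, {"degenerate": True})
        lam_sets.append(lam)
        p_rho[i] = liu_pvalue(q_rho[i], lam)
    t_min = float(p_rho.min())
    rho_star = float(rho_grid[int(p_rho.argmin())])

    try:
        p = _skato_minp_pvalue(t_min, q_rho, rho_c, lam_sets, K, core)
    except Exception:
        p = _skato_permutation_p(q_rho, rho_c, core, n_perm_fallback, seed)
    p = float(min(max(p, t_min), min(1.0, t_min * rho_c.size)))
    return ComparatorResult(
        "skat_o", q_skat, p,
        {"rho_star": rho_star, "p_rho": p_rho, "q_rho": q_rho},
    )


def _skato_minp_pvalue(t_min, q_rho, rho_c, lam_sets, K, core) -> float:
    """One-dimensional integration for the min-p statistic of the rho family."""
    from scipy import integrate

    n = core["n"]
    v = core["v"]
    Z = core["Z"]
    # Z1 = P0^{1/2} Z for the intercept-only binomial null: column-centred,
    # scaled by sqrt(v)
    Z1 = np.sqrt(v) * (Z - Z.mean(axis=0, keepdims=True))
    z_mean = Z1.mean(axis=1)
    z_mean_sq = float(z_mean @ z_mean)
    if z_mean_sq == 0:
        raise FloatingPointError("degenerate burden direction")
    cof1 = (z_mean @ Z1) / z_mean_sq
    Z_item1 = np.outer(z_mean, cof1)
    Z_item2 = Z1 - Z_item1
    W22 = Z_item2.T @ Z_item2
    lam = np.linalg.eigvalsh(W22)
    lam = lam[lam > 1e-12 * max(lam.max(), 1.0)]
    mu_q = lam.sum()
    w33 = 4.0 * float(np.sum((Z_item1.T @ Z_item1) * W22))
    var_q = 2.0 * np.sum(lam ** 2) + w33
    ker_q = np.sum(lam ** 4) / np.sum(lam ** 2) ** 2 * 12.0
    df = 12.0 / ker_q
    L = Z.shape[1]
    tau = (L ** 2 * rho_c + float(cof1 @ cof1) * (1.0 - rho_c)) * z_mean_sq

    # per-rho quantiles of Q_rho at upper tail t_min
    q_min = np.array([liu_quantile(t_min, lam_sets[i]) for i in range(rho_c.size)])

    def integrand(x: float) -> float:
        qx = np.min((q_min - tau * x) / (1.0 - rho_c))
        t = (qx - mu_q) / np.sqrt(var_q) * np.sqrt(2.0 * df) + df
        return sps.chi2.cdf(t, df) * sps.chi2.pdf(x, 1)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        val, _ = integrate.quad(integrand, 0, 40, limit=200)
    return 1.0 - val


def _skato_permutation_p(q_rho, rho_c, core, n_perm, seed) -> float:
    """Permutation calibration of min-p over the rho grid."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Z = core["Z"]
    n = core["n"]
    # resid = y - mean(y), so cases are the strictly positive residuals
    n_cases = int(np.sum(core["resid"] > 0))
    lam_sets = _eig_sets(core, rho_c)
    p_obs = np.array([liu_pvalue(q, lam) for q, lam in zip(q_rho, lam_sets)])
    t_obs = p_obs.min()
    count = 0
    base = np.zeros(n, dtype=np.int8)
    base[:n_cases] = 1
    for _ in range(n_perm):
        rng.shuffle(base)
        yb = base.astype(float)
        resid = yb - yb.mean()
        U = Z.T @ resid
        qs = float(U @ U)
        qb = float(U.sum() ** 2)
        qr = (1.0 - rho_c) * qs + rho_c * qb
        pr = np.array([liu_pvalue(q, lam) for q, lam in zip(qr, lam_sets)])
        if pr.min() <= t_obs:
            count += 1
    return (count + 1) / (n_perm + 1)


def _eig_sets(core, rho_c):
    K = core["K"]
    L = K.shape[0]
    out = []
    for r in rho_c:
        Rh = _rho_half(r, L)
        out.append(_positive_eigs(Rh @ K @ Rh))
    return out


def trend_test(
    region: RegionGenotypes,
    phenotype: PhenotypeVector,
    variant_index: int = 0,
) -> ComparatorResult:
    """Cochran-Armitage trend test for a single variant, scores (0, 1, 2).

    Equivalent to the score test of logistic regression on the additive
    genotype coding; chi-square with 1 degree of freedom.
    """
    phenotype.require_both_groups()
    x = region.X[variant_index]
    called = x != -1
    x = x[called].astype(float)
    y = phenotype.status[called].astype(float)
    N = x.size
    R = y.sum()
    if N == 0 or np.ptp(x) == 0:
        return ComparatorResult("trend", 0.0, 1.0, {"degenerate": True})
    # score-test form: T = [sum x_j (y_j - ybar)]^2 / [ybar(1-ybar) * Sxx]
    ybar = R / N
    num = float(x @ (y - ybar)) ** 2
    sxx = float(np.sum((x - x.mean()) ** 2))
    den = ybar * (1.0 - ybar) * sxx
    stat = num / den if den > 0 else 0.0
    return ComparatorResult("trend", float(stat), float(sps.chi2.sf(stat, 1)), {})


def run_comparator(
    method: str,
    region: RegionGenotypes,
    phenotype: PhenotypeVector,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> ComparatorResult:
    """Dispatch a comparator by name (cmc, wss, skat, skat_o, trend)."""
    if method == "cmc":
        return cmc_test(region, phenotype)
    if method == "wss":
        return wss_test(region, phenotype, n_perm=n_perm, seed=seed)
    if method == "skat":
        return skat_test(region, phenotype)
    if method == "skat_o":
        return skat_o_test(region, phenotype, seed=seed)
    if method == "trend":
        return trend_test(region, phenotype)
    raise ValueError(f"unknown comparator {method!r}")
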