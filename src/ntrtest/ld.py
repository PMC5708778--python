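"""Two-locus linkage disequilibrium: haplotype frequencies and Hedrick's D'.

Hedrick's multiallelic D' for loci A and B with haplotype proportions h_im is

    D' = sum_i sum_m  p_i q_m |D_im / D_max(i, m)|

with D_im = h_im - p_i q_m and

    D_max = min(p_i q_m, (1 - p_i)(1 - q_m))   if D_im < 0
    D_max = min(p_i (1 - q_m), (1 - p_i) q_m)  if D_im > 0.

For biallelic loci |D_im / D_max| is the same in all four cells, so the
measure reduces to Lewontin's classical |D'| and lies in [0, 1] regardless
of the allele frequencies. D_im = 0 (independence) is defined as 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .containers import MISSING, RegionGenotypes

__all__ = [
    "HaplotypeFreqTable",
    "LDMatrix",
    "haplotype_freqs_phased",
    "haplotype_freqs_em",
    "hedrick_dprime",
    "pairwise_dprime_matrix",
]


@dataclass
class HaplotypeFreqTable:
    """2x2 table of two-locus haplotype proportions h_im.

    Rows index the alleles of locus A (0 = major/reference coding, 1 = the
    alternative), columns those of locus B. ``degenerate`` marks tables where
    at least one locus is monomorphic, for which D' is undefined.
    """

    h: np.ndarray
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=float)
        if self.h.shape != (2, 2):
            raise ValueError("h must be a 2x2 table")
        if (self.h < -1e-12).any():
            raise ValueError("haplotype proportions must be non-negative")
        if abs(self.h.sum() - 1.0) > 1e-9:
            raise ValueError("haplotype proportions must sum to 1")

    @property
    def p(self) -> np.ndarray:
        """Marginal allele proportions of locus A."""
        return self.h.sum(axis=1)

    @property
    def q(self) -> np.ndarray:
        """Marginal allele proportions of locus B."""
        return self.h.sum(axis=0)


@dataclass
class LDMatrix:
    """Symmetric L x L matrix of pairwise Hedrick D' values, diagonal 1."""

    dprime: np.ndarray
    monomorphic: np.ndarray | None = None

    def __post_init__(self) -> None:
        d = np.asarray(self.dprime, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("dprime must be square")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("dprime must be symmetric")
        if (d < -1e-12).any() or (d > 1 + 1e-9).any():
            raise ValueError("dprime entries must lie in [0, 1]")
        self.dprime = np.clip(d, 0.0, 1.0)


def haplotype_freqs_phased(hapA: np.ndarray, hapB: np.ndarray) -> HaplotypeFreqTable:
    """Haplotype frequency table by direct counting of phased haplotypes.

    ``hapA`` and ``hapB`` are equal-length 0/1 allele vectors over the same
    haplotypes (2N entries for N diploid individuals).
    """
    a = np.asarray(hapA)
    b = np.asarray(hapB)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("haplotype vectors must be 1-D and equal length")
    if a.size == 0:
        raise ValueError("no haplotypes")
    if not (np.isin(a, (0, 1)).all() and np.isin(b, (0, 1)).all()):
        raise ValueError("alleles must be coded 0/1")
    h = np.zeros((2, 2))
    np.add.at(h, (a.astype(int), b.astype(int)), 1.0)
    h /= a.size
    degenerate = (h.sum(axis=1) == 0).any() or (h.sum(axis=0) == 0).any() \
        or (h.sum(axis=1) == 1).any() or (h.sum(axis=0) == 1).any()
    return HaplotypeFreqTable(h=h, degenerate=bool(degenerate))


def haplotype_freqs_em(
    genoA: np.ndarray,
    genoB: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> HaplotypeFreqTable:
    """Maximum-likelihood haplotype frequencies from unphased genotype pairs.

    Standard two-locus EM under Hardy-Weinberg equilibrium: only double
    heterozygotes are phase-ambiguous. Individuals with a missing genotype at
    either locus are dropped. Initialized at linkage equilibrium; iterates
    until the largest change in any cell is below ``tol``.
    """
    gA = np.asarray(genoA)
    gB = np.asarray(genoB)
    if gA.shape != gB.shape or gA.ndim != 1:
        raise ValueError("genotype vectors must be 1-D and equal length")
    keep = (gA != MISSING) & (gB != MISSING)
    gA, gB = gA[keep].astype(int), gB[keep].astype(int)
    if gA.size == 0:
        raise ValueError("no individuals with genotypes called at both loci")

    # 3x3 joint genotype counts
    counts = np.zeros((3, 3))
    np.add.at(counts, (gA, gB), 1.0)
    n_hap = 2.0 * gA.size

    pA = gA.sum() / n_hap
    qB = gB.sum() / n_hap
    if pA in (0.0, 1.0) or qB in (0.0, 1.0):
        h = np.outer([1 - pA, pA], [1 - qB, qB])
        return HaplotypeFreqTable(h=h, degenerate=True)

    # Unambiguous haplotype copies from all non-double-heterozygote
    # genotype combinations (phase is determined for those).
    base = np.zeros((2, 2))
    for i in range(3):
        for m in range(3):
            c = counts[i, m]
            if c == 0 or (i == 1 and m == 1):
                continue
            if i == 0:
                a_alleles = (0, 0)
            elif i == 1:
                a_alleles = (0, 1)
            else:
                a_alleles = (1, 1)
            if m == 0:
                b_alleles = (0, 0)
            elif m == 1:
                b_alleles = (0, 1)
            else:
                b_alleles = (1, 1)
            if i == 1:
                # single het at A: the B genotype is homozygous, phase known
                base[0, b_alleles[0]] += c
                base[1, b_alleles[1]] += c
            elif m == 1:
                base[a_alleles[0], 0] += c
                base[a_alleles[1], 1] += c
            else:
                base[a_alleles[0], b_alleles[0]] += c
                base[a_alleles[1], b_alleles[1]] += c

    n_dh = counts[1, 1]
    h = np.outer([1 - pA, pA], [1 - qB, qB])  # linkage-equilibrium start
    for _ in range(max_iter):
        # E-step: split double heterozygotes between cis (ab/AB) and
        # trans (aB/Ab) phases.
        cis = h[0, 0] * h[1, 1]
        trans = h[0, 1] * h[1, 0]
        denom = cis + trans
        f_cis = 0.5 if denom == 0 else cis / denom
        new = base.copy()
        new[0, 0] += n_dh * f_cis
        new[1, 1] += n_dh * f_cis
        new[0, 1] += n_dh * (1 - f_cis)
        new[1, 0] += n_dh * (1 - f_cis)
        new /= n_hap
        if np.abs(new - h).max() < tol:
            h = new
            break
        h = new
    return HaplotypeFreqTable(h=h, degenerate=False)


def hedrick_dprime(table: HaplotypeFreqTable) -> float:
    """Hedrick's multiallelic D' for a 2x2 haplotype table; in [0, 1]."""
    if table.degenerate:
        raise ValueError("D' undefined: at least one locus is monomorphic")
    h = table.h
    p = table.p
    q = table.q
    total = 0.0
    for i in range(2):
        for m in range(2):
            d = h[i, m] - p[i] * q[m]
            if d == 0:
                continue
            if d < 0:
                dmax = min(p[i] * q[m], (1 - p[i]) * (1 - q[m]))
            else:
                dmax = min(p[i] * (1 - q[m]), (1 - p[i]) * q[m])
            total += p[i] * q[m] * abs(d / dmax)
    return float(min(total, 1.0))


def _dprime_from_haplotype_matrix(H: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized biallelic |D'| for all variant pairs from (L, n_hap) alleles.

    Returns the D' matrix and a boolean monomorphic-locus mask. Equals
    ``hedrick_dprime(haplotype_freqs_phased(...))`` pair by pair.
    """
    H = np.asarray(H, dtype=np.float64)
    L, n = H.shape
    p = H.mean(axis=1)
    h11 = (H @ H.T) / n
    D = h11 - np.outer(p, p)
    pi = p[:, None]
    qm = p[None, :]
    dmax_neg = np.minimum(pi * qm, (1 - pi) * (1 - qm))
    dmax_pos = np.minimum(pi * (1 - qm), (1 - pi) * qm)
    dmax = np.where(D > 0, dmax_pos, dmax_neg)
    mono = (p == 0) | (p == 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        dp = np.abs(D / dmax)
    dp[D == 0] = 0.0
    dp[mono, :] = 0.0
    dp[:, mono] = 0.0
    np.fill_diagonal(dp, 1.0)
    dp = np.clip(dp, 0.0, 1.0)
    return dp, mono


def pairwise_dprime_matrix(
    region: RegionGenotypes,
    use_phased: bool | None = None,
) -> LDMatrix:
    """Pairwise Hedrick D' for every variant pair in a region.

    Uses phased haplotypes by direct counting when the region carries them
    (``use_phased=None`` auto-detects); otherwise estimates haplotype
    frequencies per pair with the EM algorithm. Pairs involving a monomorphic
    locus get D' = 0 and a warning; the diagonal is 1 by definition.
    """
    L = region.n_variants
    if L < 2:
        raise ValueError("need at least two variants for pairwise LD")
    if use_phased is None:
        use_phased = region.phased_haplotypes is not None
    if use_phased:
        if region.phased_haplotypes is None:
            raise ValueError("use_phased requested but no phased haplotypes")
        dp, mono = _dprime_from_haplotype_matrix(region.phased_haplotypes)
        if mono.any():
            warnings.warn("monomorphic loci present; their D' set to 0")
        # symmetrize against tiny float asymmetry from the matmul
        dp = (dp + dp.T) / 2.0
        return LDMatrix(dprime=dp, monomorphic=mono)

    dp = np.eye(L)
    mono = ~region.polymorphic_mask()
    warned = False
    for i in range(L):
        for m in range(i + 1, L):
            if mono[i] or mono[m]:
                val = 0.0
                warned = True
            else:
                table = haplotype_freqs_em(region.X[i], region.X[m])
                val = 0.0 if table.degenerate else hedrick_dprime(table)
            dp[i, m] = dp[m, i] = val
    if warned:
        warnings.warn("monomorphic loci present; their D' set to 0")
    return LDMatrix(dprime=dp, monomorphic=mono)
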