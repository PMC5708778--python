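"""Per-variant statistics and the NTR genetic score.

Each variant i gets a main-effect weight

    W_i = |log2 OR_i| * (1 / MF_i)

where MF_i is the pooled-sample minor allele frequency and OR_i the allelic
odds ratio (minor vs major allele, cases vs controls). Each unordered pair
(i, m) gets three alternative weights, all damped by LD so that variant
pairs carrying redundant information contribute less:

    W_im(1) = (log2 OR_i + log2 OR_m)   (1/MF_i + 1/MF_m) (1 - D'_im)
    W_im(2) = |log2 OR_i + log2 OR_m|   (1/MF_i + 1/MF_m) (1 - D'_im)
    W_im(3) = (|log2 OR_i| + |log2 OR_m|)(1/MF_i + 1/MF_m) (1 - D'_im)

The three share magnitudes up to sign except that (3) dominates by the
triangle inequality; keeping all three avoids cancellation when risk and
protective variants coexist in a region. The per-individual score is

    S_j(k) = [ sum_i W_i X_ij + sum_{i<m} W_im(k) (X_ij + X_mj) ] * PR

with PR the proportion of variants in the region with MAF below 0.01 —
regions richer in rare variants are up-weighted, but since PR is a common
positive factor it never changes score ranks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import PhenotypeVector, RegionGenotypes
from .ld import LDMatrix

__all__ = [
    "VariantStats",
    "PairWeightSet",
    "ScoreSet",
    "estimate_maf",
    "estimate_or",
    "main_weights",
    "pair_weights",
    "rare_proportion",
    "genetic_scores",
    "RARE_MAF_THRESHOLD",
]

#: MAF below which a variant counts as "rare" in the PR factor.
RARE_MAF_THRESHOLD: float = 0.01


@dataclass
class VariantStats:
    """Per-variant MAF, allelic odds ratio and main-effect weight."""

    mf: np.ndarray
    or_: np.ndarray
    w: np.ndarray

    def __post_init__(self) -> None:
        self.mf = np.asarray(self.mf, dtype=float)
        self.or_ = np.asarray(self.or_, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        if not (self.mf.shape == self.or_.shape == self.w.shape):
            raise ValueError("mf, or_ and w must have equal length")
        if (self.mf <= 0).any() or (self.mf > 0.5 + 1e-12).any():
            raise ValueError("MAF must lie in (0, 0.5]")
        if (self.or_ <= 0).any():
            raise ValueError("odds ratios must be positive")

    @classmethod
    def from_region(
        cls, region: RegionGenotypes, phenotype: PhenotypeVector
    ) -> "VariantStats":
        mf = estimate_maf(region)
        or_ = estimate_or(region, phenotype)
        w = np.abs(np.log2(or_)) / mf
        return cls(mf=mf, or_=or_, w=w)


@dataclass
class PairWeightSet:
    """The three symmetric L x L pairwise weight matrices W_im(k), k=1..3."""

    w_pair: np.ndarray  # shape (3, L, L), zero diagonal
    ld: LDMatrix

    def __post_init__(self) -> None:
        self.w_pair = np.asarray(self.w_pair, dtype=float)
        if self.w_pair.ndim != 3 or self.w_pair.shape[0] != 3:
            raise ValueError("w_pair must have shape (3, L, L)")


@dataclass
class ScoreSet:
    """Per-individual genetic scores S_j(k) for k = 1, 2, 3."""

    s: np.ndarray  # shape (3, N)
    pr: float
    degenerate: bool = False  # PR == 0: no rare variants, all scores zero

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        if self.s.ndim != 2 or self.s.shape[0] != 3:
            raise ValueError("s must have shape (3, N)")
        if not np.isfinite(self.s).all():
            raise ValueError("scores must be finite")


def estimate_maf(region: RegionGenotypes) -> np.ndarray:
    """Pooled-sample minor allele frequency per variant.

    Missing genotypes are excluded from the counts. Raises on a monomorphic
    variant (weight 1/MF would be undefined); drop such variants upstream.
    """
    minor, total = region.allele_counts()
    if (total == 0).any():
        raise ValueError("variant with no called genotypes")
    mf = minor / total
    if (mf == 0).any():
        bad = [region.variant_ids[i] for i in np.where(mf == 0)[0]]
        raise ValueError(f"monomorphic variant(s): {bad}")
    if (mf > 0.5).any():
        raise ValueError(
            "allele frequency above 0.5: genotypes are not minor-allele coded"
        )
    return mf


def estimate_or(
    region: RegionGenotypes, phenotype: PhenotypeVector, haldane: bool = True
) -> np.ndarray:
    """Allelic odds ratio per variant from the 2x2 allele-count table.

    OR_i = (case minor * control major) / (case major * control minor); with
    ``haldane`` (default) 0.5 is added to every cell of a table containing a
    zero (Haldane-Anscombe correction), keeping the estimate finite.
    """
    phenotype.require_both_groups()
    if phenotype.n != region.n_individuals:
        raise ValueError("phenotype length does not match individuals")
    case = phenotype.case_mask
    Xc = region.X[:, case]
    Xu = region.X[:, ~case]

    def _counts(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        called = X != -1
        minor = np.where(called, X, 0).sum(axis=1).astype(float)
        major = (2 * called.sum(axis=1) - minor).astype(float)
        return minor, major

    a, b = _counts(Xc)  # case minor, case major
    c, d = _counts(Xu)  # control minor, control major
    cells = np.stack([a, b, c, d])
    if haldane:
        zero = (cells == 0).any(axis=0)
        cells[:, zero] += 0.5
    a, b, c, d = cells
    if ((b == 0) | (c == 0)).any():
        raise ValueError("zero denominator in odds ratio; enable haldane")
    return (a * d) / (b * c)


def main_weights(stats: VariantStats) -> np.ndarray:
    """Main-effect weights W_i = |log2 OR_i| / MF_i."""
    return np.abs(np.log2(stats.or_)) / stats.mf


def pair_weights(stats: VariantStats, ld: LDMatrix) -> PairWeightSet:
    """The three pairwise weight matrices, LD-damped by the factor (1 - D')."""
    L = stats.mf.size
    if ld.dprime.shape != (L, L):
        raise ValueError("LD matrix does not match the variant list")
    logor = np.log2(stats.or_)
    inv_mf = 1.0 / stats.mf
    sum_log = logor[:, None] + logor[None, :]
    sum_abs = np.abs(logor)[:, None] + np.abs(logor)[None, :]
    sum_inv = inv_mf[:, None] + inv_mf[None, :]
    damp = 1.0 - ld.dprime
    w = np.stack([sum_log * sum_inv * damp,
                  np.abs(sum_log) * sum_inv * damp,
                  sum_abs * sum_inv * damp])
    for k in range(3):
        np.fill_diagonal(w[k], 0.0)
    return PairWeightSet(w_pair=w, ld=ld)


def rare_proportion(mf: np.ndarray, threshold: float = RARE_MAF_THRESHOLD) -> float:
    """PR: fraction of the region's variants with MAF below ``threshold``."""
    mf = np.asarray(mf, dtype=float)
    if mf.size == 0:
        raise ValueError("empty MAF vector")
    return float((mf < threshold).mean())


def genetic_scores(
    region: RegionGenotypes,
    stats: VariantStats,
    pairs: PairWeightSet,
    pr: float | None = None,
) -> ScoreSet:
    """Per-individual scores S_j(k), k = 1..3.

    The pair sum runs over unordered pairs i < m, each counted once; since
    each pair contributes X_ij + X_mj, the score is linear in X with
    coefficient W_i + sum_{m != i} W_im(k) for variant i. Missing genotypes
    contribute 0. ``pr`` overrides the computed rare-variant proportion
    (useful for invariance checks).
    """
    if pr is None:
        pr = rare_proportion(stats.mf)
    X = np.maximum(region.X, 0).astype(float)  # missing -> 0
    coeffs = stats.w[None, :] + pairs.w_pair.sum(axis=2)  # (3, L)
    s = pr * (coeffs @ X)
    return ScoreSet(s=s, pr=pr, degenerate=(pr == 0.0))
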