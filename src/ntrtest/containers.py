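"""Core in-memory containers for region-based case-control genotype data.

Genotypes are stored as minor-allele counts in a variants-by-individuals
matrix. ``MISSING`` (-1) marks an uncalled genotype; every called entry is
0, 1 or 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Sentinel for an uncalled genotype in ``RegionGenotypes.X``.
MISSING: int = -1


@dataclass
class PhenotypeVector:
    """Binary affected (1) / unaffected (0) status, one entry per individual."""

    status: np.ndarray
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.status = np.asarray(self.status, dtype=np.int8)
        if self.status.ndim != 1:
            raise ValueError("status must be a 1-D vector")
        if not np.isin(self.status, (0, 1)).all():
            raise ValueError("status entries must be 0 (control) or 1 (case)")
        if self.sample_ids is not None and len(self.sample_ids) != self.status.size:
            raise ValueError("sample_ids length does not match status")

    @property
    def n(self) -> int:
        return int(self.status.size)

    @property
    def n_cases(self) -> int:
        return int(self.status.sum())

    @property
    def n_controls(self) -> int:
        return int(self.n - self.n_cases)

    @property
    def case_mask(self) -> np.ndarray:
        return self.status == 1

    def require_both_groups(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("need at least one case and one control")


@dataclass
class RegionGenotypes:
    """Minor-allele count matrix for one analysis region.

    Parameters
    ----------
    region_id:
        Text label of the gene / region.
    variant_ids:
        One label per variant (row of ``X``).
    positions:
        1-based base-pair coordinates, one per variant.
    X:
        ``(L, N)`` int matrix of minor-allele counts, ``MISSING`` = -1.
    minor_allele, major_allele:
        Per-variant allele labels; the minor allele is the less frequent
        allele in the pooled sample.
    phased_haplotypes:
        Optional ``(L, 2N)`` 0/1 matrix; columns ``2j`` and ``2j+1`` are the
        two haplotypes of individual ``j`` and sum to ``X[:, j]``.
    single_variant:
        Set by region slicing when the region holds exactly one variant
        (such regions are excluded from the pairwise test).
    """

    region_id: str
    variant_ids: list[str]
    positions: np.ndarray
    X: np.ndarray
    minor_allele: list[str] | None = None
    major_allele: list[str] | None = None
    chrom: list[str] | None = None
    phased_haplotypes: np.ndarray | None = None
    single_variant: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D (variants x individuals) matrix")
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if len(self.variant_ids) != self.X.shape[0]:
            raise ValueError("variant_ids length does not match X rows")
        if self.positions.size != self.X.shape[0]:
            raise ValueError("positions length does not match X rows")
        self.validate()

    @property
    def n_variants(self) -> int:
        return int(self.X.shape[0])

    @property
    def n_individuals(self) -> int:
        return int(self.X.shape[1])

    @property
    def missing_mask(self) -> np.ndarray:
        return self.X == MISSING

    def validate(self) -> None:
        called = self.X[self.X != MISSING]
        if called.size and (called.min() < 0 or called.max() > 2):
            raise ValueError("called genotypes must be 0, 1 or 2")
        H = self.phased_haplotypes
        if H is not None:
            H = np.asarray(H)
            if H.shape != (self.n_variants, 2 * self.n_individuals):
                raise ValueError("phased_haplotypes must be (L, 2N)")
            if not np.isin(H, (0, 1)).all():
                raise ValueError("haplotype alleles must be 0/1")
            if not np.array_equal(H[:, 0::2] + H[:, 1::2], self.X):
                raise ValueError("haplotypes do not sum to genotypes")
            self.phased_haplotypes = H

    def subset_variants(self, idx: np.ndarray) -> "RegionGenotypes":
        """Return a copy restricted to the variant rows in ``idx``."""
        idx = np.asarray(idx)
        return RegionGenotypes(
            region_id=self.region_id,
            variant_ids=[self.variant_ids[i] for i in idx],
            positions=self.positions[idx],
            X=self.X[idx],
            minor_allele=None if self.minor_allele is None
            else [self.minor_allele[i] for i in idx],
            major_allele=None if self.major_allele is None
            else [self.major_allele[i] for i in idx],
            chrom=None if self.chrom is None else [self.chrom[i] for i in idx],
            phased_haplotypes=None if self.phased_haplotypes is None
            else self.phased_haplotypes[idx],
            single_variant=len(idx) == 1,
            meta=dict(self.meta),
        )

    def allele_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Pooled (minor, total called) allele counts per variant."""
        called = self.X != MISSING
        minor = np.where(called, self.X, 0).sum(axis=1)
        total = 2 * called.sum(axis=1)
        return minor.astype(np.int64), total.astype(np.int64)

    def polymorphic_mask(self) -> np.ndarray:
        """Variants with both alleles observed in the pooled called sample."""
        minor, total = self.allele_counts()
        return (minor > 0) & (minor < total)
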