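"""Case-control genotype simulator with latent AR(1) haplotype structure.

One region of L = n_causal + n_noise biallelic variants is simulated as:

1. target MAFs drawn per variant — rare ~ U(0.001, 0.01), common
   ~ U(0.01, 0.5) depending on the composition;
2. a latent N(0, Sigma) vector per haplotype with AR(1) covariance
   Sigma_ij = rho^|i-j| is dichotomized at Phi^{-1}(1 - MAF_i), so allele i
   is the minor allele with marginal probability MAF_i and neighbouring
   variants are correlated on the latent scale (rho is NOT an allele-scale
   D'; the induced LD is weaker and decays with distance);
3. two independent haplotypes per individual sum to the genotype;
4. disease status follows an additive logistic model
   P(D=1|X) = expit(beta0 + sum_causal ln(OR_i) X_i) with
   beta0 = logit(baseline_prob);
5. individuals are drawn until exactly n_cases cases and n_controls
   controls are retained (retrospective case-control sampling).

Defaults mirror the simulation study this package reproduces: 8 causal
variants, 3000 cases / 3001 controls, rho grid {0, 0.2, 0.4, 0.6}, noise
counts {0, 4, 8, 16, 32}, one-direction OR levels 1.2 / 1.5 and
two-direction pairs (2.5, 0.4) / (1.2, 0.8).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import linalg
from scipy.special import expit, logit, ndtri

from .containers import PhenotypeVector, RegionGenotypes

__all__ = [
    "ScenarioConfig",
    "SimulatedDataset",
    "draw_mafs",
    "simulate_haplotypes",
    "assign_disease",
    "sample_case_control",
]


@dataclass
class ScenarioConfig:
    """One simulation scenario.

    ``or_model`` is a single odds-ratio level applied to every causal
    variant (one direction), or a ``(risk, protective)`` pair (two
    directions) split ``n_risk`` / rest among the causal variants.
    ``or_model=1.0`` gives a pure null scenario.
    """

    rho: float = 0.2
    n_causal: int = 8
    n_noise: int = 0
    composition: str = "rare_only"  # or "rare_plus_common"
    or_model: float | tuple[float, float] = 1.2
    n_risk: int | None = None  # two-direction split; default ceil(n_causal/2)
    n_cases: int = 3000
    n_controls: int = 3001
    baseline_prob: float = 0.05
    rare_low: float = 0.001
    rare_high: float = 0.01
    common_high: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must lie in [0, 1)")
        if self.composition not in ("rare_only", "rare_plus_common"):
            raise ValueError("composition must be rare_only or rare_plus_common")
        if self.n_causal < 0 or self.n_noise < 0 or self.n_causal + self.n_noise < 1:
            raise ValueError("need at least one variant")
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("need at least one case and one control")
        if not 0.0 < self.baseline_prob < 1.0:
            raise ValueError("baseline_prob must lie in (0, 1)")
        ors = self.or_model if isinstance(self.or_model, tuple) else (self.or_model,)
        if any(o <= 0 for o in ors):
            raise ValueError("odds-ratio levels must be positive")

    @property
    def n_variants(self) -> int:
        return self.n_causal + self.n_noise

    def true_ors(self) -> np.ndarray:
        """Per-variant true odds ratios (1.0 for noise variants)."""
        ors = np.ones(self.n_variants)
        if isinstance(self.or_model, tuple):
            risk, prot = self.or_model
            n_risk = self.n_risk
            if n_risk is None:
                n_risk = math.ceil(self.n_causal / 2)
            if not 0 <= n_risk <= self.n_causal:
                raise ValueError("n_risk out of range")
            ors[:n_risk] = risk
            ors[n_risk:self.n_causal] = prot
        else:
            ors[: self.n_causal] = self.or_model
        return ors

    def causal_mask(self) -> np.ndarray:
        mask = np.zeros(self.n_variants, dtype=bool)
        mask[: self.n_causal] = True
        return mask


@dataclass
class SimulatedDataset:
    """Simulated region with truth annotations."""

    region: RegionGenotypes
    phenotype: PhenotypeVector
    true_maf: np.ndarray
    true_or: np.ndarray
    causal: np.ndarray
    config: ScenarioConfig = field(repr=False, default=None)


def draw_mafs(config: ScenarioConfig, rng: np.random.Generator) -> np.ndarray:
    """Target minor-allele frequencies for every variant (causal and noise).

    ``rare_only``: all variants ~ U(rare_low, rare_high). In
    ``rare_plus_common`` each variant is rare with probability 1/2 and
    otherwise common ~ U(rare_high, common_high); noise variants follow the
    same composition as the scenario.
    """
    L = config.n_variants
    rare = rng.uniform(config.rare_low, config.rare_high, size=L)
    if config.composition == "rare_only":
        return rare
    common = rng.uniform(config.rare_high, config.common_high, size=L)
    is_rare = rng.random(L) < 0.5
    return np.where(is_rare, rare, common)


def _ar1_cholesky(rho: float, L: int) -> np.ndarray | None:
    if rho == 0.0 or L == 1:
        return None
    cov = rho ** np.abs(np.subtract.outer(np.arange(L), np.arange(L)))
    return linalg.cholesky(cov, lower=True)


def simulate_haplotypes(
    mafs: np.ndarray,
    rho: float,
    n_haplotypes: int,
    rng: np.random.Generator,
    chol: np.ndarray | None = None,
) -> np.ndarray:
    """Draw ``n_haplotypes`` binary haplotypes of length L.

    Latent vectors are N(0, Sigma) with Sigma_ij = rho^|i-j|; allele i is 1
    (minor) when the latent component exceeds Phi^{-1}(1 - MAF_i), so the
    marginal minor-allele probability equals MAF_i exactly.
    """
    mafs = np.asarray(mafs, dtype=float)
    L = mafs.size
    z = rng.standard_normal((n_haplotypes, L))
    if chol is None:
        chol = _ar1_cholesky(rho, L)
    if chol is not None:
        z = z @ chol.T
    thresholds = ndtri(1.0 - mafs)
    return (z > thresholds).astype(np.int8)


def assign_disease(
    X: np.ndarray, config: ScenarioConfig, rng: np.random.Generator,
    true_ors: np.ndarray | None = None,
) -> np.ndarray:
    """Bernoulli disease status under the additive logistic model.

    ``X`` is (n, L) minor-allele counts; log-odds are
    logit(baseline_prob) + sum_i ln(OR_i) X_i with OR_i = 1 for noise
    variants.
    """
    if true_ors is None:
        true_ors = config.true_ors()
    beta0 = logit(config.baseline_prob)
    eta = beta0 + X @ np.log(true_ors)
    prob = expit(eta)
    return (rng.random(X.shape[0]) < prob).astype(np.int8)


def sample_case_control(
    config: ScenarioConfig,
    seed: int | np.random.Generator | None = None,
    max_batches: int = 10_000,
    batch_size: int | None = None,
) -> SimulatedDataset:
    """Simulate one case-control dataset with exact group sizes.

    Individuals are generated in batches and assigned to the case or control
    pool until both quotas are filled (rejection sampling, as in a
    retrospective design). True phased haplotypes are retained on the
    returned region. Cases precede controls in the output ordering.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(
        seed if seed is not None else config.seed
    )
    L = config.n_variants
    mafs = draw_mafs(config, rng)
    true_ors = config.true_ors()
    chol = _ar1_cholesky(config.rho, L)

    need = config.n_cases + config.n_controls
    if batch_size is None:
        # expected yield of the scarcer group governs how many draws we need
        batch_size = max(2048, int(need / max(config.baseline_prob, 0.02)) // 4)
    got_cases: list[np.ndarray] = []
    got_controls: list[np.ndarray] = []
    hap_cases: list[np.ndarray] = []
    hap_controls: list[np.ndarray] = []
    n_ca = n_co = 0
    for _ in range(max_batches):
        haps = simulate_haplotypes(mafs, config.rho, 2 * batch_size, rng, chol=chol)
        X = haps[0::2] + haps[1::2]  # (batch, L)
        status = assign_disease(X, config, rng, true_ors=true_ors)
        if n_ca < config.n_cases:
            idx = np.where(status == 1)[0][: config.n_cases - n_ca]
            got_cases.append(X[idx])
            hap_cases.append(np.stack([haps[2 * idx], haps[2 * idx + 1]], axis=1))
            n_ca += idx.size
        if n_co < config.n_controls:
            idx = np.where(status == 0)[0][: config.n_controls - n_co]
            got_controls.append(X[idx])
            hap_controls.append(np.stack([haps[2 * idx], haps[2 * idx + 1]], axis=1))
            n_co += idx.size
        if n_ca >= config.n_cases and n_co >= config.n_controls:
            break
    else:
        raise RuntimeError(
            "case/control quotas not reached; check baseline_prob and OR model"
        )

    X = np.concatenate(got_cases + got_controls).T.astype(np.int8)  # (L, N)
    hap = np.concatenate(hap_cases + hap_controls)  # (N, 2, L)
    H = hap.transpose(2, 0, 1).reshape(L, 2 * need)  # (L, 2N) interleaved
    status = np.concatenate(
        [np.ones(config.n_cases, dtype=np.int8),
         np.zeros(config.n_controls, dtype=np.int8)]
    )
    region = RegionGenotypes(
        region_id="simulated",
        variant_ids=[f"snp{i + 1}" for i in range(L)],
        positions=np.arange(1, L + 1) * 1000,
        X=X,
        minor_allele=["C"] * L,
        major_allele=["A"] * L,
        chrom=["1"] * L,
        phased_haplotypes=H,
    )
    return SimulatedDataset(
        region=region,
        phenotype=PhenotypeVector(status=status),
        true_maf=mafs,
        true_or=true_ors,
        causal=config.causal_mask(),
        config=replace(config),
    )
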