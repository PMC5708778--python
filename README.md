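# ntrtest

Region-based case-control association testing for **mixed common and
rare variants without a MAF threshold**, for statistical geneticists
analyzing gene- or region-level burdens in resequencing / dense-array
studies. The package implements the NTR (non-threshold rare) test — an
LD-aware, odds-ratio- and frequency-weighted genetic score assessed by a
permutation rank-sum — together with the standard comparator tests
(CMC, WSS, SKAT, SKAT-O, single-variant trend), a latent-AR(1)
case-control simulator, and power / type-I-error study orchestration.

## The test in brief

For a region of `L` variants with minor-allele counts `X_ij`, each
individual gets a score

```
S_j(k) = [ Σ_i W_i X_ij + Σ_{i<m} W_im(k) (X_ij + X_mj) ] × PR
```

* `W_i = |log2 OR_i| / MF_i` — rare alleles with strong effects weigh
  most;
* `W_im(k)`, k = 1,2,3 — three pairwise weights sharing magnitudes but
  treating effect *directions* differently (signed sum, absolute sum,
  sum of absolutes), each damped by `(1 − D'_im)` so variant pairs in
  strong LD (Hedrick's D') contribute little;
* `PR` — the fraction of variants in the region with MAF < 0.01.

The sum of case ranks `R(k)` is standardized against label permutations
(re-estimating the OR-derived weights under every permuted labelling) to
`Z(k)`; the best of the three weighting schemes is selected and the
selection is corrected by a Benjamini–Hochberg adjustment over the three
per-k p-values. Regions are combined with FDR across regions.

## Worked example

```python
import numpy as np
from ntrtest import ScenarioConfig, sample_case_control, ntr_region_test, skat_test

# a region with eight rare causal variants (OR 1.5 each), latent rho 0.2
cfg = ScenarioConfig(rho=0.2, n_causal=8, n_noise=0, or_model=1.5,
                     n_cases=1000, n_controls=1001)
data = sample_case_control(cfg, seed=7)

res = ntr_region_test(data.region, data.phenotype, n_perm=1000, seed=1)
print(f"Z = {np.round(res.z, 3)}  k* = {res.k_star}  p = {res.p:.4g}")
print(f"SKAT p = {skat_test(data.region, data.phenotype).p:.4g}")
```

prints

```
Z = [2.879 3.673 3.706]  k* = 3  p = 0.0003598
SKAT p = 0.01161
```

All three standardized rank sums flag the excess burden in cases; the
direction-free scheme (k = 3) wins here with Z ≈ 3.7, and after the
three-way selection correction the region p-value is ≈ 3.6e-4 — about
thirty-fold smaller than SKAT's on the same data, reflecting the
1/MAF-weighted score's sensitivity to same-direction rare-variant
effects.

On real data:

```sh
ntr test --vcf study.vcf --phenotype samples.tsv --regions genes.tsv \
    --permutations 1000 --seed 1 --out results.tsv
```

with `genes.tsv` mapping `region_id → variant_id` (or a BED file of
intervals). Input passes call-rate (≥ 0.95) and control-HWE
(p ≥ 1e-4) filters first; single-variant regions are excluded. PLINK
bed/bim/fam input is supported via `--plink`. `ntr simulate` exports
simulated datasets as VCF + phenotype TSV; `ntr power-grid` runs scenario
grids from a YAML config.

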