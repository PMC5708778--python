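"""Reading genotypes from VCF / PLINK, QC filtering, and region slicing.

The full dataset is held as one :class:`RegionGenotypes` spanning every
retained biallelic SNP, with the minor allele determined from the pooled
(cases + controls) sample, plus a :class:`PhenotypeVector`. Regions are cut
from it by gene -> variant lists or BED intervals.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import MISSING, PhenotypeVector, RegionGenotypes

__all__ = [
    "read_genotypes",
    "read_phenotype_tsv",
    "qc_filter",
    "QCReport",
    "hwe_chisq_pvalue",
    "hwe_exact_pvalue",
    "slice_regions",
    "read_region_spec",
    "write_vcf",
    "write_phenotype_tsv",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# phenotype sidecar


def read_phenotype_tsv(path: str | Path) -> dict[str, int]:
    """Two-column TSV (sample_id, status in {0, 1}) -> mapping."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("phenotype file needs columns sample_id, status")
    if set(df.iloc[0]) & {"sample_id", "status"}:
        df = df.iloc[1:]
    status = df.iloc[:, 1].astype(int)
    if not status.isin([0, 1]).all():
        raise ValueError("phenotype status must be 0 or 1")
    return dict(zip(df.iloc[:, 0], status))


# ---------------------------------------------------------------------------
# VCF


def _read_vcf(path: str | Path) -> tuple[RegionGenotypes, list[str]]:
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # unreadable / malformed
        raise ValueError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    rows, ids, positions, chroms, refs, alts = [], [], [], [], [], []
    n_multi = 0
    for v in vcf:
        if len(v.ALT) != 1 or v.ALT[0] is None:
            n_multi += 1
            continue
        # gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        gt = np.asarray(v.gt_types)
        row = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=MISSING)
        rows.append(row.astype(np.int8))
        ids.append(v.ID if v.ID else f"{v.CHROM}:{v.POS}")
        positions.append(v.POS)
        chroms.append(v.CHROM)
        refs.append(v.REF)
        alts.append(v.ALT[0])
    if n_multi:
        log.warning("dropped %d multi-allelic site(s)", n_multi)
    if not rows:
        raise ValueError("no biallelic variants")
    X = np.vstack(rows)
    region = RegionGenotypes(
        region_id="all",
        variant_ids=ids,
        positions=np.array(positions),
        X=X,
        minor_allele=list(alts),
        major_allele=list(refs),
        chrom=chroms,
    )
    return region, samples


# ---------------------------------------------------------------------------
# PLINK bed/bim/fam (SNP-major bed; 2-bit codes per genotype)

_BED_LOOKUP = None


def _bed_lookup() -> np.ndarray:
    """256 x 4 table: byte -> four A1-allele counts (MISSING for code 01)."""
    global _BED_LOOKUP
    if _BED_LOOKUP is None:
        tab = np.empty((256, 4), dtype=np.int8)
        # 2-bit codes: 00 hom A1 (2 copies), 01 missing, 10 het, 11 hom A2
        code_map = {0: 2, 1: MISSING, 2: 1, 3: 0}
        for byte in range(256):
            for k in range(4):
                tab[byte, k] = code_map[(byte >> (2 * k)) & 0b11]
        _BED_LOOKUP = tab
    return _BED_LOOKUP


def _read_plink(prefix: str | Path) -> tuple[RegionGenotypes, list[str], np.ndarray]:
    prefix = Path(prefix)
    bed_path = prefix.with_suffix(".bed")
    bim = pd.read_csv(
        prefix.with_suffix(".bim"), sep=r"\s+", header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"], dtype={"chrom": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"), sep=r"\s+", header=None,
        names=["fid", "iid", "pid", "mid", "sex", "pheno"],
    )
    raw = np.fromfile(bed_path, dtype=np.uint8)
    if raw.size < 3 or raw[0] != 0x6C or raw[1] != 0x1B:
        raise ValueError(f"{bed_path} is not a PLINK bed file")
    if raw[2] != 0x01:
        raise ValueError("only SNP-major bed files are supported")
    n = len(fam)
    L = len(bim)
    bpv = math.ceil(n / 4)  # bytes per variant
    body = raw[3:]
    if body.size != bpv * L:
        raise ValueError("bed size does not match bim/fam dimensions")
    X = _bed_lookup()[body.reshape(L, bpv)].reshape(L, bpv * 4)[:, :n]
    # fam phenotype: 1 = control, 2 = case; 0/-9 = missing
    pheno = fam["pheno"].to_numpy()
    status = np.where(pheno == 2, 1, np.where(pheno == 1, 0, MISSING)).astype(np.int8)
    region = RegionGenotypes(
        region_id="all",
        variant_ids=bim["id"].astype(str).tolist(),
        positions=bim["pos"].to_numpy(),
        X=X,
        minor_allele=bim["a1"].astype(str).tolist(),
        major_allele=bim["a2"].astype(str).tolist(),
        chrom=bim["chrom"].astype(str).tolist(),
    )
    return region, fam["iid"].astype(str).tolist(), status


# ---------------------------------------------------------------------------
# entry point


def _orient_minor(region: RegionGenotypes) -> RegionGenotypes:
    """Flip variants so X counts the pooled-sample minor allele."""
    minor, total = region.allele_counts()
    with np.errstate(invalid="ignore"):
        freq = np.where(total > 0, minor / np.maximum(total, 1), 0.0)
    flip = freq > 0.5
    if flip.any():
        X = region.X.copy()
        rows = np.where(flip)[0]
        sub = X[rows]
        X[rows] = np.where(sub == MISSING, MISSING, 2 - sub)
        ma = list(region.minor_allele or [])
        mj = list(region.major_allele or [])
        for i in rows:
            ma[i], mj[i] = mj[i], ma[i]
        H = region.phased_haplotypes
        if H is not None:
            H = H.copy()
            H[rows] = 1 - H[rows]
        region = RegionGenotypes(
            region_id=region.region_id,
            variant_ids=region.variant_ids,
            positions=region.positions,
            X=X,
            minor_allele=ma,
            major_allele=mj,
            chrom=region.chrom,
            phased_haplotypes=H,
            meta=region.meta,
        )
    return region


def read_genotypes(
    path: str | Path,
    format: str = "vcf",
    phenotype_path: str | Path | None = None,
) -> tuple[RegionGenotypes, PhenotypeVector]:
    """Read a full dataset from VCF or PLINK, minor-allele oriented.

    VCF requires a phenotype sidecar TSV; PLINK takes status from fam
    column 6 unless a sidecar overrides it. Multi-allelic sites are dropped
    with a warning.
    """
    pheno_map = read_phenotype_tsv(phenotype_path) if phenotype_path else None
    if format == "vcf":
        region, samples = _read_vcf(path)
        if pheno_map is None:
            raise ValueError(
                "phenotype required: VCF input needs a sample-phenotype TSV"
            )
        status = np.array([pheno_map.get(s, MISSING) for s in samples], dtype=np.int8)
    elif format == "plink":
        region, samples, status = _read_plink(path)
        if pheno_map is not None:
            status = np.array(
                [pheno_map.get(s, MISSING) for s in samples], dtype=np.int8
            )
    else:
        raise ValueError(f"unknown format {format!r}; use 'vcf' or 'plink'")
    if (status == MISSING).any():
        missing = [s for s, st in zip(samples, status) if st == MISSING]
        raise ValueError(
            f"phenotype required: no status for sample(s) {missing[:5]}..."
        )
    region = _orient_minor(region)
    return region, PhenotypeVector(status=status, sample_ids=samples)


# ---------------------------------------------------------------------------
# QC


def hwe_chisq_pvalue(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Chi-square (1 df) Hardy-Weinberg goodness-of-fit p-value."""
    n = n_aa + n_ab + n_bb
    if n == 0:
        return 1.0
    p = (2 * n_aa + n_ab) / (2 * n)
    if p in (0.0, 1.0):
        return 1.0
    exp = np.array([n * p * p, 2 * n * p * (1 - p), n * (1 - p) ** 2])
    obs = np.array([n_aa, n_ab, n_bb], dtype=float)
    stat = float(np.sum((obs - exp) ** 2 / exp))
    return float(sps.chi2.sf(stat, 1))


def hwe_exact_pvalue(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact Hardy-Weinberg test (sum of probabilities <= that observed)."""
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab  # rarer-allele copies by convention below
    if n == 0:
        return 1.0
    n_a = min(n_a, 2 * n - n_a)
    # log-probability of each possible heterozygote count with same margins
    hets = np.arange(n_a % 2, n_a + 1, 2)
    from scipy.special import gammaln

    def logfact(x):
        return gammaln(np.asarray(x) + 1.0)

    n_b = 2 * n - n_a
    logp = (
        hets * np.log(2.0)
        + logfact(n)
        - logfact((n_a - hets) // 2)
        - logfact(hets)
        - logfact((n_b - hets) // 2)
        + logfact(n_a)
        + logfact(n_b)
        - logfact(2 * n)
    )
    prob = np.exp(logp - logp.max())
    prob /= prob.sum()
    p_obs = prob[hets == n_ab]
    if p_obs.size == 0:
        return 1.0
    return float(min(1.0, prob[prob <= p_obs[0] * (1 + 1e-12)].sum()))


@dataclass
class QCReport:
    """Per-variant exclusions with reasons ('call_rate' or 'hwe')."""

    excluded: list[tuple[str, str]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.excluded, columns=["variant_id", "reason"])


def qc_filter(
    region: RegionGenotypes,
    phenotype: PhenotypeVector,
    call_rate_min: float = 0.95,
    hwe_alpha: float = 1e-4,
    hwe_method: str = "chisq",
) -> tuple[RegionGenotypes, QCReport]:
    """Drop variants by call rate and Hardy-Weinberg departure in controls.

    A variant is removed when its genotype call rate is below
    ``call_rate_min`` or its HWE p-value among controls falls below
    ``hwe_alpha`` (chi-square 1 df by default; ``hwe_method='exact'`` for
    the exact test).
    """
    if not 0.0 <= call_rate_min <= 1.0:
        raise ValueError("call_rate_min must lie in [0, 1]")
    hwe_fn = {"chisq": hwe_chisq_pvalue, "exact": hwe_exact_pvalue}[hwe_method]
    controls = ~phenotype.case_mask
    report = QCReport()
    keep = []
    for i in range(region.n_variants):
        x = region.X[i]
        call_rate = float((x != MISSING).mean())
        if call_rate < call_rate_min:
            report.excluded.append((region.variant_ids[i], "call_rate"))
            continue
        xc = x[controls]
        xc = xc[xc != MISSING]
        counts = [(xc == g).sum() for g in (2, 1, 0)]  # aa, Aa, AA in controls
        if hwe_fn(*counts) < hwe_alpha:
            report.excluded.append((region.variant_ids[i], "hwe"))
            continue
        keep.append(i)
    if not keep:
        log.warning("qc_filter removed every variant")
        filtered = region.subset_variants(np.array([], dtype=int))
    else:
        filtered = region.subset_variants(np.array(keep))
        filtered.single_variant = False
    return filtered, report


# ---------------------------------------------------------------------------
# region slicing


def read_region_spec(path: str | Path) -> dict[str, object]:
    """Read a region definition file.

    Two-column TSV (region_id, variant_id) -> {region: [variant ids]};
    BED (chrom, start, end[, name]) -> {region: (chrom, start, end)} with
    half-open 0-based intervals.
    """
    path = Path(path)
    if path.suffix.lower() == ".bed":
        bed = pd.read_csv(path, sep="\t", header=None, comment="#")
        spec: dict[str, object] = {}
        for idx, row in bed.iterrows():
            name = row[3] if bed.shape[1] > 3 else f"{row[0]}:{row[1]}-{row[2]}"
            spec[str(name)] = (str(row[0]), int(row[1]), int(row[2]))
        return spec
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    spec = {}
    for region_id, grp in df.groupby(0, sort=False):
        spec[str(region_id)] = grp[1].tolist()
    return spec


def slice_regions(
    region: RegionGenotypes,
    region_spec: dict[str, object],
) -> list[RegionGenotypes]:
    """Cut the full dataset into per-region :class:`RegionGenotypes`.

    ``region_spec`` maps region id -> list of variant ids, or -> a
    ``(chrom, start, end)`` half-open interval. Regions matching no variant
    are skipped with a warning; single-variant regions are flagged
    (the pairwise test cannot run on them).
    """
    id_index = {v: i for i, v in enumerate(region.variant_ids)}
    out = []
    for rid, sel in region_spec.items():
        if isinstance(sel, tuple):
            chrom, start, end = sel
            mask = (region.positions >= start + 1) & (region.positions <= end)
            if region.chrom is not None:
                mask &= np.array([c == chrom for c in region.chrom])
            idx = np.where(mask)[0]
        else:
            idx = np.array([id_index[v] for v in sel if v in id_index], dtype=int)
        if idx.size == 0:
            log.warning("region %s matches no variants; skipped", rid)
            continue
        sub = region.subset_variants(idx)
        sub.region_id = rid
        sub.single_variant = idx.size == 1
        out.append(sub)
    return out


# ---------------------------------------------------------------------------
# VCF export (minor allele written as ALT, so a round trip reproduces X)


def write_vcf(
    region: RegionGenotypes,
    path: str | Path,
    sample_ids: list[str] | None = None,
) -> None:
    """Write genotypes as an uncompressed VCF 4.2 text file."""
    N = region.n_individuals
    if sample_ids is None:
        sample_ids = [f"s{j + 1}" for j in range(N)]
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    chroms = region.chrom or ["1"] * region.n_variants
    ref = region.major_allele or ["A"] * region.n_variants
    alt = region.minor_allele or ["C"] * region.n_variants
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in dict.fromkeys(chroms):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_ids) + "\n"
        )
        H = region.phased_haplotypes
        for i in range(region.n_variants):
            if H is not None:
                gts = [f"{H[i, 2 * j]}|{H[i, 2 * j + 1]}" for j in range(N)]
            else:
                gts = [gt_map[int(g)] for g in region.X[i]]
            fh.write(
                f"{chroms[i]}\t{region.positions[i]}\t{region.variant_ids[i]}\t"
                f"{ref[i]}\t{alt[i]}\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def write_phenotype_tsv(
    phenotype: PhenotypeVector, path: str | Path, sample_ids: list[str] | None = None
) -> None:
    """Write the (sample_id, status) sidecar matching :func:`write_vcf`."""
    ids = sample_ids or phenotype.sample_ids or [
        f"s{j + 1}" for j in range(phenotype.n)
    ]
    pd.DataFrame({"sample_id": ids, "status": phenotype.status}).to_csv(
        path, sep="\t", header=False, index=False
    )
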