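"""Per-SNP quality control and cross-population frequency comparison.

Covers call rate, risk-allele frequency (RAF), the 1-df Pearson chi-square
test of Hardy-Weinberg equilibrium, the allelic 2x2 chi-square comparing
RAFs between two populations, and the closed-form expected score under HWE
(E[GRS] = sum_i 2 RAF_i w_i).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenotypeTable

logger = logging.getLogger(__name__)

__all__ = [
    "SnpQcResult",
    "FreqComparison",
    "hwe_test",
    "hwe_exact_test",
    "snp_qc",
    "call_rate",
    "allele_frequency_compare",
    "compare_populations",
    "expected_grs_hwe",
]


@dataclass(frozen=True)
class SnpQcResult:
    rsid: str
    call_rate: float
    raf: float
    genotype_counts: tuple[int, int, int]
    hwe_chi2: float
    hwe_p: float


@dataclass(frozen=True)
class FreqComparison:
    rsid: str
    raf_a: float
    raf_b: float
    n_alleles_a: int
    n_alleles_b: int
    chi2: float
    p: float


def hwe_test(genotype_counts: Sequence[int]) -> tuple[float, float]:
    """Pearson 1-df chi-square test of Hardy-Weinberg proportions.

    ``genotype_counts`` are (n0, n1, n2) = counts of individuals with 0, 1,
    2 risk alleles.  Expected counts use the estimated allele frequency.
    A monomorphic SNP is in HWE by definition: chi2 = 0, P = 1.
    """
    n0, n1, n2 = (int(c) for c in genotype_counts)
    if min(n0, n1, n2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n0 + n1 + n2
    if n == 0:
        raise ValueError("no genotyped individuals")
    p = (n1 + 2 * n2) / (2 * n)
    if p in (0.0, 1.0):
        logger.info("monomorphic SNP: HWE chi2 defined as 0")
        return 0.0, 1.0
    expected = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2]) * n
    observed = np.array([n0, n1, n2], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def hwe_exact_test(genotype_counts: Sequence[int]) -> float:
    """Exact (Levene-Haldane) HWE test P value, for low-MAF SNPs.

    Enumerates all heterozygote counts compatible with the observed allele
    counts and sums the probabilities of configurations no more likely than
    the observed one.
    """
    n0, n1, n2 = (int(c) for c in genotype_counts)
    n = n0 + n1 + n2
    n_rare = min(n1 + 2 * n2, n1 + 2 * n0)
    if n == 0:
        raise ValueError("no genotyped individuals")
    if n_rare == 0:
        return 1.0

    from math import lgamma

    def log_prob(het: int) -> float:
        hom_rare = (n_rare - het) // 2
        hom_common = n - het - hom_rare
        # P(het | n, n_rare) under HWE, Levene's conditional distribution
        return (
            het * np.log(2)
            + lgamma(n + 1) - lgamma(hom_rare + 1) - lgamma(het + 1) - lgamma(hom_common + 1)
            + lgamma(n_rare + 1) + lgamma(2 * n - n_rare + 1) - lgamma(2 * n + 1)
        )

    hets = [h for h in range(n_rare % 2, n_rare + 1, 2) if (n - h - (n_rare - h) // 2) >= 0]
    logs = np.array([log_prob(h) for h in hets])
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    obs = probs[hets.index(n1)]
    return float(probs[probs <= obs * (1 + 1e-12)].sum())


def call_rate(table: GenotypeTable) -> pd.Series:
    """Fraction of non-missing calls per SNP."""
    df = table.dosages
    if df.empty:
        raise ValueError("empty genotype table")
    return 1.0 - df.isna().mean()


def snp_qc(table: GenotypeTable) -> pd.DataFrame:
    """Per-SNP QC table: call rate, RAF, genotype counts, HWE chi2 and P."""
    rows = []
    rates = call_rate(table)
    for rsid in table.snp_ids:
        col = table.dosages[rsid].dropna()
        counts = tuple(int((col == k).sum()) for k in (0, 1, 2))
        n = sum(counts)
        if n == 0:
            rows.append((rsid, 0.0, np.nan, *counts, np.nan, np.nan))
            continue
        raf = (counts[1] + 2 * counts[2]) / (2 * n)
        chi2, p = hwe_test(counts)
        rows.append((rsid, float(rates[rsid]), raf, *counts, chi2, p))
    return pd.DataFrame(
        rows, columns=["rsid", "call_rate", "raf", "n0", "n1", "n2", "hwe_chi2", "hwe_p"]
    ).set_index("rsid")


def allele_frequency_compare(
    a: tuple[float, int], b: tuple[float, int], rsid: str = ""
) -> FreqComparison:
    """Allelic 2x2 Pearson chi-square comparing two populations' RAFs.

    Each argument is (RAF, number of alleles = 2n individuals).  Allele
    counts are reconstructed by nearest-integer rounding of RAF * n_alleles;
    P values from rounded published frequencies are therefore approximate.
    """
    raf_a, n_a = a
    raf_b, n_b = b
    for raf, n in ((raf_a, n_a), (raf_b, n_b)):
        if not 0.0 <= raf <= 1.0:
            raise ValueError(f"RAF {raf} outside [0, 1]")
        if n <= 0:
            raise ValueError("allele count must be positive")
    risk_a = round(raf_a * n_a)
    risk_b = round(raf_b * n_b)
    tbl = np.array([[risk_a, n_a - risk_a], [risk_b, n_b - risk_b]], dtype=float)
    if tbl[:, 0].sum() in (0.0, tbl.sum()):  # same allele fixed in both groups
        return FreqComparison(rsid, raf_a, raf_b, n_a, n_b, 0.0, 1.0)
    chi2, p, _, _ = stats.chi2_contingency(tbl, correction=False)
    return FreqComparison(rsid, raf_a, raf_b, n_a, n_b, float(chi2), float(p))


def compare_populations(
    rafs_a: pd.DataFrame, rafs_b: pd.DataFrame, label_a: str = "a", label_b: str = "b"
) -> pd.DataFrame:
    """Per-SNP allelic chi-square between two RAF tables.

    Inputs are DataFrames indexed by rsid with columns ``raf`` and
    ``n_individuals`` (as produced by ``panel.load_raf_table`` or derivable
    from ``snp_qc`` output).  Returns one row per shared rsid.
    """
    shared = [r for r in rafs_a.index if r in rafs_b.index]
    if not shared:
        raise ValueError("no shared rsids between the two frequency tables")
    rows = []
    for rsid in shared:
        fa, na = float(rafs_a.loc[rsid, "raf"]), 2 * int(rafs_a.loc[rsid, "n_individuals"])
        fb, nb = float(rafs_b.loc[rsid, "raf"]), 2 * int(rafs_b.loc[rsid, "n_individuals"])
        cmp = allele_frequency_compare((fa, na), (fb, nb), rsid)
        rows.append((rsid, fa, fb, cmp.chi2, cmp.p))
    return pd.DataFrame(
        rows, columns=["rsid", f"raf_{label_a}", f"raf_{label_b}", "chi2", "p"]
    ).set_index("rsid")


def expected_grs_hwe(
    rafs: Mapping[str, float], weights: Mapping[str, float] | None = None
) -> float:
    """Expected score under HWE: sum over SNPs of 2 * RAF * weight.

    With unit weights this is the expectation of the risk-allele count,
    i.e. the large-sample mean of the unweighted score.
    """
    if weights is not None:
        mismatched = set(rafs) ^ set(weights)
        if mismatched:
            raise ValueError(f"RAF/weight key mismatch for: {sorted(mismatched)}")
    total = 0.0
    for rsid, raf in rafs.items():
        if not 0.0 <= raf <= 1.0:
            raise ValueError(f"RAF for {rsid} = {raf} outside [0, 1]")
        w = 1.0 if weights is None else float(weights[rsid])
        total += 2.0 * raf * w
    return total
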