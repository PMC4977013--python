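"""Synthetic case-control cohort generator.

Emulates the statistical structure the downstream analysis assumes: per-SNP
genotypes drawn independently under Hardy-Weinberg equilibrium at specified
risk-allele frequencies, binary cardiovascular risk factors (TCRFs) at
specified prevalences, age and BMI drawn from truncated normals, disease
assigned by a logistic model on the covariates and the risk-allele count,
and case-control ascertainment (fixed numbers of cases and controls sampled
from a generated superpopulation, by default 2 controls per case).

The default configurations mirror the two study populations: an
Afro-Caribbean sample (178 cases / 359 controls, control-column TCRF
prevalences, control RAFs, per-SD GRS odds ratio 1.40) and a white,
men-only NPHSII-like sample (146 cases / 1214 controls).

All randomness flows from a single integer seed through
``numpy.random.SeedSequence``; identical config + seed gives a bit-identical
cohort.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .panel import SnpPanel, load_panel, load_raf_table, grs14_subset

__all__ = [
    "SimulationConfig",
    "Cohort",
    "simulate_genotypes",
    "simulate_case_control",
    "inject_missingness",
    "calibrate_grs_effect",
    "hwe_grs_sd",
    "afro_caribbean_config",
    "white_config",
]

BINARY_TCRFS = ("hypertension", "diabetes", "hypercholesterolemia", "smoking")
OBESITY_BMI_THRESHOLD = 30.0

# Covariate log-odds: adjusted ORs of the multivariate CHD model
# (age per year 1.06, male sex 3.09, hypertension 4.30, diabetes 2.13,
#  hypercholesterolemia 3.45, smoking 3.06).
DEFAULT_EFFECT_SIZES: Mapping[str, float] = {
    "age": math.log(1.06),
    "sex": math.log(3.09),
    "hypertension": math.log(4.30),
    "diabetes": math.log(2.13),
    "hypercholesterolemia": math.log(3.45),
    "smoking": math.log(3.06),
}

# Control-group TCRF prevalences of the Afro-Caribbean sample.
AFRO_CARIBBEAN_PREVALENCES: Mapping[str, float] = {
    "hypertension": 0.301,
    "diabetes": 0.148,
    "hypercholesterolemia": 0.150,
    "smoking": 0.134,
}


@dataclass(frozen=True)
class Cohort:
    """Genotype dosages joined to covariates and CHD outcome for one population."""

    population: str
    genotypes: pd.DataFrame  # individuals x SNPs, {0,1,2} with NaN = missing
    covariates: pd.DataFrame  # age, sex, TCRFs, bmi, obesity
    outcome: pd.Series  # binary CHD status
    seed: int | None = None

    def __post_init__(self) -> None:
        n = len(self.genotypes)
        if len(self.covariates) != n or len(self.outcome) != n:
            raise ValueError(
                "genotypes, covariates and outcome must have equal row counts"
            )
        vals = self.genotypes.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("genotype dosages must be in {0, 1, 2} or missing")
        if self.outcome.isna().any():
            raise ValueError("outcome must be defined for every individual")

    @property
    def n_cases(self) -> int:
        return int(self.outcome.sum())

    @property
    def n_controls(self) -> int:
        return int((1 - self.outcome).sum())

    def subset(self, mask: np.ndarray | pd.Series, population: str | None = None) -> "Cohort":
        return Cohort(
            population=population or self.population,
            genotypes=self.genotypes.loc[mask].copy(),
            covariates=self.covariates.loc[mask].copy(),
            outcome=self.outcome.loc[mask].copy(),
            seed=self.seed,
        )


@dataclass
class SimulationConfig:
    """Generative model parameters for one case-control cohort.

    ``effect_sizes`` are log-odds per unit of each covariate;
    ``grs_effect_per_allele`` is the log-odds per risk allele (shared by all
    panel SNPs); ``target_prevalence`` calibrates the model intercept on the
    superpopulation by root-finding.
    """

    rafs: Mapping[str, float]
    covariate_prevalences: Mapping[str, float] = field(
        default_factory=lambda: dict(AFRO_CARIBBEAN_PREVALENCES)
    )
    age_mean: float = 51.66
    age_sd: float = 13.54
    sex_male_prob: float = 0.437
    bmi_mean: float = 27.15
    bmi_sd: float = 5.62
    effect_sizes: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECT_SIZES)
    )
    grs_effect_per_allele: float = 0.0
    target_prevalence: float = 0.10
    n_cases: int = 178
    n_controls: int = 359
    controls_per_case: int = 2
    missing_rate: float = 0.0
    superpopulation_size: int | None = None
    population: str = "simulated"
    seed: int = 0

    def validate(self) -> None:
        probs = {
            "target_prevalence": self.target_prevalence,
            "sex_male_prob": self.sex_male_prob,
            "missing_rate": self.missing_rate,
            **{f"raf[{k}]": v for k, v in self.rafs.items()},
            **{f"prevalence[{k}]": v for k, v in self.covariate_prevalences.items()},
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} = {p} outside [0, 1]")
        if not 0.0 < self.target_prevalence < 1.0:
            raise ValueError("target_prevalence must be in (0, 1)")
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("n_cases and n_controls must be positive")
        for k, v in self.effect_sizes.items():
            if not np.isfinite(v):
                raise ValueError(f"effect size for {k!r} is not finite")
        if not np.isfinite(self.grs_effect_per_allele):
            raise ValueError("grs_effect_per_allele is not finite")

    def default_superpopulation_size(self) -> int:
        need = max(
            self.n_cases / self.target_prevalence,
            self.n_controls / (1.0 - self.target_prevalence),
        )
        return int(math.ceil(3.0 * need))


def hwe_grs_sd(rafs: Mapping[str, float]) -> float:
    """Closed-form SD of the risk-allele count under HWE: sqrt(sum 2p(1-p))."""
    return float(np.sqrt(sum(2.0 * p * (1.0 - p) for p in rafs.values())))


def calibrate_grs_effect(or_per_sd: float, rafs: Mapping[str, float]) -> float:
    """Per-allele log-odds giving the requested per-SD odds ratio.

    The SD is the closed-form HWE SD of the unweighted allele count at the
    supplied frequencies.
    """
    if or_per_sd <= 0:
        raise ValueError("or_per_sd must be positive")
    sd = hwe_grs_sd(rafs)
    if sd == 0:
        raise ValueError("GRS SD is zero at these RAFs; cannot calibrate")
    return math.log(or_per_sd) / sd


def simulate_genotypes(
    rafs: Mapping[str, float],
    n: int,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Draw an n x SNP dosage matrix, each SNP i.i.d. Binomial(2, RAF)."""
    for rsid, p in rafs.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"RAF for {rsid} = {p} outside [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mat = rng.binomial(2, list(rafs.values()), size=(n, len(rafs)))
    return pd.DataFrame(mat, columns=list(rafs.keys()), dtype=np.int64)


def inject_missingness(
    matrix: pd.DataFrame, rate: float, seed: int | np.random.Generator = 0
) -> pd.DataFrame:
    """Set each entry missing (NaN) independently with probability ``rate``."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"missing rate {rate} outside [0, 1]")
    out = matrix.astype(float).copy()
    if rate == 0.0:
        return out
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mask = rng.random(out.shape) < rate
    out[mask] = np.nan
    return out


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, n: int
) -> np.ndarray:
    # resampling rejection; bounds are many SDs wide so a few rounds suffice
    out = rng.normal(mean, sd, size=n)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def _calibrate_intercept(eta: np.ndarray, target: float) -> float:
    """Root-find the intercept so the mean of expit(alpha + eta) hits target."""

    def f(alpha: float) -> float:
        return float(expit(alpha + eta).mean() - target)

    return brentq(f, -60.0, 60.0, xtol=1e-10, rtol=1e-12)


def simulate_case_control(config: SimulationConfig) -> Cohort:
    """Generate a superpopulation and ascertain a case-control cohort.

    Disease is Bernoulli(expit(alpha + sum beta_j x_j + gamma * GRS)) with the
    intercept alpha calibrated so the superpopulation prevalence equals
    ``target_prevalence`` (to 1e-6).  ``n_cases`` cases and ``n_controls``
    controls are then sampled without replacement.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_geno, rng_cov, rng_dis, rng_samp, rng_miss = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    n_super = config.superpopulation_size or config.default_superpopulation_size()
    geno = simulate_genotypes(config.rafs, n_super, rng_geno)

    cov = pd.DataFrame(index=geno.index)
    cov["age"] = _truncated_normal(
        rng_cov, config.age_mean, config.age_sd, 18.0, 100.0, n_super
    )
    cov["sex"] = rng_cov.binomial(1, config.sex_male_prob, size=n_super)
    for name in BINARY_TCRFS:
        prev = config.covariate_prevalences.get(name, 0.0)
        cov[name] = rng_cov.binomial(1, prev, size=n_super)
    cov["bmi"] = _truncated_normal(
        rng_cov, config.bmi_mean, config.bmi_sd, 12.0, 65.0, n_super
    )
    cov["obesity"] = (cov["bmi"] >= OBESITY_BMI_THRESHOLD).astype(int)

    eta = np.zeros(n_super)
    for name, beta in config.effect_sizes.items():
        if name not in cov.columns:
            raise ValueError(f"effect size given for unknown covariate {name!r}")
        eta += beta * cov[name].to_numpy(dtype=float)
    grs = geno.sum(axis=1).to_numpy(dtype=float)
    eta += config.grs_effect_per_allele * grs

    alpha = _calibrate_intercept(eta, config.target_prevalence)
    p_disease = expit(alpha + eta)
    disease = rng_dis.random(n_super) < p_disease

    case_idx = np.flatnonzero(disease)
    control_idx = np.flatnonzero(~disease)
    if len(case_idx) < config.n_cases or len(control_idx) < config.n_controls:
        raise ValueError(
            f"superpopulation of {n_super} yielded {len(case_idx)} cases / "
            f"{len(control_idx)} controls; requested {config.n_cases}/"
            f"{config.n_controls} - increase superpopulation_size"
        )
    chosen_cases = rng_samp.choice(case_idx, size=config.n_cases, replace=False)
    chosen_controls = rng_samp.choice(control_idx, size=config.n_controls, replace=False)
    chosen = np.concatenate([np.sort(chosen_cases), np.sort(chosen_controls)])

    geno_out = geno.iloc[chosen].reset_index(drop=True).astype(float)
    if config.missing_rate > 0:
        geno_out = inject_missingness(geno_out, config.missing_rate, rng_miss)
    cov_out = cov.iloc[chosen].reset_index(drop=True)
    outcome = pd.Series(
        np.r_[np.ones(config.n_cases), np.zeros(config.n_controls)].astype(int),
        name="chd",
    )
    ids = pd.Index([f"{config.population}_{i:05d}" for i in range(len(chosen))], name="sample_id")
    geno_out.index = ids
    cov_out.index = ids
    outcome.index = ids
    return Cohort(
        population=config.population,
        genotypes=geno_out,
        covariates=cov_out,
        outcome=outcome,
        seed=config.seed,
    )


def afro_caribbean_config(
    seed: int = 0,
    panel: SnpPanel | None = None,
    or_per_sd: float = 1.40,
    missing_rate: float = 0.0,
) -> SimulationConfig:
    """Study-condition defaults for the Afro-Caribbean case-control sample.

    178 cases / 359 controls (2 controls per case), control-group TCRF
    prevalences, control RAFs, and the GRS effect calibrated so the
    per-SD odds ratio of the unweighted 19-SNP score is ``or_per_sd``.
    """
    panel = panel or load_panel("grs19")
    raf_tbl = load_raf_table("afro_caribbean_controls")
    rafs = {r: float(raf_tbl.loc[r, "raf"]) for r in panel.rsids}
    return SimulationConfig(
        rafs=rafs,
        covariate_prevalences=dict(AFRO_CARIBBEAN_PREVALENCES),
        age_mean=51.66,
        age_sd=13.54,
        sex_male_prob=0.437,
        bmi_mean=27.15,
        bmi_sd=5.62,
        grs_effect_per_allele=calibrate_grs_effect(or_per_sd, rafs),
        n_cases=178,
        n_controls=359,
        missing_rate=missing_rate,
        population="afro_caribbean",
        seed=seed,
    )


def white_config(
    seed: int = 0,
    panel: SnpPanel | None = None,
    or_per_sd: float = 1.27,
    missing_rate: float = 0.0,
) -> SimulationConfig:
    """Study-condition defaults for the white NPHSII-like sample.

    Men only (middle-aged at recruitment), 146 incident cases / 1214
    controls, white-control RAFs, per-SD odds ratio of the unweighted
    19-SNP score defaulting to 1.27 (the adjusted white estimate).
    """
    panel = panel or load_panel("grs19")
    raf_tbl = load_raf_table("white_controls")
    rafs = {r: float(raf_tbl.loc[r, "raf"]) for r in panel.rsids}
    return SimulationConfig(
        rafs=rafs,
        covariate_prevalences=dict(AFRO_CARIBBEAN_PREVALENCES),
        age_mean=57.0,
        age_sd=4.0,
        sex_male_prob=1.0,
        bmi_mean=26.5,
        bmi_sd=3.6,
        grs_effect_per_allele=calibrate_grs_effect(or_per_sd, rafs),
        n_cases=146,
        n_controls=1214,
        controls_per_case=8,
        missing_rate=missing_rate,
        population="white_nphsii",
        seed=seed,
    )
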