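"""Risk-score computation and case-control association analyses.

Builds per-individual genetic risk scores (unweighted allele counts or
beta-weighted sums), standardizes them per SD, fits covariate-adjusted
maximum-likelihood logistic models with Wald inference, and runs the
quintile, 2x2 and stratified-summary analyses used for case-control GRS
studies.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .io import GenotypeTable
from .panel import SnpPanel
from .simulate import Cohort, BINARY_TCRFS

logger = logging.getLogger(__name__)

__all__ = [
    "GrsVector",
    "LogisticFit",
    "QuintileResult",
    "compute_grs",
    "per_sd_standardize",
    "fit_logistic",
    "or_from_2x2",
    "quintile_analysis",
    "two_sample_t",
    "grs_by_tcrf_summary",
    "TCRF_MODEL_COLUMNS",
]

Z_95 = stats.norm.ppf(0.975)

# covariates of the adjusted CHD model
TCRF_MODEL_COLUMNS = ["age", "sex", *BINARY_TCRFS]


@dataclass(frozen=True)
class GrsVector:
    """Per-individual genetic risk score with its sample summary."""

    values: pd.Series
    panel_name: str
    weighted: bool

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def sd(self) -> float:
        # n-1 denominator
        return float(self.values.std(ddof=1))

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class LogisticFit:
    """Maximum-likelihood logistic fit with per-term Wald inference."""

    terms: pd.DataFrame  # coef, se, or, ci_low, ci_high, p per predictor
    log_likelihood: float
    converged: bool
    n: int

    def odds_ratio(self, term: str) -> tuple[float, float, float]:
        row = self.terms.loc[term]
        return float(row["or"]), float(row["ci_low"]), float(row["ci_high"])


@dataclass(frozen=True)
class QuintileResult:
    bin_edges: np.ndarray  # 4 interior cut points
    table: pd.DataFrame  # per-bin n_cases, n_controls, control_fraction, or, ci, p


def compute_grs(
    table: GenotypeTable | pd.DataFrame,
    panel: SnpPanel,
    weighted: bool = False,
    allow_missing: bool = False,
) -> GrsVector:
    """Sum risk-allele dosages across the panel, optionally beta-weighted.

    Unweighted: score = sum of dosages (an integer in [0, 2 * n_snps]).
    Weighted: score = sum of dosage * ln-OR weight.  Missing dosages are an
    error unless ``allow_missing`` (then individuals with any missing SNP
    get a NaN score).
    """
    df = table.dosages if isinstance(table, GenotypeTable) else table
    missing_cols = [r for r in panel.rsids if r not in df.columns]
    if missing_cols:
        raise ValueError(f"genotype table lacks panel SNP(s): {missing_cols}")
    df = df[panel.rsids]
    if df.isna().to_numpy().any() and not allow_missing:
        raise ValueError(
            "genotype table contains missing dosages; run "
            "complete_case_filter (or impute explicitly) before scoring"
        )
    if weighted:
        w = np.array([panel[r].weight for r in panel.rsids])
        values = df.mul(w, axis=1).sum(axis=1, skipna=False)
    else:
        values = df.sum(axis=1, skipna=False)
    return GrsVector(values=values.rename("grs"), panel_name=panel.name, weighted=weighted)


def per_sd_standardize(
    grs: GrsVector,
    sd_source: str = "sample",
    controls: pd.Series | np.ndarray | None = None,
    external_sd: float | None = None,
    center: bool = False,
) -> pd.Series:
    """Divide scores by a standard deviation so model ORs read per-SD.

    ``sd_source`` is one of ``sample`` (SD of the whole analysis sample,
    the default), ``controls`` (SD among controls; pass the control mask),
    or ``external`` (pass ``external_sd``).  Centering is optional - the
    per-SD OR is location-invariant.
    """
    if sd_source == "sample":
        sd = grs.sd
    elif sd_source == "controls":
        if controls is None:
            raise ValueError("sd_source='controls' requires the control mask")
        sd = float(grs.values[np.asarray(controls, dtype=bool)].std(ddof=1))
    elif sd_source == "external":
        if external_sd is None:
            raise ValueError("sd_source='external' requires external_sd")
        sd = float(external_sd)
    else:
        raise ValueError(f"unknown sd_source {sd_source!r}")
    if not sd > 0:
        raise ValueError(f"standard deviation must be positive, got {sd}")
    out = grs.values / sd
    if center:
        out = out - out.mean()
    return out


def fit_logistic(outcome: pd.Series | np.ndarray, predictors: pd.DataFrame) -> LogisticFit:
    """Maximum-likelihood logistic regression with Wald 95% CIs.

    An intercept is added automatically.  Raises on complete separation
    (naming the separating predictor when one predictor alone separates)
    and on rank-deficient design matrices (naming collinear columns).
    """
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("need at least one case and one control")
    X = predictors.astype(float)
    if X.isna().to_numpy().any():
        raise ValueError("predictors contain missing values")
    rank = np.linalg.matrix_rank(X.to_numpy()) if X.shape[1] else 0
    if rank < X.shape[1]:
        corr = X.corr().abs()
        np.fill_diagonal(corr.values, 0)
        pairs = [
            (a, b)
            for a in corr.index
            for b in corr.columns
            if a < b and corr.loc[a, b] > 1 - 1e-8
        ]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {pairs or list(X.columns)}")
    for col in X.columns:
        x = X[col].to_numpy()
        if x.std() == 0:
            raise ValueError(f"predictor {col!r} is constant")
        if x[y == 1].min() > x[y == 0].max() or x[y == 1].max() < x[y == 0].min():
            raise ValueError(f"complete separation on predictor {col!r}")
    Xc = (sm.add_constant(X, has_constant="add") if X.shape[1]
          else pd.DataFrame({"const": np.ones(len(y))}, index=X.index))
    try:
        res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
    except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError) as exc:
        raise ValueError(f"logistic fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise ValueError("logistic fit did not converge")
    coefs = res.params
    ses = res.bse
    terms = pd.DataFrame(
        {
            "coef": coefs,
            "se": ses,
            "or": np.exp(coefs),
            "ci_low": np.exp(coefs - Z_95 * ses),
            "ci_high": np.exp(coefs + Z_95 * ses),
            "p": 2 * stats.norm.sf(np.abs(coefs / ses)),
        }
    )
    terms.index = ["intercept", *X.columns]
    return LogisticFit(
        terms=terms,
        log_likelihood=float(res.llf),
        converged=True,
        n=len(y),
    )


def or_from_2x2(
    table: Sequence[float], haldane: bool = False
) -> tuple[float, float, float]:
    """Odds ratio and Woolf 95% CI from a 2x2 table (a, b, c, d).

    Layout: a = exposed cases, b = exposed controls, c = unexposed cases,
    d = unexposed controls; OR = ad/bc.  A zero cell raises unless
    ``haldane`` adds 0.5 to every cell.
    """
    a, b, c, d = (float(x) for x in table)
    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be non-negative")
    if min(a, b, c, d) == 0:
        if not haldane:
            raise ValueError(
                "zero cell in 2x2 table; pass haldane=True to apply the "
                "Haldane-Anscombe 0.5 correction"
            )
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return or_, or_ * math.exp(-Z_95 * se), or_ * math.exp(Z_95 * se)


def _quintile_bins(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    edges = np.quantile(values, [0.2, 0.4, 0.6, 0.8])
    # ties on a cut point fall in the lower bin
    bins = np.searchsorted(edges, values, side="left")
    return edges, bins


def quintile_analysis(
    grs: GrsVector,
    outcome: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> QuintileResult:
    """Quintile-of-score ORs vs the bottom quintile, covariate adjusted.

    Cut points are the 20/40/60/80 percentiles of the whole analysis sample
    (cases + controls); integer scores tie heavily, and ties on a cut point
    go to the lower bin.  Q1 is the reference (OR = 1 by construction); the
    control share of each bin is reported alongside.
    """
    if len(grs) < 5:
        raise ValueError("need at least 5 individuals for quintiles")
    values = grs.values.to_numpy(dtype=float)
    y = np.asarray(outcome, dtype=float)
    edges, bins = _quintile_bins(values)
    occupied = np.unique(bins)
    if len(occupied) < 5:
        raise ValueError(
            f"ties collapsed quintile bins (only {len(occupied)} non-empty); "
            "use fewer bins for this score distribution"
        )
    dummies = pd.get_dummies(pd.Categorical(bins, categories=range(5)), prefix="q").astype(float)
    dummies = dummies.drop(columns="q_0")  # Q1 reference
    dummies.index = grs.values.index
    X = dummies
    if covariates is not None:
        X = pd.concat([dummies, covariates.astype(float)], axis=1)
    fit = fit_logistic(outcome, X)
    n_controls_total = float((y == 0).sum())
    rows = []
    for q in range(5):
        in_bin = bins == q
        n_cases = int(y[in_bin].sum())
        n_ctrl = int((1 - y[in_bin]).sum())
        if q == 0:
            or_, lo, hi, p = 1.0, np.nan, np.nan, np.nan
        else:
            row = fit.terms.loc[f"q_{q}"]
            or_, lo, hi, p = row["or"], row["ci_low"], row["ci_high"], row["p"]
        rows.append(
            {
                "quintile": q + 1,
                "n_cases": n_cases,
                "n_controls": n_ctrl,
                "control_fraction": n_ctrl / n_controls_total,
                "or": or_,
                "ci_low": lo,
                "ci_high": hi,
                "p": p,
            }
        )
    return QuintileResult(bin_edges=edges, table=pd.DataFrame(rows).set_index("quintile"))


def two_sample_t(
    a: Sequence[float] | tuple[float, float, int],
    b: Sequence[float] | tuple[float, float, int],
    from_stats: bool = False,
    welch: bool = False,
) -> tuple[float, float, float]:
    """Two-sample t test from raw vectors or (mean, sd, n) summaries.

    Student's pooled-variance t by default; Welch on request.  Returns
    (t, df, p).
    """
    if from_stats:
        (m1, s1, n1), (m2, s2, n2) = a, b
        if n1 < 2 or n2 < 2:
            raise ValueError("need n >= 2 per group")
        res = stats.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=not welch)
        if welch:
            v1, v2 = s1**2 / n1, s2**2 / n2
            df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
        else:
            df = n1 + n2 - 2
    else:
        x, yv = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
        if len(x) < 2 or len(yv) < 2:
            raise ValueError("need n >= 2 per group")
        if not welch and np.concatenate([x, yv]).std(ddof=1) == 0:
            raise ValueError("zero pooled variance")
        res = stats.ttest_ind(x, yv, equal_var=not welch)
        df = len(x) + len(yv) - 2 if not welch else float(res.df)
    if np.isnan(res.statistic):
        raise ValueError("zero pooled variance")
    return float(res.statistic), float(df), float(res.pvalue)


def grs_by_tcrf_summary(grs: GrsVector, cohort: Cohort) -> pd.DataFrame:
    """Mean score by risk-factor presence, separately in cases and controls.

    For every TCRF x presence/absence x CHD-status stratum, reports n,
    mean, SD and the t-test P for present vs absent within CHD stratum.
    Degenerate strata (n < 2) get NaN summaries and P, never an exception.
    """
    rows = []
    y = cohort.outcome.to_numpy(dtype=int)
    for tcrf in BINARY_TCRFS:
        flag = cohort.covariates[tcrf].to_numpy(dtype=float)
        for status, status_name in ((1, "chd"), (0, "control")):
            in_status = y == status
            groups = {}
            for present in (1, 0):
                vals = grs.values.to_numpy()[in_status & (flag == present)]
                groups[present] = vals
                rows.append(
                    {
                        "tcrf": tcrf,
                        "group": status_name,
                        "present": present,
                        "n": len(vals),
                        "mean": float(np.mean(vals)) if len(vals) else np.nan,
                        "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan,
                    }
                )
            if len(groups[1]) > 1 and len(groups[0]) > 1:
                _, _, p = two_sample_t(groups[1], groups[0])
            else:
                logger.warning(
                    "stratum too small for t test: %s/%s", tcrf, status_name
                )
                p = np.nan
            rows[-1]["p_present_vs_absent"] = p
            rows[-2]["p_present_vs_absent"] = p
    return pd.DataFrame(rows)
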