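"""ROC discrimination and cross-population expected-risk projection.

The AUC is the Mann-Whitney estimator (probability a random case outscores
a random control, ties half-credited); its standard error and the paired
two-model comparison use the DeLong structural-components method.  The
projection converts a between-population difference in mean genetic score
into an expected relative risk reduction, by closed-form odds scaling and
by a standardization (counterfactual-shift) average, reported side by side
because the two answers differ when baseline risk is not small.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from numpy.polynomial.hermite_e import hermegauss
from scipy import stats
from scipy.special import expit, logit

from .association import LogisticFit

logger = logging.getLogger(__name__)

__all__ = [
    "RocResult",
    "ProjectionResult",
    "roc_auc",
    "compare_auc",
    "compare_auc_bootstrap",
    "project_risk_reduction",
]


@dataclass(frozen=True)
class RocResult:
    auc: float
    se: float
    model_label: str = ""
    n_cases: int = 0
    n_controls: int = 0


@dataclass(frozen=True)
class ProjectionResult:
    delta_grs: float
    method: str
    relative_risk_reduction: float
    inputs_record: dict


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(scores: np.ndarray, outcome: np.ndarray):
    """Per-case and per-control placement values (DeLong V10, V01)."""
    cases = scores[outcome == 1]
    controls = scores[outcome == 0]
    m, n = len(cases), len(controls)
    if m == 0 or n == 0:
        raise ValueError("need at least one case and one control")
    all_ranks = _midrank(np.concatenate([cases, controls]))
    case_ranks = _midrank(cases)
    control_ranks = _midrank(controls)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (all_ranks[:m] - case_ranks) / n  # per-case placements
    v01 = 1.0 - (all_ranks[m:] - control_ranks) / m  # per-control placements
    return auc, v10, v01


def roc_auc(
    scores: np.ndarray | pd.Series,
    outcome: np.ndarray | pd.Series,
    label: str = "",
) -> RocResult:
    """Mann-Whitney AUC with DeLong standard error.

    ``scores`` may be fitted probabilities or any monotone risk score; the
    AUC is rank-based so either gives the same answer.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    auc, v10, v01 = _delong_components(s, y)
    var = 0.0
    if len(v10) > 1:
        var += np.var(v10, ddof=1) / len(v10)
    if len(v01) > 1:
        var += np.var(v01, ddof=1) / len(v01)
    return RocResult(
        auc=float(auc),
        se=float(math.sqrt(var)),
        model_label=label,
        n_cases=int(y.sum()),
        n_controls=int((1 - y).sum()),
    )


def compare_auc(
    scores_a: np.ndarray | pd.Series,
    scores_b: np.ndarray | pd.Series,
    outcome: np.ndarray | pd.Series,
) -> dict:
    """Paired DeLong test for the AUC difference of two models.

    Both score vectors must be over the same individuals.  Returns the two
    AUCs, their difference, the z statistic, and the two-sided P.  Identical
    score vectors give P = 1 with a zero-variance note.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if a.shape != b.shape or a.shape != y.shape:
        raise ValueError("both models must score the same individuals")
    auc_a, v10_a, v01_a = _delong_components(a, y)
    auc_b, v10_b, v01_b = _delong_components(b, y)
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    delta = auc_a - auc_b
    if var_diff <= 0:
        note = "zero variance of the AUC difference (identical or tied scores)"
        logger.info(note)
        return {
            "auc_a": float(auc_a), "auc_b": float(auc_b), "delta": float(delta),
            "z": 0.0, "p": 1.0, "note": note,
        }
    z = delta / math.sqrt(var_diff)
    return {
        "auc_a": float(auc_a), "auc_b": float(auc_b), "delta": float(delta),
        "z": float(z), "p": float(2 * stats.norm.sf(abs(z))),
    }


def compare_auc_bootstrap(
    scores_a: np.ndarray,
    scores_b: np.ndarray,
    outcome: np.ndarray,
    n_boot: int = 2000,
    seed: int = 0,
) -> dict:
    """Paired-bootstrap AUC comparison (cross-check for the DeLong test).

    Resamples individuals with replacement, stratified by outcome, and
    reports the bootstrap two-sided P for a zero AUC difference.
    """
    rng = np.random.default_rng(seed)
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = np.asarray(outcome, dtype=float)
    case_idx = np.flatnonzero(y == 1)
    ctrl_idx = np.flatnonzero(y == 0)
    obs = roc_auc(a, y).auc - roc_auc(b, y).auc
    deltas = np.empty(n_boot)
    for i in range(n_boot):
        idx = np.concatenate(
            [rng.choice(case_idx, len(case_idx)), rng.choice(ctrl_idx, len(ctrl_idx))]
        )
        deltas[i] = roc_auc(a[idx], y[idx]).auc - roc_auc(b[idx], y[idx]).auc
    se = deltas.std(ddof=1)
    if se == 0:
        return {"delta": float(obs), "p": 1.0, "se": 0.0}
    z = obs / se
    return {"delta": float(obs), "p": float(2 * stats.norm.sf(abs(z))), "se": float(se)}


def _standardized_reduction_from_fit(
    fit: LogisticFit,
    reference_X: pd.DataFrame,
    grs_column: str,
    delta: float,
) -> float:
    beta = fit.terms["coef"]
    X = reference_X.copy().astype(float)
    eta = beta["intercept"] + X.mul(beta.drop("intercept"), axis=1).sum(axis=1)
    eta_shift = eta - beta[grs_column] * delta
    p_obs = expit(eta).mean()
    p_shift = expit(eta_shift).mean()
    return float(1.0 - p_shift / p_obs)


def project_risk_reduction(
    grs_mean_a: float,
    grs_mean_b: float,
    or_per_sd: float | None = None,
    sd: float | None = None,
    fit: LogisticFit | None = None,
    reference_X: pd.DataFrame | None = None,
    grs_column: str = "grs",
    method: str = "both",
    baseline_risk: float = 0.10,
) -> list[ProjectionResult]:
    """Expected relative risk reduction for population a vs reference b.

    ``delta = grs_mean_b - grs_mean_a`` is the reference population's mean
    score excess.  Two methods:

    - ``odds-scaling``: 1 - exp(-beta_per_unit * delta), the closed-form
      odds reduction for a delta-unit lower score (beta_per_unit =
      ln(or_per_sd)/sd, or the fitted GRS coefficient).
    - ``standardization``: 1 - mean(p(score - delta)) / mean(p(score))
      averaged over the reference population.  With a fit and that
      population's design matrix the average is over its individuals;
      from summary inputs the score distribution is taken as
      Normal(mean_b, sd) with the stated ``baseline_risk`` at the mean
      (Gauss-Hermite quadrature, deterministic).

    Both are returned when ``method='both'`` (the default), with the inputs
    recorded in each result.
    """
    if fit is not None:
        if not fit.converged:
            raise ValueError("refusing to project from a non-converged fit")
        beta_unit = float(fit.terms.loc[grs_column, "coef"])
    else:
        if or_per_sd is None or sd is None:
            raise ValueError("need either a fit or (or_per_sd, sd)")
        if sd <= 0:
            raise ValueError("sd must be positive")
        beta_unit = math.log(or_per_sd) / sd
    delta = float(grs_mean_b - grs_mean_a)
    inputs = {
        "grs_mean_a": grs_mean_a,
        "grs_mean_b": grs_mean_b,
        "delta_grs": delta,
        "beta_per_unit": beta_unit,
        "or_per_sd": or_per_sd,
        "sd": sd,
        "from_fit": fit is not None,
        "baseline_risk": None if fit is not None else baseline_risk,
    }
    methods = ("odds-scaling", "standardization") if method == "both" else (method,)
    results = []
    for m in methods:
        if m == "odds-scaling":
            red = 1.0 - math.exp(-beta_unit * delta)
        elif m == "standardization":
            if fit is not None and reference_X is not None:
                red = _standardized_reduction_from_fit(fit, reference_X, grs_column, delta)
            else:
                if sd is None or sd <= 0:
                    raise ValueError("summary-based standardization needs sd > 0")
                nodes, wts = hermegauss(64)
                wts = wts / wts.sum()
                g_centered = nodes * sd
                eta = logit(baseline_risk) + beta_unit * g_centered
                p_obs = float((wts * expit(eta)).sum())
                p_shift = float((wts * expit(eta - beta_unit * delta)).sum())
                red = 1.0 - p_shift / p_obs
        else:
            raise ValueError(f"unknown method {m!r}")
        results.append(
            ProjectionResult(
                delta_grs=delta,
                method=m,
                relative_risk_reduction=float(red),
                inputs_record=dict(inputs),
            )
        )
    return results
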