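"""Random-effects meta-analysis of study-level proportions.

The model parameters are pooled from study-level records: inverse-variance
weighted means under a DerSimonian-Laird random-effects model on the raw
proportion scale (a logit-scale option guards against boundary
pathologies), Cochran's Q heterogeneity test, single-covariate
random-effects meta-regression with a method-of-moments between-study
variance, and the Welch t-tests used for group comparisons.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .params import Treatment, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "StudyRecord",
    "PooledEstimate",
    "MetaRegressionResult",
    "PRIOR_PROCEDURE_CUTOFF",
    "pool_proportion",
    "heterogeneity_test",
    "meta_regress",
    "welch_t_test",
    "load_study_records",
    "write_study_records",
    "apply_exclusions",
]

#: studies in which more than this fraction of cases had a previous pain
#: procedure are excluded at load, mirroring the corpus inclusion rule
PRIOR_PROCEDURE_CUTOFF = 0.35


@dataclass(frozen=True)
class StudyRecord:
    """One publication's contribution to one pooled outcome."""

    study_id: str
    treatment: Treatment
    outcome: str
    n: int
    events: int
    follow_up_months: float = float("nan")
    mean_age: float = float("nan")
    pct_female: float = float("nan")
    pct_prior_procedures: float = float("nan")

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValidationError(f"{self.study_id}: study size must be positive")
        if not (0 <= self.events <= self.n):
            raise ValidationError(
                f"{self.study_id}: events {self.events} outside [0, {self.n}]"
            )

    def proportion(self) -> tuple[float, float]:
        """(proportion, sampling variance) with 0.5 continuity correction at the
        boundary (0 or n events), so every study carries a positive variance."""
        e, n = self.events, self.n
        if e == 0 or e == n:
            p = (e + 0.5) / (n + 1.0)
        else:
            p = e / n
        var = p * (1.0 - p) / n
        return p, var


@dataclass(frozen=True)
class PooledEstimate:
    mean: float
    se: float
    tau2: float
    q: float
    p_het: float
    k: int

    @property
    def sd(self) -> float:
        """Alias: the pooled standard error, used as the dispersion of the
        pooled mean when it feeds a beta distribution downstream."""
        return self.se


@dataclass(frozen=True)
class MetaRegressionResult:
    intercept: float
    slope: float
    slope_se: float
    p_slope: float
    r2: float
    tau2: float
    k: int


def _check_records(records: Sequence[StudyRecord]) -> None:
    if len(records) == 0:
        raise ValidationError("no study records to pool")
    outcomes = {r.outcome for r in records}
    if len(outcomes) != 1:
        raise ValidationError(f"mixed outcome labels: {sorted(outcomes)}")


def _effects(records: Sequence[StudyRecord], scale: str) -> tuple[np.ndarray, np.ndarray]:
    props = np.array([r.proportion() for r in records])
    p, var = props[:, 0], props[:, 1]
    if scale == "proportion":
        return p, var
    if scale == "logit":
        # delta-method variance on the logit scale
        y = np.log(p / (1.0 - p))
        v = var / (p * (1.0 - p)) ** 2
        return y, v
    raise ValueError(f"unknown scale {scale!r}")


def _dl_tau2(y: np.ndarray, var: np.ndarray) -> tuple[float, float]:
    """DerSimonian-Laird between-study variance (truncated at 0) and Cochran Q."""
    w = 1.0 / var
    mean_fe = float(np.sum(w * y) / np.sum(w))
    q = float(np.sum(w * (y - mean_fe) ** 2))
    k = len(y)
    s1 = float(np.sum(w))
    s2 = float(np.sum(w**2))
    denom = s1 - s2 / s1
    tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
    return tau2, q


def pool_proportion(
    records: Sequence[StudyRecord], scale: str = "proportion"
) -> PooledEstimate:
    """Random-effects pooled proportion across studies of one outcome.

    Inverse-variance weighting with the DerSimonian-Laird method-of-moments
    between-study variance, on the raw proportion scale by default
    (``scale="logit"`` pools on the logit scale and back-transforms the
    mean).  A single study is returned as-is with ``tau2 = 0``.
    """
    _check_records(records)
    y, var = _effects(records, scale)
    k = len(records)
    if k == 1:
        mean, se = float(y[0]), float(math.sqrt(var[0]))
        if scale == "logit":
            mean = 1.0 / (1.0 + math.exp(-mean))
            se = se * mean * (1.0 - mean)
        return PooledEstimate(mean=mean, se=se, tau2=0.0, q=0.0, p_het=1.0, k=1)
    tau2, q = _dl_tau2(y, var)
    w_re = 1.0 / (var + tau2)
    mean = float(np.sum(w_re * y) / np.sum(w_re))
    se = float(math.sqrt(1.0 / np.sum(w_re)))
    p_het = float(stats.chi2.sf(q, k - 1))
    if scale == "logit":
        m = 1.0 / (1.0 + math.exp(-mean))
        se = se * m * (1.0 - m)
        mean = m
    return PooledEstimate(mean=mean, se=se, tau2=float(tau2), q=q, p_het=p_het, k=k)


def heterogeneity_test(records: Sequence[StudyRecord], scale: str = "proportion") -> tuple[float, float]:
    """Cochran's Q with fixed-effect weights; p-value from chi-square(k-1)."""
    _check_records(records)
    if len(records) < 2:
        raise ValidationError("heterogeneity test requires at least two studies")
    y, var = _effects(records, scale)
    _, q = _dl_tau2(y, var)
    p = float(stats.chi2.sf(q, len(records) - 1))
    return q, p


def _mom_tau2(y: np.ndarray, var: np.ndarray, X: np.ndarray) -> float:
    """Method-of-moments between-study variance for a weighted regression.

    Generalizes DerSimonian-Laird to a design matrix X: residual Q from the
    fixed-effect fit, centred at its degrees of freedom, scaled by
    tr(W) - tr[(X'WX)^-1 X'W^2 X]; truncated at zero.
    """
    k, p = X.shape
    w = 1.0 / var
    W = np.diag(w)
    xtwx = X.T @ W @ X
    beta = np.linalg.solve(xtwx, X.T @ (w * y))
    resid = y - X @ beta
    q_res = float(np.sum(w * resid**2))
    trace_term = float(np.trace(np.linalg.solve(xtwx, X.T @ np.diag(w**2) @ X)))
    denom = float(np.sum(w)) - trace_term
    if denom <= 0:
        return 0.0
    return max(0.0, (q_res - (k - p)) / denom)


def meta_regress(
    records: Sequence[StudyRecord],
    covariate: str | None,
    scale: str = "proportion",
) -> MetaRegressionResult:
    """Random-effects meta-regression of study proportions on one covariate.

    Weighted least squares with weights 1/(var + tau2), tau2 by method of
    moments; the slope is tested by normal approximation.  R-squared is the
    proportional reduction in between-study variance relative to the
    intercept-only model, truncated to [0, 1].  ``covariate=None`` fits the
    intercept-only model, which reproduces :func:`pool_proportion`.
    """
    _check_records(records)
    k = len(records)
    if covariate is not None and k < 3:
        raise ValidationError("meta-regression requires at least three studies")
    y, var = _effects(records, scale)
    if covariate is None:
        X = np.ones((k, 1))
    else:
        x = np.array([getattr(r, covariate) for r in records], dtype=float)
        if np.any(np.isnan(x)):
            raise ValidationError(f"covariate {covariate!r} missing on some records")
        if np.ptp(x) == 0.0:
            raise ValidationError(f"covariate {covariate!r} has zero variance")
        X = np.column_stack([np.ones(k), x])

    tau2_null = _dl_tau2(y, var)[0]
    tau2 = _mom_tau2(y, var, X) if X.shape[1] > 1 else tau2_null
    w = 1.0 / (var + tau2)
    xtwx = X.T @ np.diag(w) @ X
    beta = np.linalg.solve(xtwx, X.T @ (w * y))
    cov = np.linalg.inv(xtwx)

    if X.shape[1] == 1:
        intercept, slope = float(beta[0]), 0.0
        slope_se, p_slope, r2 = float("nan"), float("nan"), 0.0
    else:
        intercept, slope = float(beta[0]), float(beta[1])
        slope_se = float(math.sqrt(cov[1, 1]))
        z = slope / slope_se if slope_se > 0 else float("inf")
        p_slope = float(2.0 * stats.norm.sf(abs(z)))
        r2 = 0.0 if tau2_null <= 0 else min(1.0, max(0.0, (tau2_null - tau2) / tau2_null))
    return MetaRegressionResult(
        intercept=intercept, slope=slope, slope_se=slope_se,
        p_slope=p_slope, r2=r2, tau2=float(tau2), k=k,
    )


def welch_t_test(sample_a: Sequence[float], sample_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Welch (unequal-variance) t-test between two samples."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("welch_t_test needs at least two values per sample")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Study-record CSV I/O
# ---------------------------------------------------------------------------

STUDY_CSV_COLUMNS = [
    "study_id", "treatment", "outcome", "n", "events",
    "follow_up_months", "mean_age", "pct_female", "pct_prior",
]


def apply_exclusions(records: Iterable[StudyRecord]) -> list[StudyRecord]:
    """Drop studies whose prior-procedure fraction exceeds the corpus cutoff."""
    kept, dropped = [], 0
    for r in records:
        if not math.isnan(r.pct_prior_procedures) and r.pct_prior_procedures > PRIOR_PROCEDURE_CUTOFF:
            dropped += 1
        else:
            kept.append(r)
    if dropped:
        logger.info(
            "excluded %d study record(s) with > %.0f%% prior procedures",
            dropped, 100 * PRIOR_PROCEDURE_CUTOFF,
        )
    return kept


def load_study_records(path: str | Path, exclude_prior: bool = True) -> list[StudyRecord]:
    records: list[StudyRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for i, row in enumerate(reader, start=2):
            try:
                records.append(
                    StudyRecord(
                        study_id=row["study_id"],
                        treatment=Treatment(row["treatment"]),
                        outcome=row["outcome"],
                        n=int(row["n"]),
                        events=int(row["events"]),
                        follow_up_months=float(row.get("follow_up_months") or "nan"),
                        mean_age=float(row.get("mean_age") or "nan"),
                        pct_female=float(row.get("pct_female") or "nan"),
                        pct_prior_procedures=float(row.get("pct_prior") or "nan"),
                    )
                )
            except (KeyError, ValueError) as exc:
                raise ValidationError(f"{path}:{i}: {exc}") from exc
    return apply_exclusions(records) if exclude_prior else records


def write_study_records(records: Iterable[StudyRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(STUDY_CSV_COLUMNS)
        for r in records:
            writer.writerow([
                r.study_id, r.treatment.value, r.outcome, r.n, r.events,
                repr(r.follow_up_months), repr(r.mean_age),
                repr(r.pct_female), repr(r.pct_prior_procedures),
            ])
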