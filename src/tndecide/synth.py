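"""Synthetic study-level corpora emulating the published evidence base.

Generates study records with the statistical structure of the literature
the pooled parameters came from: binomial event counts around true outcome
rates, study sizes spanning the observed range, follow-up durations and
demographics drawn from the published per-arm summary distributions.  This
lets the meta-analytic layer and the end-to-end pipeline (corpus -> pooling
-> decision model -> PSA) be exercised with known ground truth.

Covariate effects enter on the logit scale against standardized covariates,
so generated rates stay inside [0, 1] while meta-regression recovery can be
tested at known effect sizes.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .meta import PooledEstimate, StudyRecord, pool_proportion
from .params import (
    BNI_ORDER,
    BniLevel,
    ProbabilityEstimate,
    Treatment,
    TreatmentParams,
    ValidationError,
    default_parameters,
)

__all__ = ["CorpusSpec", "OUTCOME_LABELS", "generate_corpus", "pool_corpus", "end_to_end_fixture"]

#: outcome labels a full corpus carries, in pooling order
OUTCOME_LABELS = (
    "BNI_I",
    "BNI_II",
    "BNI_III",
    "BNI_IV_V",
    "complication",
    "recurrence",
    "retreat",
)

_BNI_LABELS = {f"BNI_{lvl.value}": lvl for lvl in BNI_ORDER}


def _default_rates() -> dict[Treatment, dict[str, float]]:
    out: dict[Treatment, dict[str, float]] = {}
    for t in Treatment:
        p = default_parameters(t)
        out[t] = {
            **{f"BNI_{lvl.value}": p.bni_dist[lvl].mean for lvl in BNI_ORDER},
            "complication": p.complication_rate.mean,
            "recurrence": p.recurrence_rate_7y.mean,
            "retreat": p.retreat_fraction.mean,
        }
    return out


@dataclass(frozen=True)
class CorpusSpec:
    """Generating conditions for one synthetic corpus.

    Defaults emulate the published evidence base: 40 radiosurgery and 17
    decompression series (57 publications minus the handful reporting both
    arms), sizes between 15 and 500 cases, follow-up normal truncated at six
    months with the published per-arm means/SDs, and demographics from the
    pooled patient-characteristics table.  ``slopes`` adds logit-scale
    covariate effects (per standard deviation of the covariate) shared by
    all outcomes; the default is no effect.
    """

    n_studies: Mapping[Treatment, int] = field(
        default_factory=lambda: {Treatment.SRS: 40, Treatment.MVD: 17}
    )
    size_range: tuple[int, int] = (15, 500)
    true_rates: Mapping[Treatment, Mapping[str, float]] = field(default_factory=_default_rates)
    follow_up: Mapping[Treatment, tuple[float, float]] = field(
        default_factory=lambda: {Treatment.SRS: (31.7, 19.2), Treatment.MVD: (43.2, 27.6)}
    )
    follow_up_min_months: float = 6.0
    mean_age: Mapping[Treatment, tuple[float, float]] = field(
        default_factory=lambda: {Treatment.SRS: (67.6, 4.5), Treatment.MVD: (57.5, 3.3)}
    )
    pct_female: Mapping[Treatment, tuple[float, float]] = field(
        default_factory=lambda: {Treatment.SRS: (0.609, 0.080), Treatment.MVD: (0.627, 0.080)}
    )
    pct_prior: Mapping[Treatment, tuple[float, float]] = field(
        default_factory=lambda: {Treatment.SRS: (0.211, 0.104), Treatment.MVD: (0.149, 0.108)}
    )
    slopes: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.size_range
        if lo <= 0 or hi < lo:
            raise ValidationError(f"invalid size range {self.size_range}")
        if self.follow_up_min_months <= 0:
            raise ValidationError("follow-up truncation bound must be positive")
        for t, rates in self.true_rates.items():
            for name, r in rates.items():
                if not (0.0 <= r <= 1.0):
                    raise ValidationError(f"rate {name}={r} for {t} outside [0, 1]")


def _truncated_normal(mean: float, sd: float, lower: float, rng: np.random.Generator) -> float:
    if sd <= 0:
        return max(mean, lower)
    a = (lower - mean) / sd
    u = rng.uniform(stats.norm.cdf(a), 1.0)
    return float(mean + sd * stats.norm.ppf(u))


def _adjust_rate(rate: float, z_effect: float) -> float:
    """Shift a rate on the logit scale; boundary rates stay put."""
    if rate <= 0.0 or rate >= 1.0 or z_effect == 0.0:
        return min(1.0, max(0.0, rate))
    logit = math.log(rate / (1.0 - rate)) + z_effect
    return 1.0 / (1.0 + math.exp(-logit))


def generate_corpus(spec: CorpusSpec, rng: np.random.Generator | None = None) -> list[StudyRecord]:
    """Draw one corpus of study records, reproducibly from ``spec.seed``.

    Each study contributes one record per outcome label with shared size,
    follow-up and demographics; event counts are binomial around the true
    rate adjusted by any covariate slopes.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    records: list[StudyRecord] = []
    lo, hi = spec.size_range
    for treatment, k in spec.n_studies.items():
        treatment = Treatment(treatment)
        fu_mean, fu_sd = spec.follow_up[treatment]
        age_mean, age_sd = spec.mean_age[treatment]
        fem_mean, fem_sd = spec.pct_female[treatment]
        prior_mean, prior_sd = spec.pct_prior[treatment]
        for i in range(k):
            n = int(rng.integers(lo, hi + 1))
            follow_up = _truncated_normal(fu_mean, fu_sd, spec.follow_up_min_months, rng)
            age = float(rng.normal(age_mean, age_sd))
            pct_female = float(np.clip(rng.normal(fem_mean, fem_sd), 0.0, 1.0))
            pct_prior = float(np.clip(rng.normal(prior_mean, prior_sd), 0.0, 1.0))
            covariates = {
                "follow_up_months": (follow_up - fu_mean) / fu_sd if fu_sd > 0 else 0.0,
                "mean_age": (age - age_mean) / age_sd if age_sd > 0 else 0.0,
                "pct_female": (pct_female - fem_mean) / fem_sd if fem_sd > 0 else 0.0,
                "pct_prior_procedures": (pct_prior - prior_mean) / prior_sd if prior_sd > 0 else 0.0,
            }
            z_effect = sum(spec.slopes.get(name, 0.0) * z for name, z in covariates.items())
            study_id = f"{treatment.value.lower()}_{i:03d}"
            for outcome, rate in spec.true_rates[treatment].items():
                adj = _adjust_rate(rate, z_effect)
                events = int(rng.binomial(n, adj))
                records.append(
                    StudyRecord(
                        study_id=study_id,
                        treatment=treatment,
                        outcome=outcome,
                        n=n,
                        events=events,
                        follow_up_months=follow_up,
                        mean_age=age,
                        pct_female=pct_female,
                        pct_prior_procedures=pct_prior,
                    )
                )
    return records


def pool_corpus(
    records: Sequence[StudyRecord], treatment: Treatment
) -> dict[str, PooledEstimate]:
    """Pool every outcome label present for one arm of a corpus."""
    out: dict[str, PooledEstimate] = {}
    for outcome in OUTCOME_LABELS:
        subset = [r for r in records if r.treatment is treatment and r.outcome == outcome]
        if subset:
            out[outcome] = pool_proportion(subset)
    return out


def end_to_end_fixture(
    spec: CorpusSpec,
) -> tuple[list[StudyRecord], dict[Treatment, TreatmentParams]]:
    """Corpus plus the TreatmentParams pooled from it, ready for the model.

    Pooled means replace the packaged Table-derived probabilities (BNI
    distribution, complication rate, recurrence, re-treated fraction), with
    the pooled standard errors as their dispersions; utilities, the
    complication catalogue, the medication model and timing constants stay
    at the packaged defaults, which the corpus does not inform.
    """
    corpus = generate_corpus(spec)
    params_by: dict[Treatment, TreatmentParams] = {}
    for treatment in spec.n_studies:
        treatment = Treatment(treatment)
        pooled = pool_corpus(corpus, treatment)
        missing = [o for o in OUTCOME_LABELS if o not in pooled]
        if missing:
            raise ValidationError(f"{treatment.value}: corpus missing outcomes {missing}")
        base = default_parameters(treatment)
        bni = {
            lvl: ProbabilityEstimate(pooled[label].mean, pooled[label].se, label)
            for label, lvl in _BNI_LABELS.items()
        }
        params_by[treatment] = dataclasses.replace(
            base,
            bni_dist=bni,
            complication_rate=ProbabilityEstimate(
                pooled["complication"].mean, pooled["complication"].se, "complication"
            ),
            recurrence_rate_7y=ProbabilityEstimate(
                pooled["recurrence"].mean, pooled["recurrence"].se, "recurrence"
            ),
            retreat_fraction=ProbabilityEstimate(
                pooled["retreat"].mean, pooled["retreat"].se, "retreat"
            ),
        )
    return corpus, params_by
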