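"""The trigeminal-neuralgia treatment model.

Assembles the full chance tree for one strategy — primary procedure,
complications, BNI pain outcome, recurrence, and capped re-treatment — with
every terminal carrying a patient timeline whose payoff is its
quality-adjusted life years (QALYs) over the follow-up horizon.

Utility arithmetic follows the standard decision-analytic multiplication
rule: a patient's per-year utility is the product of the utilities of every
health state they carry simultaneously (BNI pain level, maintenance
medication if BNI III or IV-V, procedure complications, and a 0.915
multiplier per additional procedure).  QALYs are the time integral of that
utility over the horizon: perfect health for seven years is seven QALYs,
utility 0.25 for four years is one QALY.

Event timing differs between the arms.  After microvascular decompression
(MVD) the pain outcome is observed immediately, failures are re-treated at
one month and complications act from time zero.  After stereotactic
radiosurgery (SRS) the outcome is observed at one month on average (the
first month is spent in the pre-treatment state), failures are re-treated
at three months and complications act from six months.  Complications are
modelled as permanent from onset.  All pain recurrences happen at a fixed
time (default 2.5 years) after the procedure that relieved the pain;
untreated recurrences settle at BNI III on medication, re-treated ones
enter a fresh procedure subtree per the modality mix.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .params import (
    BNI_ORDER,
    BniLevel,
    ComplicationEntry,
    MedicationModel,
    ModelConfig,
    Treatment,
    TreatmentParams,
    ValidationError,
    default_parameters,
)
from .tree import Branch, ChanceNode, Node, TerminalNode, enumerate_paths, rollback

__all__ = [
    "HealthStateSegment",
    "PatientTimeline",
    "StateUtilityContext",
    "MONTHS_PER_YEAR",
    "complication_submodel",
    "medication_submodel",
    "state_utility",
    "timeline_qaly",
    "build_treatment_tree",
    "expected_qalys",
    "one_way_sensitivity",
    "set_parameter",
]

MONTHS_PER_YEAR = 12.0


@dataclass(frozen=True)
class HealthStateSegment:
    """A span of follow-up time spent at a constant utility."""

    start_years: float
    end_years: float
    utility: float
    label: str = ""

    @property
    def duration(self) -> float:
        return self.end_years - self.start_years


@dataclass(frozen=True)
class PatientTimeline:
    """Contiguous utility segments covering the whole follow-up horizon."""

    segments: tuple[HealthStateSegment, ...]
    events: Mapping[str, float] = field(default_factory=dict)


def timeline_qaly(timeline: PatientTimeline, tol: float = 1e-9) -> float:
    """Total QALYs of a timeline: sum of duration x utility per segment.

    Segments must partition the follow-up interval — contiguous, in order,
    without gaps or overlaps.
    """
    total = 0.0
    prev_end: float | None = None
    for seg in timeline.segments:
        if seg.duration < -tol:
            raise ValidationError(f"segment with negative duration: {seg}")
        if not (0.0 <= seg.utility <= 1.0):
            raise ValidationError(f"segment utility {seg.utility} outside [0, 1]")
        if prev_end is not None and abs(seg.start_years - prev_end) > tol:
            raise ValidationError(
                f"segments not contiguous: gap/overlap between {prev_end} and {seg.start_years}"
            )
        prev_end = seg.end_years
        total += seg.duration * seg.utility
    return total


@dataclass(frozen=True)
class StateUtilityContext:
    """Everything that multiplies into one health state's per-year utility."""

    bni: BniLevel
    complication_multiplier: float = 1.0
    medicated: bool | None = None  # None: derived from the BNI level
    retreat_depth: int = 0

    def is_medicated(self) -> bool:
        return self.bni.medicated if self.medicated is None else self.medicated


def medication_submodel(model: MedicationModel, pinned: float | None = None) -> float:
    """Expected utility of requiring maintenance medication.

    The probability-weighted mean of the three side-effect severity
    categories, after renormalizing their probabilities.  ``pinned``
    substitutes a fixed constant (the published sub-tree value) for the
    computed mean.
    """
    if pinned is not None:
        return pinned
    norm = model.renormalized()
    return math.fsum(c.probability.mean * c.utility.mean for c in norm.categories)


def complication_submodel(
    entries: Sequence[ComplicationEntry],
) -> tuple[float, float]:
    """Total complication rate and the expected utility conditional on one.

    Individual complication incidences add.  Each entry's effective utility
    is the product of its own utility and the utilities of any entries named
    in ``compound_with`` (corneal keratitis compounds with facial numbness
    and facial palsy).  Conditional utility is the incidence-weighted mean
    over entries, i.e. the rollback value of the complication sub-tree.
    """
    if not entries:
        return 0.0, 1.0
    total = math.fsum(e.incidence.mean for e in entries)
    if total > 1.0 + 1e-9:
        raise ValidationError(f"complication incidences sum to {total:.6g} > 1")
    if total == 0.0:
        return 0.0, 1.0
    by_name = {e.name: e for e in entries}
    weighted = 0.0
    for e in entries:
        u = e.utility.mean
        for other in e.compound_with:
            if other not in by_name:
                raise ValidationError(
                    f"complication {e.name!r} compounds with unknown entry {other!r}"
                )
            u *= by_name[other].utility.mean
        weighted += e.incidence.mean * u
    return total, weighted / total


def state_utility(
    ctx: StateUtilityContext, params: TreatmentParams, config: ModelConfig
) -> float:
    """Per-year utility of a health state: product of all coexisting factors."""
    u = params.bni_utilities[ctx.bni].mean
    if ctx.is_medicated():
        u *= medication_submodel(params.medication, config.pinned_medication_utility)
    u *= ctx.complication_multiplier
    u *= config.retreat_utility_multiplier**ctx.retreat_depth
    return u


# ---------------------------------------------------------------------------
# Tree assembly
# ---------------------------------------------------------------------------


def _resolve_params_by_treatment(
    params: TreatmentParams,
    params_by_treatment: Mapping[Treatment, TreatmentParams] | None,
) -> dict[Treatment, TreatmentParams]:
    by = {params.treatment: params}
    if params_by_treatment:
        for t, p in params_by_treatment.items():
            by.setdefault(Treatment(t), p)
    for t in Treatment:
        if t not in by:
            by[t] = default_parameters(t)
    return by


class _TreeBuilder:
    """Recursive construction of the strategy tree for one primary procedure."""

    def __init__(
        self,
        params_by: Mapping[Treatment, TreatmentParams],
        config: ModelConfig,
    ) -> None:
        self.params_by = params_by
        self.config = config
        self.horizon = config.horizon_years

    def _seg(
        self,
        start: float,
        end: float,
        bni: BniLevel,
        comp_mult: float,
        depth: int,
        params: TreatmentParams,
        label: str,
    ) -> list[HealthStateSegment]:
        start = min(start, self.horizon)
        end = min(end, self.horizon)
        if end - start <= 1e-12:
            return []
        u = state_utility(
            StateUtilityContext(bni=bni, complication_multiplier=comp_mult, retreat_depth=depth),
            params,
            self.config,
        )
        return [HealthStateSegment(start, end, u, label)]

    def _outcome_segments(
        self,
        bni: BniLevel,
        start: float,
        end: float,
        comp_mult_in: float,
        comp_factor: float,
        t_onset: float,
        depth: int,
        params: TreatmentParams,
        label: str,
    ) -> list[HealthStateSegment]:
        """Segments in a post-procedure state, split where the current
        procedure's complication takes effect."""
        if comp_factor == 1.0 or end <= t_onset:
            return self._seg(start, end, bni, comp_mult_in, depth, params, label)
        if start >= t_onset:
            return self._seg(start, end, bni, comp_mult_in * comp_factor, depth, params, label)
        return self._seg(start, t_onset, bni, comp_mult_in, depth, params, label) + self._seg(
            t_onset, end, bni, comp_mult_in * comp_factor, depth, params, label
        )

    def procedure(
        self,
        modality: Treatment,
        t0: float,
        depth: int,
        comp_mult_in: float,
        prior: list[HealthStateSegment],
    ) -> Node:
        cfg = self.config
        P = self.params_by[modality]
        H = self.horizon
        t0 = min(t0, H)
        t_resp = min(t0 + P.response_delay_months / MONTHS_PER_YEAR, H)
        pre_level = cfg.post_recurrence_pre_treatment_level
        pre = prior + self._seg(
            t0, t_resp, pre_level, comp_mult_in, depth, P, f"pre-response {modality.value}"
        )
        rate = P.complication_rate.mean
        _, cond_utility = complication_submodel(P.complications)
        t_onset = t0 + P.complication_onset_months / MONTHS_PER_YEAR

        comp_branches = []
        for has_comp, p_comp, label in (
            (False, 1.0 - rate, "no_complication"),
            (True, rate, "complication"),
        ):
            factor = cond_utility if has_comp else 1.0
            child = self._bni_node(modality, t0, t_resp, depth, comp_mult_in, factor, t_onset, pre)
            comp_branches.append(Branch(probability=p_comp, child=child, label=label))
        return ChanceNode(branches=tuple(comp_branches), label=f"{modality.value} procedure")

    def _bni_node(
        self,
        modality: Treatment,
        t0: float,
        t_resp: float,
        depth: int,
        comp_mult_in: float,
        comp_factor: float,
        t_onset: float,
        pre: list[HealthStateSegment],
    ) -> Node:
        P = self.params_by[modality]
        probs = P.bni_probabilities()
        branches = []
        for level in BNI_ORDER:
            if level is BniLevel.IV_V:
                child = self._failure_branch(
                    modality, t0, t_resp, depth, comp_mult_in, comp_factor, t_onset, pre
                )
            else:
                child = self._relief_branch(
                    modality, level, t0, t_resp, depth, comp_mult_in, comp_factor, t_onset, pre
                )
            branches.append(
                Branch(probability=probs[level], child=child, label=f"BNI_{level.value}")
            )
        return ChanceNode(branches=tuple(branches), label="BNI outcome")

    # -- initial therapeutic failure (BNI IV-V at response assessment) -------

    def _failure_branch(
        self,
        modality: Treatment,
        t0: float,
        t_resp: float,
        depth: int,
        comp_mult_in: float,
        comp_factor: float,
        t_onset: float,
        pre: list[HealthStateSegment],
    ) -> Node:
        cfg = self.config
        P = self.params_by[modality]
        H = self.horizon
        persist = pre + self._outcome_segments(
            BniLevel.IV_V, t_resp, H, comp_mult_in, comp_factor, t_onset, depth, P, "persistent failure"
        )
        persist_node = self._terminal(persist, "persistent_IV_V")
        t_rt = min(t0 + P.retreat_delay_months / MONTHS_PER_YEAR, H)
        if depth >= cfg.max_additional_procedures or P.retreat_fraction.mean <= 0.0 or t_rt >= H:
            return persist_node
        wait = pre + self._outcome_segments(
            BniLevel.IV_V, t_resp, t_rt, comp_mult_in, comp_factor, t_onset, depth, P, "awaiting re-treatment"
        )
        comp_mult_child = comp_mult_in * comp_factor
        retreat_node = self._modality_mix_node(modality, t_rt, depth + 1, comp_mult_child, wait)
        rf = P.retreat_fraction.mean
        return ChanceNode(
            branches=(
                Branch(probability=rf, child=retreat_node, label="retreat"),
                Branch(probability=1.0 - rf, child=persist_node, label="no_retreat"),
            ),
            label="failure re-treatment",
        )

    # -- pain relief (BNI I-III), possible recurrence -------------------------

    def _relief_branch(
        self,
        modality: Treatment,
        level: BniLevel,
        t0: float,
        t_resp: float,
        depth: int,
        comp_mult_in: float,
        comp_factor: float,
        t_onset: float,
        pre: list[HealthStateSegment],
    ) -> Node:
        cfg = self.config
        P = self.params_by[modality]
        H = self.horizon
        t_rec = t0 + cfg.recurrence_time_years
        rr = P.recurrence_rate_7y.mean
        if t_rec >= H or rr <= 0.0:
            segs = pre + self._outcome_segments(
                level, t_resp, H, comp_mult_in, comp_factor, t_onset, depth, P, f"BNI {level.value}"
            )
            return self._terminal(segs, f"stable_{level.value}")

        stable = pre + self._outcome_segments(
            level, t_resp, H, comp_mult_in, comp_factor, t_onset, depth, P, f"BNI {level.value}"
        )
        stable_node = self._terminal(stable, f"stable_{level.value}")

        before = pre + self._outcome_segments(
            level, t_resp, t_rec, comp_mult_in, comp_factor, t_onset, depth, P, f"BNI {level.value}"
        )
        comp_mult_after = comp_mult_in * (comp_factor if t_rec >= t_onset else 1.0)
        untreated = before + self._seg(
            t_rec, H, cfg.post_recurrence_untreated_level, comp_mult_after, depth, P,
            "untreated recurrence",
        )
        untreated_node = self._terminal(untreated, "recurrence_untreated")

        rf = P.retreat_fraction.mean
        if depth >= cfg.max_additional_procedures or rf <= 0.0:
            rec_node: Node = untreated_node
        else:
            retreat_node = self._modality_mix_node(modality, t_rec, depth + 1, comp_mult_after, before)
            rec_node = ChanceNode(
                branches=(
                    Branch(probability=rf, child=retreat_node, label="retreat"),
                    Branch(probability=1.0 - rf, child=untreated_node, label="no_retreat"),
                ),
                label="recurrence re-treatment",
            )
        return ChanceNode(
            branches=(
                Branch(probability=1.0 - rr, child=stable_node, label="no_recurrence"),
                Branch(probability=rr, child=rec_node, label="recurrence"),
            ),
            label=f"recurrence after BNI {level.value}",
        )

    def _modality_mix_node(
        self,
        modality: Treatment,
        t_start: float,
        depth: int,
        comp_mult: float,
        prior: list[HealthStateSegment],
    ) -> Node:
        mix = [(m, w) for m, w in self.params_by[modality].retreat_modality_mix.items() if w > 0.0]
        children = [
            (w, self.procedure(m, t_start, depth, comp_mult, prior), f"retreat_{m.value}")
            for m, w in mix
        ]
        if len(children) == 1:
            return children[0][1]
        return ChanceNode(
            branches=tuple(Branch(probability=w, child=c, label=lbl) for w, c, lbl in children),
            label="re-treatment modality",
        )

    def _terminal(self, segments: list[HealthStateSegment], label: str) -> TerminalNode:
        timeline = PatientTimeline(segments=tuple(segments))
        return TerminalNode(payoff=timeline_qaly(timeline), label=label, meta=timeline)


def build_treatment_tree(
    treatment: Treatment | str,
    params: TreatmentParams,
    config: ModelConfig,
    params_by_treatment: Mapping[Treatment, TreatmentParams] | None = None,
) -> Node:
    """Assemble the full strategy tree for one primary procedure.

    ``params_by_treatment`` supplies parameter sets for re-treatment
    modalities other than the primary one (the modality mix can route MVD
    failures to SRS and vice versa); missing arms fall back to the packaged
    defaults.
    """
    treatment = Treatment(treatment)
    if params.treatment is not treatment:
        raise ValidationError(
            f"params are for {params.treatment.value}, tree requested for {treatment.value}"
        )
    by = _resolve_params_by_treatment(params, params_by_treatment)
    builder = _TreeBuilder(by, config)
    return builder.procedure(treatment, 0.0, 0, 1.0, [])


def expected_qalys(
    treatment: Treatment | str,
    params: TreatmentParams,
    config: ModelConfig,
    params_by_treatment: Mapping[Treatment, TreatmentParams] | None = None,
) -> float:
    """Deterministic expected QALYs: rollback of the assembled tree at the
    point (mean) parameter values."""
    root = build_treatment_tree(treatment, params, config, params_by_treatment)
    return rollback(root)


# ---------------------------------------------------------------------------
# One-way sensitivity analysis
# ---------------------------------------------------------------------------


def set_parameter(params: TreatmentParams, parameter_id: str, value: float) -> TreatmentParams:
    """Return a copy of ``params`` with one scalar mean replaced.

    ``parameter_id`` is a dotted address: ``complication_rate``,
    ``recurrence_rate_7y``, ``retreat_fraction``, ``bni_dist.<level>``,
    ``bni_utilities.<level>``, ``complication.<name>.incidence``,
    ``complication.<name>.utility``, ``medication.<category>.probability``
    or ``medication.<category>.utility``.
    """
    parts = parameter_id.split(".")
    head = parts[0]
    if head in ("complication_rate", "recurrence_rate_7y", "retreat_fraction") and len(parts) == 1:
        est = dataclasses.replace(getattr(params, head), mean=value)
        return dataclasses.replace(params, **{head: est})
    if head == "bni_dist" and len(parts) == 2:
        lvl = BniLevel(parts[1])
        dist = dict(params.bni_dist)
        dist[lvl] = dataclasses.replace(dist[lvl], mean=value)
        return dataclasses.replace(params, bni_dist=dist)
    if head == "bni_utilities" and len(parts) == 2:
        lvl = BniLevel(parts[1])
        utils = dict(params.bni_utilities)
        utils[lvl] = dataclasses.replace(utils[lvl], mean=value)
        return dataclasses.replace(params, bni_utilities=utils)
    if head == "complication" and len(parts) == 3 and parts[2] in ("incidence", "utility"):
        name, which = parts[1], parts[2]
        entries = []
        found = False
        for e in params.complications:
            if e.name == name:
                entries.append(
                    dataclasses.replace(e, **{which: dataclasses.replace(getattr(e, which), mean=value)})
                )
                found = True
            else:
                entries.append(e)
        if not found:
            raise ValidationError(f"unknown complication {name!r}")
        return dataclasses.replace(params, complications=tuple(entries))
    if head == "medication" and len(parts) == 3 and parts[2] in ("probability", "utility"):
        name, which = parts[1], parts[2]
        cats = []
        found = False
        for c in params.medication.categories:
            if c.name == name:
                cats.append(
                    dataclasses.replace(c, **{which: dataclasses.replace(getattr(c, which), mean=value)})
                )
                found = True
            else:
                cats.append(c)
        if not found:
            raise ValidationError(f"unknown medication category {name!r}")
        return dataclasses.replace(params, medication=MedicationModel(categories=tuple(cats)))
    raise ValidationError(f"unknown parameter_id {parameter_id!r}")


def one_way_sensitivity(
    treatment: Treatment | str,
    params: TreatmentParams,
    config: ModelConfig,
    parameter_id: str,
    values: Sequence[float],
    params_by_treatment: Mapping[Treatment, TreatmentParams] | None = None,
) -> list[tuple[float, float]]:
    """Expected QALYs at each value of one parameter, all else fixed.

    The baseline (unmodified) value is always included as the first entry.
    """
    baseline = _resolve_baseline(params, parameter_id)
    out = [(baseline, expected_qalys(treatment, params, config, params_by_treatment))]
    for v in values:
        varied = set_parameter(params, parameter_id, v)
        out.append((v, expected_qalys(treatment, varied, config, params_by_treatment)))
    return out


def _resolve_baseline(params: TreatmentParams, parameter_id: str) -> float:
    parts = parameter_id.split(".")
    head = parts[0]
    if head in ("complication_rate", "recurrence_rate_7y", "retreat_fraction"):
        return getattr(params, head).mean
    if head == "bni_dist":
        return params.bni_dist[BniLevel(parts[1])].mean
    if head == "bni_utilities":
        return params.bni_utilities[BniLevel(parts[1])].mean
    if head == "complication":
        for e in params.complications:
            if e.name == parts[1]:
                return getattr(e, parts[2]).mean
    if head == "medication":
        for c in params.medication.categories:
            if c.name == parts[1]:
                return getattr(c, parts[2]).mean
    raise ValidationError(f"unknown parameter_id {parameter_id!r}")
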