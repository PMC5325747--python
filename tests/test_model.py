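"""Treatment model: sub-models, state utilities, timelines, assembled tree."""

import dataclasses
import math

import numpy as np
import pytest

from tndecide.model import (
    HealthStateSegment,
    PatientTimeline,
    StateUtilityContext,
    build_treatment_tree,
    complication_submodel,
    expected_qalys,
    medication_submodel,
    one_way_sensitivity,
    set_parameter,
    state_utility,
    timeline_qaly,
)
from tndecide.params import (
    BNI_ORDER,
    BniLevel,
    ComplicationEntry,
    ModelConfig,
    ProbabilityEstimate,
    Treatment,
    UtilityEstimate,
    ValidationError,
    default_parameters,
)
from tndecide.tree import enumerate_paths, rollback


def comp_entry(name, inc, util, compound=()):
    return ComplicationEntry(
        name, ProbabilityEstimate(inc), UtilityEstimate(util), tuple(compound)
    )


def force_outcome(params, level=BniLevel.I):
    """Point-parameter set with certain outcome, no complications/recurrence."""
    dist = {lvl: ProbabilityEstimate(1.0 if lvl is level else 0.0) for lvl in BNI_ORDER}
    return dataclasses.replace(
        params,
        bni_dist=dist,
        complication_rate=ProbabilityEstimate(0.0),
        recurrence_rate_7y=ProbabilityEstimate(0.0),
    )


# -- complication sub-model --------------------------------------------------

def test_single_entry_passthrough():
    assert complication_submodel([comp_entry("x", 0.1, 0.9)]) == (
        pytest.approx(0.1), pytest.approx(0.9))


def test_empty_entries_are_benign():
    assert complication_submodel([]) == (0.0, 1.0)


def test_incidence_sum_over_one_rejected():
    with pytest.raises(ValidationError):
        complication_submodel([comp_entry("a", 0.6, 0.9), comp_entry("b", 0.5, 0.9)])


def test_unknown_compound_reference_rejected():
    with pytest.raises(ValidationError, match="ghost"):
        complication_submodel([comp_entry("a", 0.1, 0.9, compound=("ghost",))])


def test_compound_utility_multiplies():
    entries = [
        comp_entry("numb", 0.2, 0.9),
        comp_entry("palsy", 0.1, 0.8),
        comp_entry("keratitis", 0.1, 0.7, compound=("numb", "palsy")),
    ]
    total, cond = complication_submodel(entries)
    # hand-rolled expectation: keratitis carries 0.7*0.9*0.8
    expect = (0.2 * 0.9 + 0.1 * 0.8 + 0.1 * 0.7 * 0.9 * 0.8) / 0.4
    assert total == pytest.approx(0.4)
    assert cond == pytest.approx(expect, abs=1e-12)


def test_mvd_profile_totals_and_conditional(mvd_params):
    total, cond = complication_submodel(mvd_params.complications)
    assert total == pytest.approx(0.133, abs=1e-12)
    # direct weighted mean over the published incidence/utility pairs
    expect = (0.044 * 0.960 + 0.011 * 0.983 + 0.002 * 0.0 + 0.018 * 0.929
              + 0.013 * 0.985 + 0.012 * 0.930 + 0.033 * 1.0) / 0.133
    assert cond == pytest.approx(expect, abs=1e-12)


def test_srs_profile_totals_and_conditional(srs_params):
    total, cond = complication_submodel(srs_params.complications)
    assert total == pytest.approx(0.193, abs=1e-12)
    expect = (0.141 * 0.960 + 0.017 * 0.983
              + 0.015 * (0.963 * 0.960 * 0.983) + 0.020 * 1.0) / 0.193
    assert cond == pytest.approx(expect, abs=1e-12)
    assert cond == pytest.approx(0.962, abs=5e-4)


# -- medication sub-model ----------------------------------------------------

def test_medication_weighted_mean(mvd_params):
    value = medication_submodel(mvd_params.medication)
    expect = (0.176 * 0.940 + 0.514 * 0.912 + 0.311 * 0.774) / (0.176 + 0.514 + 0.311)
    assert value == pytest.approx(expect, abs=1e-12)


def test_medication_equal_utilities_collapse(mvd_params):
    cats = tuple(
        dataclasses.replace(c, utility=UtilityEstimate(0.85))
        for c in mvd_params.medication.categories
    )
    model = dataclasses.replace(mvd_params.medication, categories=cats)
    assert medication_submodel(model) == pytest.approx(0.85)


def test_medication_zero_probability_category_drops_out(mvd_params):
    cats = list(mvd_params.medication.categories)
    cats[2] = dataclasses.replace(cats[2], probability=ProbabilityEstimate(0.0))
    model = dataclasses.replace(mvd_params.medication, categories=tuple(cats))
    value = medication_submodel(model)
    expect = (0.176 * 0.940 + 0.514 * 0.912) / (0.176 + 0.514)
    assert value == pytest.approx(expect, abs=1e-12)


def test_medication_pinned_constant(mvd_params):
    assert medication_submodel(mvd_params.medication, pinned=0.881) == 0.881


# -- state utility (the multiplication rule) ---------------------------------

def test_state_utility_multiplies_published_factors(mvd_params):
    """BNI III with an MVD complication on medication: the product of the
    three published sub-tree utilities."""
    cfg = ModelConfig(pinned_medication_utility=0.881)
    ctx = StateUtilityContext(bni=BniLevel.III, complication_multiplier=0.958)
    u = state_utility(ctx, mvd_params, cfg)
    assert u == pytest.approx(0.958 * 0.739 * 0.881, abs=1e-12)
    assert u == pytest.approx(0.6237, abs=5e-4)


def test_state_utility_perfect_outcome(mvd_params, config):
    ctx = StateUtilityContext(bni=BniLevel.I)
    assert state_utility(ctx, mvd_params, config) == 1.0


def test_state_utility_retreat_multiplier_compounds(mvd_params, config):
    for depth in (1, 2):
        ctx = StateUtilityContext(bni=BniLevel.I, retreat_depth=depth)
        assert state_utility(ctx, mvd_params, config) == pytest.approx(0.915**depth)


# -- timelines ---------------------------------------------------------------

def test_quarter_utility_four_years_is_one_qaly():
    tl = PatientTimeline(segments=(HealthStateSegment(0.0, 4.0, 0.25),))
    assert timeline_qaly(tl) == pytest.approx(1.0)


def test_seven_perfect_years_is_seven_qalys():
    tl = PatientTimeline(segments=(HealthStateSegment(0.0, 7.0, 1.0),))
    assert timeline_qaly(tl) == pytest.approx(7.0)


def test_death_at_time_zero_accrues_nothing():
    tl = PatientTimeline(segments=(HealthStateSegment(0.0, 7.0, 0.0),))
    assert timeline_qaly(tl) == 0.0


def test_gapped_segments_rejected():
    tl = PatientTimeline(segments=(
        HealthStateSegment(0.0, 2.0, 1.0), HealthStateSegment(3.0, 7.0, 1.0)))
    with pytest.raises(ValidationError, match="contiguous"):
        timeline_qaly(tl)


# -- assembled tree ----------------------------------------------------------

@pytest.mark.parametrize("treatment", ["MVD", "SRS"])
def test_path_probabilities_conserved(treatment, config):
    params = default_parameters(treatment)
    root = build_treatment_tree(treatment, params, config)
    paths = enumerate_paths(root)
    assert paths.total_probability() == pytest.approx(1.0, abs=1e-9)
    assert abs(paths.expectation() - rollback(root)) < 1e-10


def test_certain_cure_attains_horizon(mvd_params, config):
    params = force_outcome(mvd_params, BniLevel.I)
    root = build_treatment_tree("MVD", params, config)
    paths = enumerate_paths(root)
    assert len(paths) == 1
    assert rollback(root) == pytest.approx(config.horizon_years)


def test_retreat_cap_zero_removes_retreat_branches(mvd_params):
    cfg = ModelConfig(max_additional_procedures=0)
    root = build_treatment_tree("MVD", mvd_params, cfg)
    for path in enumerate_paths(root):
        assert not any(lbl.startswith("retreat") for lbl in path.labels)


def test_one_year_horizon_disables_recurrence(srs_params):
    cfg = ModelConfig(horizon_years=1.0)
    root = build_treatment_tree("SRS", srs_params, cfg)
    for path in enumerate_paths(root):
        assert "recurrence" not in path.labels
    assert 0.0 <= rollback(root) <= 1.0


def test_closed_form_agreement_without_recurrence_or_retreat(mvd_params):
    """With recurrence off and the re-treatment cap at zero the tree reduces
    to horizon x state-utility mixture."""
    cfg = ModelConfig(max_additional_procedures=0)
    params = set_parameter(mvd_params, "recurrence_rate_7y", 0.0)
    probs = params.bni_probabilities()
    _, cond = complication_submodel(params.complications)
    rate = params.complication_rate.mean
    mix = sum(
        probs[lvl] * state_utility(StateUtilityContext(bni=lvl), params, cfg)
        for lvl in BNI_ORDER
    )
    closed_form = cfg.horizon_years * mix * (1.0 - rate * (1.0 - cond))
    assert expected_qalys("MVD", params, cfg) == pytest.approx(closed_form, abs=1e-9)


@pytest.mark.parametrize("treatment", ["MVD", "SRS"])
def test_expected_qalys_within_bounds(treatment, config):
    q = expected_qalys(treatment, default_parameters(treatment), config)
    assert 0.0 < q < config.horizon_years


def test_all_utilities_one_attains_horizon(mvd_params, config):
    utils = {lvl: UtilityEstimate(1.0) for lvl in BNI_ORDER}
    cats = tuple(
        dataclasses.replace(c, utility=UtilityEstimate(1.0))
        for c in mvd_params.medication.categories
    )
    comps = tuple(
        dataclasses.replace(c, utility=UtilityEstimate(1.0), compound_with=())
        for c in mvd_params.complications
    )
    params = dataclasses.replace(
        mvd_params, bni_utilities=utils, complications=comps,
        medication=dataclasses.replace(mvd_params.medication, categories=cats),
    )
    cfg = dataclasses.replace(config, retreat_utility_multiplier=1.0)
    # SRS re-treatment arm must also carry unit utilities
    srs = dataclasses.replace(params, treatment=Treatment.SRS)
    q = expected_qalys("MVD", params, cfg, params_by_treatment={Treatment.SRS: srs})
    assert q == pytest.approx(config.horizon_years, abs=1e-9)


def test_horizon_zero_gives_zero(mvd_params):
    cfg = ModelConfig(horizon_years=0.0)
    assert expected_qalys("MVD", mvd_params, cfg) == pytest.approx(0.0)


def test_mismatched_treatment_rejected(srs_params, config):
    with pytest.raises(ValidationError):
        build_treatment_tree("MVD", srs_params, config)


# -- sensitivity -------------------------------------------------------------

def test_sensitivity_baseline_first(mvd_params, config):
    rows = one_way_sensitivity("MVD", mvd_params, config, "complication_rate", [0.176])
    assert rows[0][0] == pytest.approx(0.176)
    assert rows[0][1] == pytest.approx(rows[1][1])


def test_qalys_decrease_with_complication_rate(mvd_params, config):
    values = [0.0, 0.1, 0.2, 0.4, 0.8]
    rows = one_way_sensitivity("MVD", mvd_params, config, "complication_rate", values)[1:]
    qalys = [q for _, q in rows]
    assert all(a > b for a, b in zip(qalys, qalys[1:]))


def test_qalys_monotone_in_bni_utility(mvd_params, config):
    values = [0.2, 0.5, 0.739, 0.9]
    rows = one_way_sensitivity("MVD", mvd_params, config, "bni_utilities.III", values)[1:]
    qalys = [q for _, q in rows]
    assert all(a <= b for a, b in zip(qalys, qalys[1:]))


def test_unknown_parameter_id_rejected(mvd_params, config):
    with pytest.raises(ValidationError):
        one_way_sensitivity("MVD", mvd_params, config, "nonsense", [0.1])
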