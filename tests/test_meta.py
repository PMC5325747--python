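"""Meta-analytic layer: pooling, heterogeneity, meta-regression, t-tests."""

import math

import numpy as np
import pytest
from statsmodels.stats.meta_analysis import combine_effects

from tndecide.meta import (
    StudyRecord,
    ValidationError,
    apply_exclusions,
    heterogeneity_test,
    load_study_records,
    meta_regress,
    pool_proportion,
    welch_t_test,
    write_study_records,
)
from tndecide.params import Treatment


def records_from(pairs, outcome="BNI_I", treatment=Treatment.MVD, **extra):
    return [
        StudyRecord(
            study_id=f"s{i}", treatment=treatment, outcome=outcome,
            n=n, events=e, **extra,
        )
        for i, (e, n) in enumerate(pairs)
    ]


# -- pooling -----------------------------------------------------------------

def test_identical_studies_pool_to_common_rate():
    est = pool_proportion(records_from([(20, 100)] * 5))
    assert est.mean == pytest.approx(0.200, abs=1e-12)
    assert est.tau2 == 0.0
    assert est.k == 5


def test_single_study_passthrough():
    est = pool_proportion(records_from([(30, 60)]))
    assert est.mean == pytest.approx(0.5)
    assert est.k == 1 and est.tau2 == 0.0


def test_empty_and_mixed_outcomes_rejected():
    with pytest.raises(ValidationError):
        pool_proportion([])
    recs = records_from([(10, 50)]) + records_from([(10, 50)], outcome="recurrence")
    with pytest.raises(ValidationError, match="mixed"):
        pool_proportion(recs)


def test_pooled_mean_within_study_range():
    rng = np.random.default_rng(5)
    for _ in range(25):
        k = int(rng.integers(2, 12))
        pairs = [(int(rng.integers(0, n + 1)), n) for n in rng.integers(20, 400, size=k)]
        recs = records_from(pairs)
        est = pool_proportion(recs)
        props = [r.proportion()[0] for r in recs]
        assert min(props) - 1e-12 <= est.mean <= max(props) + 1e-12


def test_equal_size_studies_pool_to_unweighted_mean_when_homogeneous():
    # equal n and similar rates: weights equalize, pooled -> arithmetic mean
    pairs = [(48, 200), (50, 200), (52, 200)]
    est = pool_proportion(records_from(pairs))
    props = [e / n for e, n in pairs]
    assert est.mean == pytest.approx(np.mean(props), abs=2e-4)


def test_agrees_with_statsmodels_dl_when_tau2_positive():
    """Independent cross-check against statsmodels' DerSimonian-Laird pooling."""
    pairs = [(20, 100), (45, 120), (10, 80), (70, 150), (30, 90)]
    recs = records_from(pairs)
    est = pool_proportion(recs)
    eff = np.array([r.proportion()[0] for r in recs])
    var = np.array([r.proportion()[1] for r in recs])
    res = combine_effects(eff, var, method_re="dl")
    assert res.tau2 > 0  # in this regime statsmodels' untruncated tau2 matches ours
    assert est.tau2 == pytest.approx(float(res.tau2), rel=1e-9)
    assert est.mean == pytest.approx(float(res.mean_effect_re), rel=1e-9)
    assert est.se == pytest.approx(float(res.sd_eff_w_re), rel=1e-9)


def test_boundary_counts_get_continuity_correction():
    est = pool_proportion(records_from([(0, 50), (0, 80)]))
    assert 0.0 < est.mean < 0.02
    assert math.isfinite(est.se) and est.se > 0


def test_logit_scale_option_stays_close_on_interior_rates():
    recs = records_from([(40, 100), (50, 120), (45, 110)])
    raw = pool_proportion(recs, scale="proportion")
    logit = pool_proportion(recs, scale="logit")
    assert logit.mean == pytest.approx(raw.mean, abs=0.02)


# -- heterogeneity -----------------------------------------------------------

def test_identical_studies_show_no_heterogeneity():
    q, p = heterogeneity_test(records_from([(20, 100)] * 4))
    assert q == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_extreme_contrast_is_heterogeneous():
    q, p = heterogeneity_test(records_from([(5, 100), (95, 100)]))
    assert p < 0.001


def test_q_invariant_to_study_order():
    recs = records_from([(5, 100), (40, 90), (70, 150)])
    q1, _ = heterogeneity_test(recs)
    q2, _ = heterogeneity_test(list(reversed(recs)))
    assert q1 == pytest.approx(q2, rel=1e-12)


def test_heterogeneity_needs_two_studies():
    with pytest.raises(ValidationError):
        heterogeneity_test(records_from([(10, 50)]))


# -- meta-regression ---------------------------------------------------------

def test_constant_only_model_reproduces_pooled_mean():
    recs = records_from([(20, 100), (45, 120), (10, 80), (70, 150)])
    pooled = pool_proportion(recs)
    reg = meta_regress(recs, covariate=None)
    assert reg.intercept == pytest.approx(pooled.mean, rel=1e-9)
    assert reg.tau2 == pytest.approx(pooled.tau2, rel=1e-9)


def test_degenerate_covariate_rejected():
    recs = records_from([(20, 100)] * 4, follow_up_months=24.0)
    with pytest.raises(ValidationError, match="zero variance"):
        meta_regress(recs, covariate="follow_up_months")


def test_null_slope_recovery_unbiased():
    """With no true covariate effect the slope estimate is centred on zero."""
    rng = np.random.default_rng(42)
    slopes = []
    for _ in range(200):
        recs = []
        for i in range(15):
            n = 200
            fu = float(rng.uniform(12, 72))
            e = int(rng.binomial(n, 0.3))
            recs.append(StudyRecord(f"s{i}", Treatment.MVD, "recurrence", n, e,
                                    follow_up_months=fu))
        slopes.append(meta_regress(recs, "follow_up_months").slope)
    mean_slope = np.mean(slopes)
    se = np.std(slopes, ddof=1) / math.sqrt(len(slopes))
    assert abs(mean_slope) < 3 * se


def test_positive_slope_sign_recovered():
    """A real follow-up effect is detected with the right sign almost always."""
    rng = np.random.default_rng(7)
    hits = 0
    n_rep = 200
    for _ in range(n_rep):
        recs = []
        for i in range(20):
            n = 200
            fu = float(rng.uniform(12, 72))
            z = (fu - 42.0) / 17.0
            rate = 1.0 / (1.0 + math.exp(-(math.log(0.3 / 0.7) + 1.0 * z)))
            e = int(rng.binomial(n, rate))
            recs.append(StudyRecord(f"s{i}", Treatment.MVD, "recurrence", n, e,
                                    follow_up_months=fu))
        if meta_regress(recs, "follow_up_months").slope > 0:
            hits += 1
    assert hits / n_rep >= 0.95


def test_r2_bounded():
    rng = np.random.default_rng(3)
    for _ in range(20):
        recs = []
        for i in range(10):
            n = int(rng.integers(50, 300))
            fu = float(rng.uniform(6, 90))
            e = int(rng.binomial(n, rng.uniform(0.1, 0.6)))
            recs.append(StudyRecord(f"s{i}", Treatment.SRS, "recurrence", n, e,
                                    follow_up_months=fu))
        r2 = meta_regress(recs, "follow_up_months").r2
        assert 0.0 <= r2 <= 1.0


# -- Welch t-test ------------------------------------------------------------

def test_welch_identical_samples():
    a = [1.0, 2.0, 3.0, 4.0]
    t, p = welch_t_test(a, a)
    assert t == pytest.approx(0.0)
    assert p == pytest.approx(1.0)


def test_welch_antisymmetric():
    a = [1.0, 2.0, 3.0]
    b = [4.0, 5.0, 7.0]
    t1, p1 = welch_t_test(a, b)
    t2, p2 = welch_t_test(b, a)
    assert t1 == pytest.approx(-t2)
    assert p1 == pytest.approx(p2)


def test_welch_separated_samples_significant(rng):
    a = rng.normal(0.0, 1.0, size=100)
    b = rng.normal(5.0, 1.0, size=100)
    _, p = welch_t_test(a, b)
    assert p < 0.001


def test_welch_requires_two_values():
    with pytest.raises(ValidationError):
        welch_t_test([1.0], [1.0, 2.0])


# -- record I/O and exclusions ----------------------------------------------

def test_prior_procedure_exclusion_rule():
    keep = StudyRecord("a", Treatment.MVD, "BNI_I", 100, 50, pct_prior_procedures=0.2)
    drop = StudyRecord("b", Treatment.MVD, "BNI_I", 100, 50, pct_prior_procedures=0.5)
    nan = StudyRecord("c", Treatment.MVD, "BNI_I", 100, 50)
    kept = apply_exclusions([keep, drop, nan])
    assert [r.study_id for r in kept] == ["a", "c"]


def test_study_record_invariants():
    with pytest.raises(ValidationError):
        StudyRecord("x", Treatment.MVD, "BNI_I", 0, 0)
    with pytest.raises(ValidationError):
        StudyRecord("x", Treatment.MVD, "BNI_I", 50, 60)


def test_study_csv_roundtrip(tmp_path):
    recs = records_from([(20, 100), (0, 50)], follow_up_months=30.0,
                        mean_age=60.0, pct_female=0.6, pct_prior_procedures=0.1)
    path = tmp_path / "corpus.csv"
    write_study_records(recs, path)
    loaded = load_study_records(path)
    assert loaded == recs
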