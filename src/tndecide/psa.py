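"""Probabilistic sensitivity analysis by two-dimensional Monte Carlo.

Every probability and utility in the model carries a (mean, sd) pair, to
which a beta distribution is fitted by the method of moments.  The outer
loop of the simulation draws one parameter set per simulated trial; the
inner loop runs patient-level microsimulations through the assembled tree
for that trial.  Trial means are compared across the two strategies with a
Welch t-test.  A single master seed drives everything through
deterministically spawned substreams, so results are bitwise reproducible.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass

import numpy as np

from .meta import welch_t_test
from .model import build_treatment_tree
from .params import (
    BNI_ORDER,
    MedicationModel,
    ModelConfig,
    ProbabilityEstimate,
    Treatment,
    TreatmentParams,
    UtilityEstimate,
    ValidationError,
)
from .tree import ChanceNode, Node, TerminalNode, _norm_probs

__all__ = [
    "BetaSpec",
    "PsaResult",
    "PsaComparison",
    "fit_beta",
    "draw_parameter_set",
    "sample_path",
    "simulate_patient",
    "run_two_level_psa",
]


@dataclass(frozen=True)
class BetaSpec:
    """Beta distribution matched by moments to a (mean, sd) pair.

    ``degenerate`` marks a point mass (sd = 0 or a boundary mean), in which
    case ``alpha``/``beta`` are unused and draws return the mean exactly.
    """

    mean: float
    sd: float
    alpha: float = 0.0
    beta: float = 0.0
    degenerate: bool = False

    def sample(self, rng: np.random.Generator) -> float:
        if self.degenerate:
            return self.mean
        return float(rng.beta(self.alpha, self.beta))


def fit_beta(mean: float, sd: float, on_infeasible: str = "clip") -> BetaSpec:
    """Method-of-moments beta fit: nu = mean(1-mean)/sd^2 - 1.

    When sd^2 >= mean(1-mean) no beta distribution matches the moments; the
    sd is clipped to 95% of the feasible bound with a warning
    (``on_infeasible="error"`` raises instead).  sd = 0 or a boundary mean
    yields a degenerate point mass.
    """
    if not (0.0 <= mean <= 1.0):
        raise ValidationError(f"beta mean {mean!r} outside [0, 1]")
    if sd < 0.0:
        raise ValidationError(f"negative sd {sd!r}")
    if sd == 0.0 or mean in (0.0, 1.0):
        return BetaSpec(mean=mean, sd=0.0, degenerate=True)
    bound = mean * (1.0 - mean)
    if sd**2 >= bound:
        if on_infeasible == "error":
            raise ValidationError(
                f"sd^2 = {sd**2:.6g} >= mean*(1-mean) = {bound:.6g}; no beta fit exists"
            )
        clipped = 0.95 * math.sqrt(bound)
        warnings.warn(
            f"sd {sd:.6g} infeasible for beta with mean {mean:.6g}; clipped to {clipped:.6g}",
            stacklevel=2,
        )
        sd = clipped
    nu = bound / sd**2 - 1.0
    return BetaSpec(mean=mean, sd=sd, alpha=mean * nu, beta=(1.0 - mean) * nu)


def _draw_prob(e: ProbabilityEstimate, rng: np.random.Generator) -> ProbabilityEstimate:
    spec = fit_beta(e.mean, e.sd)
    return dataclasses.replace(e, mean=spec.sample(rng), sd=0.0)


def _draw_util(e: UtilityEstimate, rng: np.random.Generator) -> UtilityEstimate:
    spec = fit_beta(e.mean, e.sd)
    return dataclasses.replace(e, mean=spec.sample(rng), sd=0.0)


def draw_parameter_set(params: TreatmentParams, rng: np.random.Generator) -> TreatmentParams:
    """One beta draw of every probability and utility in a parameter set.

    BNI outcome levels are drawn independently and renormalized to sum to
    one (a Dirichlet draw is available via :func:`draw_parameter_set_dirichlet`).
    Draw order is fixed so a given generator state maps to a unique
    parameter set.
    """
    bni = {lvl: _draw_prob(params.bni_dist[lvl], rng) for lvl in BNI_ORDER}
    total = sum(e.mean for e in bni.values())
    bni = {lvl: dataclasses.replace(e, mean=e.mean / total) for lvl, e in bni.items()}
    bni_utils = {lvl: _draw_util(params.bni_utilities[lvl], rng) for lvl in BNI_ORDER}
    comp_rate = _draw_prob(params.complication_rate, rng)
    recurrence = _draw_prob(params.recurrence_rate_7y, rng)
    retreat = _draw_prob(params.retreat_fraction, rng)
    comps = tuple(
        dataclasses.replace(
            c, incidence=_draw_prob(c.incidence, rng), utility=_draw_util(c.utility, rng)
        )
        for c in params.complications
    )
    med = MedicationModel(
        categories=tuple(
            dataclasses.replace(
                c, probability=_draw_prob(c.probability, rng), utility=_draw_util(c.utility, rng)
            )
            for c in params.medication.categories
        )
    ).renormalized()
    return dataclasses.replace(
        params,
        bni_dist=bni,
        bni_utilities=bni_utils,
        complication_rate=comp_rate,
        recurrence_rate_7y=recurrence,
        retreat_fraction=retreat,
        complications=comps,
        medication=med,
    )


def draw_parameter_set_dirichlet(
    params: TreatmentParams, rng: np.random.Generator
) -> TreatmentParams:
    """Variant drawing the BNI distribution jointly from a Dirichlet whose
    marginals match the per-level beta fits (alpha parameters reused)."""
    drawn = draw_parameter_set(params, rng)
    alphas = []
    for lvl in BNI_ORDER:
        e = params.bni_dist[lvl]
        spec = fit_beta(e.mean, e.sd)
        alphas.append(spec.alpha if not spec.degenerate else max(e.mean, 1e-6) * 1e6)
    sample = rng.dirichlet(alphas)
    bni = {
        lvl: dataclasses.replace(params.bni_dist[lvl], mean=float(p), sd=0.0)
        for lvl, p in zip(BNI_ORDER, sample)
    }
    return dataclasses.replace(drawn, bni_dist=bni)


# ---------------------------------------------------------------------------
# Patient-level microsimulation
# ---------------------------------------------------------------------------


def sample_path(root: Node, rng: np.random.Generator) -> float:
    """Walk one root-to-terminal path by sequential categorical draws."""
    node = root
    while isinstance(node, ChanceNode):
        probs = _norm_probs(node)
        r = rng.random()
        acc = 0.0
        child = node.branches[-1].child  # guard against floating-point shortfall
        for p, b in zip(probs, node.branches):
            acc += p
            if r < acc:
                child = b.child
                break
        node = child
    assert isinstance(node, TerminalNode)
    return node.payoff


def simulate_patient(
    point_params: TreatmentParams,
    config: ModelConfig,
    rng: np.random.Generator,
    tree: Node | None = None,
) -> float:
    """QALYs of one simulated patient under point (no-uncertainty) parameters.

    Builds the strategy tree if one is not supplied; callers running many
    patients should build the tree once and pass it in.
    """
    if tree is None:
        tree = build_treatment_tree(point_params.treatment, point_params, config)
    return sample_path(tree, rng)


# ---------------------------------------------------------------------------
# Two-level Monte Carlo
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PsaResult:
    """Per-strategy outcome of the outer x inner simulation."""

    treatment: Treatment
    trial_means: tuple[float, ...]
    grand_mean: float
    sd: float  # across-trial standard deviation
    n_outer: int
    n_inner: int
    seed: int


@dataclass(frozen=True)
class PsaComparison:
    mvd: PsaResult
    srs: PsaResult
    t: float
    p: float

    @property
    def difference(self) -> float:
        return self.mvd.grand_mean - self.srs.grand_mean


def _run_arm(
    treatment: Treatment,
    params_mvd: TreatmentParams,
    params_srs: TreatmentParams,
    config: ModelConfig,
    seed_seq: np.random.SeedSequence,
) -> PsaResult:
    trial_means = []
    child_seqs = seed_seq.spawn(config.psa_outer)
    for trial_seq in child_seqs:
        rng = np.random.default_rng(trial_seq)
        # draw both arms so re-treatment subtrees share the trial's uncertainty
        drawn = {
            Treatment.MVD: draw_parameter_set(params_mvd, rng),
            Treatment.SRS: draw_parameter_set(params_srs, rng),
        }
        tree = build_treatment_tree(treatment, drawn[treatment], config, drawn)
        qalys = [sample_path(tree, rng) for _ in range(config.psa_inner)]
        trial_means.append(float(np.mean(qalys)))
    arr = np.asarray(trial_means)
    return PsaResult(
        treatment=treatment,
        trial_means=tuple(trial_means),
        grand_mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
        n_outer=config.psa_outer,
        n_inner=config.psa_inner,
        seed=config.seed,
    )


def run_two_level_psa(
    params_mvd: TreatmentParams,
    params_srs: TreatmentParams,
    config: ModelConfig,
) -> PsaComparison:
    """Outer parameter draws x inner microsimulations for both strategies.

    Each outer trial draws one parameter set per arm from the fitted beta
    distributions, then simulates ``psa_inner`` patients through that
    trial's tree; the across-trial means of the two strategies are compared
    with a two-sided Welch t-test.  Identical seeds give identical output.
    """
    if config.psa_outer < 2 or config.psa_inner < 1:
        raise ValidationError("need psa_outer >= 2 and psa_inner >= 1")
    master = np.random.SeedSequence(config.seed)
    mvd_seq, srs_seq = master.spawn(2)
    res_mvd = _run_arm(Treatment.MVD, params_mvd, params_srs, config, mvd_seq)
    res_srs = _run_arm(Treatment.SRS, params_mvd, params_srs, config, srs_seq)
    t, p = welch_t_test(res_mvd.trial_means, res_srs.trial_means)
    return PsaComparison(mvd=res_mvd, srs=res_srs, t=t, p=p)
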