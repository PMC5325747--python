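# Methods

## Model structure

The unit of analysis is a single patient with medically refractory
trigeminal neuralgia undergoing a primary procedure (MVD or SRS) at time
zero, followed over a fixed horizon (default 7 years; a 1-year alternative
is available). The strategy is a chance tree, not a Markov model: all
event times are fixed constants, so each root-to-terminal path maps to a
deterministic timeline of health-state segments and its payoff is that
timeline's QALY integral.

Each procedure sub-tree branches over:

1. **Complication** (probability = the pooled per-arm complication rate).
   The complication branch multiplies subsequent utility by the
   complication sub-tree's conditional expected utility — the
   incidence-weighted mean utility over the arm's complication catalogue,
   divided by the total incidence. Because rollback is linear in terminal
   payoffs, collapsing the individual complications into this single
   multiplier is exactly equivalent to branching over them, and it mirrors
   how the aggregate "complications after MVD/SRS" utility rows are used in
   the source tables. Perioperative death (utility 0) is part of the MVD
   catalogue and therefore inside the multiplier; no separate survival
   model is applied. Complications are permanent from their onset time.
2. **BNI outcome** over the four levels (I, II, III, IV–V merged), with the
   pooled distribution renormalized to sum to one.
3. **Initial failure** (BNI IV–V at response assessment): re-treated with
   the arm's "recurrences re-treated" fraction at the re-treatment delay,
   otherwise persisting at IV–V on medication to the horizon. The evidence
   base reports only one re-treatment fraction per arm, so the same figure
   governs initial failures and recurrences; this is an assumption, not a
   reported value.
4. **Recurrence** (BNI I–III only): all recurrences occur at a fixed 2.5
   years after the procedure that relieved the pain (configurable;
   `horizon/2` is the natural alternative reading). Re-treated recurrences
   enter a fresh procedure sub-tree at that time; untreated recurrences
   settle at BNI III on medication for the remainder.
5. **Re-treatment** recurses with depth + 1, capped at two additional
   procedures. Each additional procedure multiplies subsequent utilities
   by 0.915, compounding with depth. The modality of a re-treatment
   follows the arm's mix: failed MVD → 80% MVD / 20% SRS; failed SRS →
   100% MVD. At the cap, initial failures persist at BNI IV–V and
   recurrences go entirely to the untreated BNI III branch.

### Event timing (months after each procedure)

| | MVD | SRS |
|---|---|---|
| pain outcome observed | 0 | 1 |
| failures re-treated | 1 | 3 |
| complications act from | 0 | 6 |

Before the outcome is observed (and between failure and re-treatment) the
patient sits in the pre-treatment state, BNI IV–V on medication. The SRS
timing reflects the delayed action of radiosurgery.

### Utility arithmetic

Per-year utility of a state is the product of all coexisting factors: the
BNI-level utility; the medication sub-model utility if the level requires
medication (III and IV–V; II — occasional pain *not* requiring medication —
does not); any complication multipliers; and 0.915 per additional
procedure. The medication sub-model returns the renormalized
probability-weighted mean of its three severity categories, 0.8740 with the
packaged values; the corresponding published sub-tree value is 0.881, which
is not the direct weighted mean of the printed table. Both are available —
`ModelConfig.pinned_medication_utility` pins the published constant — and
the default is the computed mean. Likewise the MVD complication sub-tree
evaluates to 0.9529 against a published 0.958: the residual
"other complications" categories carry no published utility and are set to
1.0 (replace those catalogue entries to override), which fully reproduces
the SRS value 0.962 and accounts for the small MVD gap.

## Parameters

All probabilities and utilities are (mean, SD) pairs on the proportion
scale; printed percentage tables are converted exactly once, in the
transcribed defaults or at file load (`units: percent`). Noteworthy
defaults: MVD BNI I 0.528, SRS BNI I 0.388; complication rates 0.176 / 0.193
(the MVD catalogue itself sums to 0.133 — the branch probability uses the
pooled outcome-table rate, the catalogue only the conditional utility);
7-year recurrence 0.159 / 0.226; re-treated fractions 0.080 / 0.455. The
MVD BNI IV–V SD is transcribed verbatim as 0.0067, anomalously small next
to its neighbours. The medication category probabilities print to 1.001
and are renormalized by their sum. Keratitis (SRS) compounds with the
facial-numbness and facial-palsy utilities. Catalogue utilities with no
reported dispersion (CSF leak, keratitis, stroke) carry SD 0 and behave as
point masses in the PSA.

## Probabilistic sensitivity analysis

Beta distributions are fitted to every (mean, SD) pair by the method of
moments (ν = m(1−m)/s² − 1); SD 0 or boundary means give point masses; an
infeasible SD (s² ≥ m(1−m)) is clipped to 95% of the feasible bound with a
warning (strict mode raises). Draws are independent across parameters —
no correlation structure is imposed — and the four BNI levels are drawn
independently then renormalized (a Dirichlet variant is provided). The
outer loop draws one parameter set per arm per trial (both arms, so
re-treatment sub-trees that cross modalities share the trial's
uncertainty); the inner loop samples patients by walking the trial's tree
with sequential categorical draws. Defaults are 100 trials × 100
microsimulations. The across-trial dispersion reported as ± is the SD of
trial means; with patient-level noise included it is wider than the
published ± values, which the source does not define precisely. Trial
means are compared by two-sided Welch t-test at the 0.05 level. A single
master seed is expanded into per-arm, per-trial substreams
(`SeedSequence.spawn`), so results are bitwise reproducible and independent
of evaluation order.

## Meta-analytic layer

Proportions are pooled on the raw-proportion scale (the stated method is
inverse-variance weighting of means; a logit-scale option guards against
boundary pathologies) with a 0.5 continuity correction applied only at 0 or
n events. Between-study variance uses the DerSimonian–Laird method of
moments truncated at zero — implemented directly because the statsmodels
estimator is untruncated; the two agree whenever τ² > 0, which a test
verifies. Heterogeneity is Cochran's Q against χ²(k−1). Meta-regression
is weighted least squares with 1/(vᵢ + τ²) weights, τ² by the
method-of-moments generalization of DL to a design matrix, slope inference
by normal approximation, and R² = (τ²₀ − τ²₁)/τ²₀ truncated to [0, 1].
Studies with more than 35% prior procedures are excluded at record load.

## Synthetic corpus

The generator emulates the published evidence base's statistical shape:
40 SRS and 17 MVD series; sizes uniform on 15–500; follow-up normal with
per-arm means/SDs (31.7 ± 19.2 and 43.2 ± 27.6 months) truncated below at
6 months; demographics (age, % female, % prior procedures) normal with the
pooled per-arm summaries; event counts binomial around the arm's true
rates, optionally shifted on the logit scale by standardized-covariate
slopes. It does **not** emulate publication bias, selective outcome
reporting, outcome-definition heterogeneity across studies, or
within-study correlation between outcomes — so recovery tests demonstrate
the estimators' calibration under a well-specified sampling model, not
robustness to the messiness of real literature data.

## Numerical choices and limitations

* Chance-node probabilities within 1e−6 of summing to one are silently
  renormalized (printed tables carry rounding); larger deviations are
  errors. Zero-probability branches are pruned from path enumeration.
* Rollback uses compensated summation and memoizes shared subtrees; the
  exhaustive path enumeration doubles as a brute-force oracle and is tested
  to agree with rollback to 1e−12 on random trees.
* Problem sizes in the test suite (20 000–100 000 microsimulation walks,
  500 pooling replicates, 100 propagation replicates at 30 studies × 300
  cases) were chosen to hold Monte Carlo error well below the tested
  tolerances while keeping the default suite around a minute on one core.
* No discounting of future QALYs, no cost layer, and no distinction among
  SRS platforms; percutaneous procedures are out of scope. Deterministic
  expected QALYs at the point estimates (5.88 MVD / 5.48 SRS) sit slightly
  below the published simulation means, consistent with the structural
  choices the source leaves open (shared re-treatment fraction, recurrence
  clock, complication-rate source noted above); the PSA grand means land
  within ±0.2 QALYs of the published 6.009 / 5.411.
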