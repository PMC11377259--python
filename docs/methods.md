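# Methods

## Model structure and assumptions

The model is a two-arm decision tree for a single on-demand dose of an acute
migraine treatment, evaluated over a 2-hour horizon. Each arm assigns a
patient to exactly one of three principal health states at 2 hours — pain
freedom (PF), freedom from the most bothersome symptom (FMBS), or treatment
ineffectiveness (TI, sustained pain) — and subdivides PF and FMBS by the time
symptoms resolved: 15, 30, 45, 60, 90 or 120 minutes post-dose. That yields
13 terminal branches per arm (6 PF + 6 FMBS + 1 TI).

Key structural assumptions:

* **States are mutually exclusive.** Although PF and FMBS originate as
  co-primary trial endpoints with possibly overlapping populations, the tree
  treats them as disjoint branch memberships; the branch probabilities are
  taken directly from the published per-state responder counts, and this
  reading reproduces the published base-case outputs exactly. The synthetic
  trial generator simulates the same disjoint structure (one multinomial over
  the three states per arm).
* **A terminal utility applies to the whole horizon.** Effectiveness is
  QALD = expected utility × horizon_hours / 24. This convention reproduces
  both published per-arm effectiveness values (0.0438 and 0.0420 QALD) to
  4 decimal places, which pins it down; no within-horizon utility ramp is
  modelled.
* **Cost is the dose price alone.** No adverse-event, recurrence, or indirect
  costs; the comparator costs zero. No discounting over a 2-hour horizon.

## Parameters

| parameter | default | units | notes |
|---|---|---|---|
| horizon | 2 | hours | final time bin must end at the horizon |
| WTP threshold λ | 734.45 | CNY/QALD | three times the daily-adjusted 2023 per-capita GDP; configurable |
| FMBS utility factor | 0.87 | — | u_FMBS(t) = 0.87 · u_PF(t); an explicit `utilities.fmbs` block overrides the derivation |
| dose cost (treatment) | 219.00 (175.20–262.80, SD 22.24) | CNY | ±20% deterministic range |
| 2-h state probabilities | from counts | — | e.g. PF 132/666 = 0.1982 |
| conditional bin splits | from counts | — | denominator = the state's 2-h responders |
| PF utilities | 0.7573 … 0.5040 | — | per bin, with low/high and SD |
| TI utility | 0.4400 (0.374–0.502, SD 0.2477) | — | "sustained pain in 2 h" |

Probabilities may be configured as responder counts (preferred; enables exact
beta PSA distributions) or directly as probabilities (point masses in the
PSA). Two quantities are never configured: the 120-minute conditional bin and
the TI probability are complements, derived on load (and logged). All derived
deterministic results use count-exact probabilities, not their 4-d.p.
roundings; the two agree on the ICER to within 0.05%.

The threshold price solves in closed form: because effects do not depend on
price and the comparator is fixed, ICER(price) is linear, and
price* = comparator cost + λ·ΔE; re-evaluating the tree at price* returns
ICER = λ to numerical precision.

## Deterministic sensitivity analysis

One parameter moves to its low/high value with all others at base: utilities
and costs use their configured ranges; probabilities use ±10% of base.
Perturbing a conditional time-bin probability rebalances only the residual
(120-minute) bin so the set still sums to one; perturbations that would push
any probability outside [0, 1] are clipped with a warning. Entries are ranked
by the width of the ICER interval; an end that flips the incremental result
out of the ICER-defined quadrant is reported as its dominance classification
and ranks as infinitely wide. Parameters are varied singly; a grouped variant
(`include_grouped_fmbs`) additionally scales all of an arm's listed FMBS bins
jointly by ±10%, since the FMBS bin probabilities act as a block in practice.

## Probabilistic sensitivity analysis

Per iteration, every parameter is drawn independently: probabilities from
beta(α, β) with the responder counts as shapes; utilities from betas
moment-matched to (base, SD); costs from gammas moment-matched to (base, SD).
A zero SD, or an infeasible moment match (SD² ≥ base·(1−base) for a utility),
degrades to a point mass with a logged warning. Two constraints are enforced
by resampling (up to 100 attempts, frequency logged) rather than truncation
or renormalisation, to keep the marginal families intact: p_PF + p_FMBS ≤ 1,
and each state's five listed conditional bins summing to at most one (the
residual bin takes the complement).

Resampling conditions the joint distribution on the constraint, so the
*joint* means of the most tightly constrained parameters (the comparator's
FMBS bins, whose listed sum is 0.888 at base) sit about 0.5% relative below
their base values; each distribution taken alone is mean-exact, and the mean
incremental effect of the PSA remains within Monte Carlo error of the
deterministic ΔE. This is an inherent property of constrained independent
sampling, not a calibration choice.

**Utility correlation.** By default utilities are sampled independently for
each arm's branches (`psa.utility_sampling: independent`). With the large
published utility SDs (~0.25) this makes the between-arm utility difference
the dominant noise source in ΔE and yields the characteristic pattern of a
large dominated fraction (~45% of draws costlier-and-less-effective) and an
acceptability curve that rises only slowly with WTP. Setting
`utility_sampling: shared` draws one utility set per iteration for both arms,
which removes utility noise from ΔE entirely; ΔE then varies only through the
(much tighter) probability betas and is almost surely positive. The published
100-iteration analysis is consistent with the independent default at WTP
100,000 CNY/QALD and on the dominated fraction, but its reported probability
of cost-effectiveness at WTP 30,000 (18%) is lower than independent sampling
produces (~36%); the source analysis's correlation structure and seed are
unknown, and no single independence assumption matches all three published
fractions simultaneously, so the default is kept and the discrepancy noted.

The published analysis used 100 Monte Carlo iterations, whose fractions carry
±5 percentage-point standard errors; this package's tests and acceptance
script use 10,000 iterations (fraction SE ≈ 0.5 pp, runtime ~2 s), so
comparisons against the published fractions are statistical, not exact.

The CEAC reports, per λ on a grid (default 0–150,000 CNY/QALD in 1,000-CNY
steps), the fraction of draws with λ·ΔE − ΔC > 0; the comparator's curve is
the complement. CE-plane quadrants treat ΔE = 0 as "no gain" (a draw with
positive ΔC and zero ΔE counts as dominated).

## Synthetic trials

The generator emulates a two-arm acute-treatment trial with the tree's
endpoint structure: per arm, one multinomial draw over (PF, FMBS, TI)
membership — so each 2-hour endpoint count is marginally binomial — followed
by a multinomial allocation of each state's responders across the six time
bins. Default scenario sizes (666 treatment, 674 comparator) match the source
trial's endpoint denominators. Counts are emitted in the input-table layout
and flow through the ordinary configuration loader, so simulated trials
exercise the same validation and derivation paths as real inputs.

What the generator does *not* emulate: overlapping co-primary endpoint
populations, dropout and missingness, within-patient correlation of relief
times, and covariates. Passing parameter-recovery and plug-in-consistency
tests therefore demonstrates correctness of the estimator pipeline under the
model's own assumptions, not robustness to real-trial complications. A state
with zero simulated responders has no conditional bin split; the generator
emits no bins for it and configuration building fails with a validation
error rather than inventing a split.

## Numerical choices

* Probability sums are validated to 1e-9; branch-level expected values use
  compensated summation (`math.fsum`).
* Incremental classifications treat |Δ| ≤ 1e-12 as zero; the ICER is reported
  only when ΔC and ΔE are both non-zero with the same sign, otherwise the
  draw is classified (dominant / dominated / equivalent) and no division
  occurs.
* Moment matching: beta shapes (m·k, (1−m)·k) with k = m(1−m)/SD² − 1; gamma
  shape (m/SD)² and scale SD²/m.
* Reports print CNY to 2 d.p. and QALD to 4 d.p.; CSV outputs keep full
  precision. With a fixed configuration, seed and version, primary CSV
  outputs are byte-identical across runs.
* Tests freeze the expected per-arm utilities (0.5256, 0.5041) from an
  independent enumeration of the 13 terminal branches, and verify the nested
  evaluation against that enumeration on random arms to 1e-12.

## Known limitations

* Single dose, single episode: no recurrence, repeat dosing, or preventive
  use; no adverse-event states or costs; no productivity losses.
* Utilities adapted from monthly-headache-day instruments to a 2-hour episode
  inherit that transformation's speculation; the very large SDs drive the PSA
  and the tornado.
* The PSA's agreement with the published fractions is statistical and partial
  (see above); the published analysis's sampling correlations are not
  recoverable from the inputs alone.
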