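# Methods

## Setting and model

The package implements a short-horizon cost-utility analysis of
radiotherapy from a healthcare-system perspective (direct non-medical
costs — transportation, accompaniment, out-of-pocket spending — are added
to capture part of the societal perspective). The unit of analysis is the
patient: one treatment arm (2D, 3D-CRT, IMRT or VMAT), one of twelve
cancer-type strata, two cost components, and three EQ-5D-5L utility
measurements (baseline, end of treatment, 6-month follow-up). The horizon
covers treatment plus six months of follow-up; no discounting is applied
at this horizon, and no discounting hook is exposed.

Effectiveness is measured in QALYs built by the area-under-the-curve
method: the utility trajectory is taken piecewise-linear through the three
measurements and integrated by the trapezoidal rule, with optional
last-value carry-forward when the accrual horizon extends past the final
measurement. Utilities may be negative (down to −1) for states worse than
death. EQ-5D-5L profiles map to utilities through an additive value set
(intercept 1 at full health plus non-positive per-dimension level
decrements), loaded from a delimited coefficient file. A toy tariff ships
for testing; any national tariff in the same three-column format plugs in
unchanged — the package deliberately ships no published national value
set.

Comparison is against a "no RT" / best-supportive-care arm whose cost and
QALY means come from literature, not from observed patients; the
comparator block therefore requires a provenance note and enters as
configuration, never as data the package derives.

## Incremental analysis

For intervention i and comparator c, ΔC = C̄ᵢ − C̄꜀, ΔE = Ēᵢ − Ē꜀, and
ICER = ΔC/ΔE whenever ΔE ≠ 0, computed at full precision and rounded only
for reporting (EUR to 2 dp, QALYs to 4 dp, distribution parameters to
4 dp). Classification follows the CE-plane quadrant: SE dominant, NW
dominated, NE more-effective-more-costly (judged against the WTP
threshold, default €30,000/QALY), SW cost-saving-but-less-effective.
SW-quadrant ratios are reported as positive values — savings per QALY
forgone — because that is how such rows are conventionally tabulated; the
classification enum prevents reading them as value for money, and the WTP
verdict there is "not applicable". Equal effect with savings is
`cost_saving_equal`; equal effect at extra cost counts as weakly
dominated. The WTP verdict is `cost_effective` only for dominant results
or NE results with ICER ≤ WTP; the weakly-dominant `cost_saving_equal`
case is deliberately not called cost-effective, since it buys no health
gain.

Arm summaries use the n−1 sample SD; a group of one reports its SD as
missing. Pooled totals are n-weighted means of group means (exact);
pooled SDs are not derivable from group moments and are reported missing.
Patients with an incomplete utility trajectory keep contributing to cost
moments but are excluded from QALY moments, with logged counts.

The one-way deterministic sensitivity analysis perturbs a single
comparator parameter (cost or QALY) to base × (1 ∓ p/100), default
p = 20, and recomputes the ICER at each bound; a bound that drives ΔE to
exactly zero yields an undefined ICER, flagged rather than fabricated.

## Parameter uncertainty

Costs are Gamma-distributed (continuous, non-negative, right-skewed):
k = (mean/SD)², θ = SD²/mean, an exact moment fit. QALYs are
Beta-distributed on [0, 1]: with ν = μ(1−μ)/σ² − 1, α = μν and
β = (1−μ)ν, feasible only when σ² < μ(1−μ) and 0 < μ < 1.

Observed arm moments can violate feasibility (a very dispersed small arm,
or a negative mean from worse-than-death utilities). The repair rule is
deterministic and auditable: clamp the mean into [10⁻³, 1−10⁻³] if
outside the unit interval (with a prominent warning — a clamped mean is a
modelling concession, not a measurement), then set the SD to a fixed
fraction (default 0.9) of the feasibility bound √(μ(1−μ)) and refit. The
repair preserves the mean exactly unless clamped and always yields
positive shapes; the original and adjusted moments are both recorded. A
printed-override mode accepts explicit (α, β) verbatim, for running the
PSA from an externally published parameter table whose own adjustment
rule is unrecoverable: the bundled reference table's 2D and 3D-CRT Beta
rows are exactly that case — their printed shapes imply means that
contradict their printed QALY means, so no repair rule can reproduce
them, and they are usable only verbatim.

Cost and QALY are sampled independently within a strategy (no correlation
structure is specified for the reference analysis); the PSA samples each
strategy from an independent substream keyed by (seed, CRC-32 of label),
so adding or removing a strategy never perturbs the draws of the others
and every stochastic output is reproducible from the recorded seed.

## Decision output

NMB = QALY × WTP − Cost. The CEAC's default definition is the **argmax**
rule: at each WTP, the cost-effective strategy of an iteration is the one
with the highest NMB over the whole strategy set including the comparator
(ties broken by lower cost that iteration, then label order), so
probabilities sum to 1 at every grid point. A **pairwise** mode
(P(NMB_s > NMB_comparator) per strategy) is also provided, because
published acceptability figures frequently do not state which definition
they used; the mode is recorded on the result. The default WTP grid is
€0–€60,000 in €1,000 steps, covering both the conventional €20,000–€50,000
evaluation range and the wider range used for NMB reporting.

The CE plane tallies quadrant frequencies of (ΔE, ΔC) per iteration.
Two conventions are implemented: deltas against the comparator **draw**
of the same iteration (default — comparator uncertainty propagated), or
against a **fixed comparator point** (the convention of analyses that
leave the counterfactual arm unsampled). They give visibly different
spreads — under the bundled reference parameters VMAT's NE share is ≈0.48
sampled versus ≈0.53 fixed — so the choice is an explicit argument and
should be reported alongside the figure. Boundary draws (a delta exactly
zero) count toward the positive side; the event has measure zero under
the continuous sampling distributions, so the choice is inert but
documented.

## Synthetic cohorts

The generator's defaults mirror the reference study's structure: arm
sizes 5/56/152/88 (n = 301), the published per-arm cost moments and QALY
SDs, the deterministic-table QALY means, cancer-type strata drawn
independently of arm with weights proportional to the published stratum
sizes (the joint arm × stratum distribution is unpublished), and an exact
80/20 split of total cost into medical/non-medical per patient.

Per patient, total cost is drawn from the arm's moment-fitted Gamma and a
target QALY from the arm's Beta (repaired where infeasible — for such
arms only the mean, not the SD, is recoverable, and the generator says so
in its log). The three-point trajectory is then solved **exactly** to the
target: writing the AUC as w₀u₀ + w₁u₁ + w₂u₂ (trapezoid weights plus
carry-forward, Σw = horizon), the patient sits at constant level
c = target/Σw and receives a zero-area shaped perturbation (baseline
rise, end-of-treatment dip, noise), scaled per patient to the largest
factor keeping all utilities in [−1, 1]. Inverse construction makes
arm-level recovery exact in expectation rather than approximate, which is
what the recovery tests assert (3 SE at n = 10⁵ and n = 2×10⁴ per arm).

Timing: measurement defaults are t₀ = 0, t₁ = 0.115 yr (≈6 weeks of
treatment), t₂ = t₁ + 0.5 yr. The `qaly` module's default horizon equals
t₂ (no carry-forward). The default **synthetic spec**, however, sets the
horizon to 1.0 yr with carry-forward: Beta-distributed targets live on
[0, 1], and only a horizon ≥ 1 yr makes every target attainable with
utilities ≤ 1 (with horizon = t₂ ≈ 0.62 yr, a large share of draws would
need clipping and arm moments could not be recovered). This also matches
the magnitude of the reference QALY means (up to 0.523), which are not
reconcilable with a strict half-year accrual window. All times are
configurable; analyses of real data should set them to the actual
calendar.

What the generator does **not** emulate: per-dimension EQ-5D-5L response
patterns (only trajectory-level utilities are produced), cost–utility
correlation within patients, arm × cancer-type dependence, and missing
data. Tests passing on synthetic cohorts therefore demonstrate the
pipeline's correctness under the stated moment structure, not robustness
to the messiness of real hospital exports beyond what the validation
layer checks.

## Numerical choices and limitations

* ICERs, deltas and pooled means are computed in double precision from
  unrounded inputs; published-value comparisons in the tests are made at
  the published numbers' printed precision.
* Moment fits are closed-form and round-trip their inputs to 1e−9
  relative; samplers are numpy `Generator`-based (Gamma, Beta).
* The reference tables contain internal inconsistencies that no
  implementation can smooth over: the technique-level ICERs printed for
  IMRT and VMAT, the DSA base-case ICER and the DSA ICER ranges are not
  derivable from any pair of printed cells, and the VMAT QALY mean
  differs by 0.002 between the deterministic and probabilistic tables.
  The package reproduces every reconcilable number and treats the rest
  as non-reconcilable inputs rather than targets.
* Problem sizes in the test suite — 10⁵ PSA iterations, 10⁵- and
  2×10⁴-patient recovery cohorts, 10⁶-draw law-of-large-numbers checks —
  were chosen to hold Monte Carlo error well inside the 3 SE assertions
  while keeping the suite fast.
* Small arms (the 2D arm has n = 5) make arm-level moments fragile; the
  PSA propagates that fragility but cannot repair it. Subgroup results
  with negative QALY means should be read as descriptive, not decisional.
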