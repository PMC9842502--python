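# Methods

## Estimand and meta-analysis

The unit of evidence is one field contrast: a treatment-group mean and a
control-group mean of the same outcome (an N-loss flux, crop yield, or
NUE).  The effect metric is the log response ratio ln r = ln(x̄_t/x̄_c),
reported as the percentage change (r − 1) × 100.  Per measure × outcome
cell the point estimate is the **unweighted** mean of log ratios.
Weighting by inverse variance or replication is deliberately not
offered: field studies frequently publish neither, and a mixed weighting
scheme would make cells incomparable.

Confidence intervals come from a nonparametric bootstrap of the cell's
log ratios (resamples of size n with replacement, default 4,999
iterations).  Two endpoint constructions are available:

* `bc` (default): bias-corrected percentile, with the tail level
  *expanded* from z to √(n/(n−1))·t₍n−1₎.  Percentile-type intervals for
  a mean are systematically narrow at moderate n — the resampling SD
  carries divisor n and no t-correction — and the expansion (Hesterberg's
  calibration) is the standard fix.  The acceptance suite measures the
  resulting operating characteristics by simulation rather than assuming
  them.
* `percentile`: plain percentile quantiles, with the same expansion.

An effect is flagged *significant* exactly when the interval excludes
zero.  Cells with one observation (or zero spread) return a degenerate
interval equal to the point estimate and are flagged as such.
Observations with non-positive means are outside the estimand's domain
and are rejected at the record level with a logged, row-addressed error.

Numerical conventions: each cell's log ratios are sorted before
resampling, so estimates depend only on the multiset of observations and
not their file order; cells are processed in a fixed vocabulary order,
each with a child seed spawned from the table seed, making the whole
effect table bit-reproducible and insensitive to which other cells are
present.

Converting effects to abatement efficacies: for a loss pathway,
η = −(percentage change)/100 clipped to [0, 1].  A measure that
*increases* a pathway contributes η = 0 there and the cell is surfaced
in a trade-off report — pollution swapping is reported, never credited
as negative abatement.  Yield and NUE effects become multiplicative
factors.

## Budgets, abatement and the fertilizer chain

A region's cropland budget carries five inputs (fertilizer, manure,
fixation, deposition, irrigation; kt N/yr), harvest, four gaseous
emissions (NH₃, N₂O, NOₓ, N₂), leaching and runoff.  NUE is
harvest/input.  No soil-stock term is carried: synthetic budgets close
exactly by construction, while user budgets may be non-closed and are
only flagged with a warning.

Abatement of pathway j by measure k: ΔE = A × EF × η × X.  When no
explicit activity/emission-factor table is given, the decomposition is
taken from the baseline budget itself (activity = total N input,
EF = flux/input), which guarantees A × EF reproduces the baseline flux —
so η = X = 1 removes the pathway entirely and X = 0 is exactly the
baseline.

Combination rules: measures add; a pair listed in the interaction table
abates the co-adopted activity fraction min(X_a, X_b) at the pair's
joint efficacy, with each measure's remaining adoption at its own
efficacy (the default interaction table is empty, reflecting how few
combined-treatment experiments exist).  Per-pathway reductions are
capped at the baseline flux.  Measures are adopted in a deterministic
priority order — ascending tier, then descending standalone reduction,
then name — and adoption stops once the region's projected NUE reaches
its target; the target caps mitigation because not every measure is
needed everywhere.  The priority order itself is a package choice (the
tier structure implies cheap-first, and the secondary sort makes the
truncation reproducible).

Yield multipliers are adoption-weighted (1 + (m − 1)X per measure) and
compound multiplicatively across adopted measures; harvested N is capped
at the regional target harvest.  N₂ losses are assumed to shrink by the
same *fraction* as total reactive-N losses — denitrification scales with
the surplus — and are tracked separately because an N₂ cut saves
fertilizer but is not an environmental improvement.

The input-side consequence follows from mass balance: the input no
longer needed equals everything no longer lost (reactive plus N₂) minus
the extra N exported in the larger harvest.  Deposition to cropland
falls in proportion to the gaseous reactive-N cut; the default
proportionality is the region's baseline deposition-to-gaseous-emission
ratio.  Extra manure recycling is the increase implied by a target
recycling ratio applied to the manure production potential, capped at
the cropland carrying capacity (defaults: target ratio 0.7, baseline
ratio 0.5, capacity 1.5 × baseline manure input).  Avoided chemical
fertilizer is then

    ΔN_fer = ΔN_input + ΔN_man − ΔN_dep.

Fertilizer cannot go negative.  Two clamp readings are implemented: the
default caps ΔN_fer at baseline fertilizer use (post-mitigation
fertilizer floored at zero), preserving the rest of the region's
mitigation; a strict mode zeroes any ΔN_fer exceeding the baseline.  The
default is preferred because discarding a region's entire fertilizer
saving on an overshoot breaks mass-balance coherence; the strict mode is
kept behind a flag for comparability.  Regions whose ΔN_fer comes out
negative should *increase* fertilizer ("too little" regions); the
increase is applied to the budget but never counted as a saving.

## Monetization

All accounting is single-year, in constant 2017 USD, masses in kt N and
unit prices in USD per kg N.  IC = ΔE × UC with UC an integrated unit
abatement cost per region; where a per-measure decomposition is needed
the integrated UC is interpreted as a ΔE-weighted average (an assumption,
since the composition across a measure mix is not otherwise defined).
Benefits: ecosystem EH = Σ_j ΔE_j × ∂_US,j × (WTP_i/WTP_US) ×
(PGDP_i/PGDP_US) — a benefit transfer of US unit damage costs; health
HH = Σ ΔE_j × HCost_j; yield YD = ΔHν × YP (signed: yield losses are
monetized costs); climate GHG = Σ ΔE_j × CCost_j with signed prices
(N₂O positive, NH₃/NOₓ negative — their abatement forgoes aerosol
cooling and reduces deposition-driven carbon uptake).  SOC is the exact
four-component sum, enforced draw-wise.  Fertilizer savings are kept
separate from UC and reported alongside gross cost; benefit-to-cost
ratios are quoted against the net cost (gross minus savings) and only
when that denominator is positive, with a gross-denominator variant
carried as well.  No discounting is applied.

Uncertainty is Monte Carlo, reported as mean ± 1 SD (the "±" of the
headline numbers is thus a 1-SD spread, a package convention).  Per
draw: each cell's effect is redrawn on the log-ratio scale from a normal
centred at the estimate with the CI-implied standard error; positive
prices are drawn normal truncated at zero; signed climate prices are
drawn untruncated.  The whole mitigation and accounting chain is re-run
per draw, so nonlinearities (clamps, NUE-target truncation) propagate
honestly.

## Scenarios

Four scenarios: BAU (no further adoption) and the cumulative Tier 1,
Tier 1+2, Tier 1+2+3 packages.  Harvest demand per region-year is an
exogenous input, identical across scenarios.  Adoption is filtered by a
declarative rules table over region attributes (default rules: buffer
zones capped at X ≤ 0.2 where land is scarce; Tier 2 and Tier 3 capped
at 0.5 and 0.3 in low-income regions).  Per region the scenario's
measure package at full adoption defines an endpoint NUE (capped by the
regional target) and yield multiplier; NUE and adoption interpolate
linearly from the base year to the horizon — the functional form is a
package choice, as no evidence favours another.  Each year: harvest :=
demand, input = harvest/NUE(t), surplus split into loss pathways by
shares interpolated between baseline and full-adoption budgets,
deposition proportional to gaseous losses, fixation and irrigation held
constant, fertilizer as the residual input (floored at zero), area =
harvest/yield(t).  The identities surplus = input − harvest and NUE =
harvest/input hold exactly at every point.  A demand point that would
need NUE > 1 raises an error naming the region-year rather than being
silently capped.

## The synthetic world

The generator emulates the statistical *structure* of the study's data
families, not its actual values.  Defaults mirror the study conditions:
11 measures × 8 outcomes with true effects spanning 30–70% loss
reduction, +10–30% yield and +10–80% NUE (the EEF cell anchored at −47%
total loss, +25% yield, +18% NUE); 17 observations per cell (≈1,500 in
the grid); log-scale noise SD 0.25.  Control means are lognormal
(median 50, log-SD 0.6) because field fluxes are positive and
right-skewed; treatment means multiply the control by exp(effect +
noise), so the log response ratio is the exact estimand and all means
stay positive.  Budgets close exactly with NUE uniform on (0.2, 0.8) by
default and input/loss shares drawn from Dirichlet distributions shaped
to typical global proportions; every world contains a "USA" region as
the willingness-to-pay/PGDP reference.  Unit damage costs are fixed
US-reference values with health costs scaled by relative income and WTP
by its square root.  A single seed determines every table bit-exactly,
via named substreams per family.

What the generator does **not** emulate — and what passing tests
therefore do not establish about real data: between-study heterogeneity
beyond iid noise, correlated outcomes within a study, publication bias,
region-dependent effect sizes (effects are global by design),
non-closed budgets, soil N stock dynamics, price dynamics or trade
feedbacks.

## Problem sizes and verification

The test suite exercises: closed-form and hand-worked fixtures for every
budget, abatement and monetization operation (including a full worked
chain on a round-number region); equivalence of the measure-combination
logic with an exhaustive brute-force oracle on randomized ≤4-measure
instances; equivalence of the bootstrap with an independent loop-based
resampler on a shared seed stream; interval coverage and the
significance rule's type-I error on 500 simulated meta-datasets of 50
observations each; and end-to-end recovery of configured global accounts
within 3 Monte-Carlo SDs at 1,000 draws on an 8-region world.  These
sizes keep the full suite under a minute while leaving the binomial
error of the calibration checks (≈1 percentage point) well inside the
asserted bands.

## Known limitations

* Implementation rates X are consumed as data; no adoption behaviour is
  modelled.
* The integrated unit abatement cost hides measure-level cost structure;
  marginal-abatement-cost ordering cannot be recovered from it.
* Health damage costs are unit prices per kg N, not a dose-response
  chain; benefit transfer by WTP/PGDP ratios is a strong assumption for
  low-income regions.
* The NUE-target truncation applies after manure substitution; the
  alternative ordering is defensible and would change region-level (not
  aggregate-identity) results.
* Scenario projections have no land-use economics: area follows
  harvest/yield with no competition for land.
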