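# Methods

## Stochastic partial budgeting

Partial budgeting values only the cash flows that change when a farm
adopts an intervention.  Because single-point budgets hide the large
between-farm variation in those cash flows, every cost and benefit item
here is a three-point estimate — minimum, most-likely, maximum, in GBP per
pig produced — treated as a triangular distribution.  The net effect is
the sum of benefit draws minus the sum of cost draws; an intervention is
profitable in a draw when the net effect is non-negative.

Assumptions worth stating explicitly:

* **Independence.** Items are sampled independently.  Correlations between
  expert three-point estimates of this kind cannot be estimated from the
  available data, so no correlation machinery exists; results should be
  read accordingly (positively correlated costs would fatten both tails of
  the net effect).
* **Mode convention.** The central value of each envelope is used as the
  *mode* of the triangular distribution.  For survey-derived envelopes the
  central value is the arithmetic mean across farmers; using it as the
  mode is the standard three-point-estimate convention and matches how the
  envelopes were assembled.
* **Tie handling.** "Neutral or positive" means net ≥ 0 and "loss" means
  net < 0.  The tie set has probability zero for non-degenerate items, so
  the split is well defined and `prob_loss + prob_nonneg = 1` exactly.
* **Units.** GBP per pig produced throughout; no currency conversion,
  inflation adjustment or discounting (structural investments are
  amortised linearly, see below).

## Simulation engine

Sampling is inverse-transform: each item consumes exactly one uniform per
draw from a single `numpy` PCG64 stream, so a run is reproducible from
(seed, n, scenario, aggregate mode) alone, and scaling all monetary bounds
by k > 0 scales every sampled net effect by exactly k.  The default run
size is 500 draws, the size at which the headline results are reported; a
500-draw loss-probability estimate carries a binomial standard error of
about 2.2 percentage points, which is why oracle-equivalence tests use
100,000 draws instead.

`aggregate_mode` offers two readings of a multi-item scenario: sampling
each component row independently (`components`, the default) or sampling
one triangular per direction built from the summed bounds (`totals`).
The two give different net-effect distributions (summed-bounds totals are
wider in the middle); both are exposed because either reading of a
published cost table is defensible.  Reported extremes are the observed
Monte Carlo extremes, not the analytic support bounds — published ranges
of this kind are sample extremes and must be compared as such.

### Analytic oracle

`analytic_net_distribution` convolves the item densities numerically:
each triangular density is discretised to cell-centred probability masses
on a regular grid (step 0.001 GBP by default, costs negated), the masses
are convolved with `numpy.convolve`, and the cumulative sums are
attributed to the right edge of each cell — the cumulative mass through an
atom covers its whole cell, and ignoring that half-step shift biases the
CDF upward by h·f/2.  With the shift handled, the oracle agrees with
adaptive quadrature of the exact integrals to ~10⁻⁶ at the default step,
far below the Monte Carlo noise it is used to check.  Degenerate
(point-mass) items occupy a single cell.

## Cost sub-models

**Growth penalty (large groups).**  Average daily gain for a growing pig
declines linearly with group size: 0.65 kg/day minus 0.00048 kg/day per
additional pig, floored at zero.  Moving from the industry-typical group
of 50 to 100+ pigs therefore costs 0.024 kg/day, monetised as
Δadg × days-on-phase × price/kg.  The shipped fixture uses 83.3 days on
the growing phase and a (0.60, 0.80, 1.00) GBP/kg price envelope — a
calibration chosen so the central value reproduces the packaged
(1.20, 1.60, 2.00) cost row, declared as such in the fixture file rather
than claimed as sourced market data.

**Pheromone dosing.**  Product instructions put one diffuser per 25 m² of
pen, effective for six weeks (the 1.5 m mounting height has no monetary
consequence).  Diffusers needed = ⌈pen area / 25⌉; one installation cycle
serves the pigs housed on the covered area (38 pigs at the default
0.65 m²/pig stocking density for a 25 m² pen).  Purchase and installation
labour are reported separately per pig.  Diffuser prices
(11.78, 14.82, 17.48 GBP) and installation times (2.4, 7.2, 9.6 minutes
at £9.50/h) are calibrated to the packaged (0.31, 0.39, 0.46) and
(0.01, 0.03, 0.04) cost rows and flagged `calibrated_to` in the fixture.

**Benefit scaling.**  Farmers priced the saving from an optimistic 50%
reduction in aggression (mean £0.30 per pig produced); that figure is the
benefit maximum.  The most likely value is half of it (£0.15), matching a
realistic 25% reduction under an assumed linear benefit–reduction
relationship, and the minimum is zero.  Linearity is an assumption — the
true shape has never been measured — but survey respondents cannot be
expected to price non-linearity either.

**Amortisation.**  Structural investments spread linearly over a ten-year
lifetime with no discounting: GBP per pig produced =
investment / (lifetime × annual output).

## Survey aggregation

Answers arrive per pig, per pen or per farm.  Conversion to GBP per pig
produced divides per-pen answers by pigs-per-pen × batches-per-year
(default 3, a ~115-day finishing cycle) and per-farm answers by annual
output (taken from the profile, or finisher places × batches-per-year);
investment answers are additionally amortised over ten years.  Per-pig
answers pass through unchanged — they are read as already expressed per
pig produced, which keeps the three scales mutually consistent.

Inclusion rules: a farmer contributes only when every entry for the
scenario, in both the investment and on-going phases, is answered
(zero is an answer, not missingness — several farmers genuinely price
their own labour at nothing).  Mortality items are removed before
aggregation because increased mortality under these interventions is not
supported by experimental evidence; removal happens before the
completeness check, so adding a blacklisted item can never change a
result.  The aggregate is the across-farmer minimum, arithmetic mean and
maximum of the per-pig totals (farmers weighted equally); the standard
deviation is reported but plays no role downstream.  The mean becomes the
mode of the triangular estimate the engine consumes.

## Synthetic survey generator

The original survey responses are confidential, so the pipeline is tested
against a generator that emulates their structure: 16 farmers by default;
herd sizes per production stage from truncated lognormals calibrated so
the simulated means match the surveyed summaries (weaners 1359, growers
999, finishers 1447, sows 390; σ = 0.7, ranges enforced by rejection) and
pigs-per-pen from a more skewed model (σ = 0.9) that reproduces both the
surveyed mean of 64 and median of 39; per-item ground-truth envelopes
mirroring the surveyed cost structure; a 50/25/25 per-pig/per-pen/per-farm
reporting-scale mix; 30% zero-inflation of answered costs; and 30%
phase-level missingness — a farmer answers a phase fully or not at all,
matching the level at which the complete-case rule operates.

Every answer is generated by drawing a per-pig truth and *inverting* the
aggregation module's conversion with the farmer's own profile.  Recovery
tests are therefore meaningful: with clean settings, aggregation must
return the generated envelope exactly; with mixed scales, to within
floating-point round-off (1e-9).  What passing these tests does **not**
show: that real farmers report on consistent scales, that real answers are
triangular, or that real missingness is ignorable — the generator has no
response-bias or scale-confusion mechanisms, deliberately.

## Willingness to pay

The welfare-motivated farmer class (50% of respondents in the underlying
choice experiment) will pay £0.11 per pig place (installation) and £0.03
per pig produced (running) for each 1% reduction in aggression lesions;
the other two classes pay nothing for aggression reduction specifically.
Conversion to GBP per pig produced at reduction r%:
running × r + install × r / pigs-per-place-lifetime.  The default lifetime
throughput of 137.5 pigs per place is backed out so the welfare class
totals £0.77 at r = 25 — a calibration, flagged in the fixture.

Viability compares the worst simulated loss (−sample minimum, or the
analytic support bound if requested) against the WTP budget: `profitable`
when no draw loses, `viable_within_wtp` when the worst loss is covered,
`beyond_wtp` otherwise.  The verdict is monotone in the budget.

## Numerical and testing choices

* Convolution step 0.001 GBP; refining converges (checked at 0.0002).
* Quantile/CDF round-trips hold to 1e-12; triangular primitives are
  verified against `scipy.stats.triang`, which is never used in the
  implementation path.
* Loss-probability checks at the published 500-draw size are made on the
  median across 200 seeded runs: a single 500-draw estimate has a 2.2 pp
  standard error, so any single-seed comparison against a ±5 pp band
  would fail roughly one seed in ten by chance alone.  Published
  net-effect ranges are likewise checked distributionally — the printed
  extreme must lie within the central 95% spread of the simulated extreme
  across 200 seeded 500-draw runs.
* Simulation sizes used by the tests (200 × 500 draws for distributional
  checks, 100,000 draws for oracle equivalence, 10,000 draws for
  farm-size calibration) keep the whole suite under a few seconds while
  leaving Monte Carlo error well below the tolerances tested.

## Known limitations

* No correlation between items; no distributions other than triangular.
* The calibrated sub-model parameters reproduce the packaged envelopes but
  are not claimed to be the historically correct market inputs.
* Survey conversion constants (batches per year, pigs per sow per year)
  are industry-typical defaults, configurable per analysis.
* Costs of building new housing for large groups are out of scope; the
  large-groups scenario prices the conversion of existing buildings only.
* WTP is taken from a prior choice experiment as fixed rates; no
  re-estimation from choice data.
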