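# Methods

## The composite score

For a child with WHO z-scores (HAZ, WAZ, WHZ) inside the plausibility box
B = [−6, +6] × [−6, +5] × [−5, +5], the score at integer power n ≥ 1 is

    score = 100 / D · [ A − sp(HAZ, n) − sp(WAZ, n) + |WHZ|ⁿ ]

with sp(z, n) = sign(z)·|z|ⁿ, A = 6ⁿ + 5ⁿ and D = 3·6ⁿ + 2·5ⁿ. The
construction is motivated as follows:

* Plain averaging of z-scores lets positive and negative deviations cancel;
  subtracting HAZ and WAZ from a constant makes deficits raise the score.
* Both tails of WHZ are failures (wasting below −2, overweight above +2),
  so WHZ enters through its absolute value; equivalently, the score has two
  algebraically identical branches (adding the WHZ term when WHZ < 0,
  subtracting it when WHZ > 0) that coincide at WHZ = 0. The implementation
  uses the single form; equivalence with the branch form, written with the
  literal quotient power z^(2n−1)/|z^(n−1)|, is property-tested to 1e-9
  relative error.
* Raising to the power n (sign-preservingly, so even n do not fold negative
  z-scores positive) makes extreme deviations dominate moderate ones. The
  default n = 15 concentrates the score on severe failure.
* A is the maximum of the branch-appropriate sum over B (attained at
  HAZ = +6, WAZ = +5, WHZ = 0; 11 at n = 1), which pins the score minimum
  at 0; D is the bracket's value at the all-worst corner (−6, −6, −5)
  (28 at n = 1), which pins the maximum at 100. Higher score = more severe
  failure. These maxima are re-derived by brute force (corner enumeration of
  the two WHZ half-boxes, where the n = 1 objective is linear; a dense grid
  is available as a cross-check) rather than asserted.

sp is computed directly as sign(z)·|z|ⁿ instead of the quotient form: at
n = 15 the quotient's numerator reaches 6²⁹ ≈ 3.7·10²², which loses double
precision. With the evaluation order 100·bracket/D, integral corner inputs
are exact up to n = 19; at n = 20 the bracket exceeds 2⁵³ and the top corner
is 1 ulp below 100. Tests assert exactness for n ≤ 19 and 1e-12 relative
agreement at n = 20.

## Cut-off calibration and gating

The Failure/No-failure threshold is calibrated on a scored population: the
cut-off is the minimum score among children with HAZ strictly below −2.10
SD. The threshold sits deliberately below the conventional −2 stunting line:
linear growth is saltatory, and a child briefly below −2 may be growing
normally; requiring −2.10 keeps such children out of the qualifying set.
Ties at the cut-off classify as Failure — the record defining the cut-off
has HAZ < −2.10 and must itself be Failure for the rule to be coherent.
Score comparisons use exact float ordering (scores are deterministic
functions of the inputs, so ties reproduce).

A structural note: at n = 15 the cut-off is tightly pinned across
populations. A qualifying child just below HAZ = −2.10 with unremarkable
WAZ/WHZ scores ≈ 100·(A + 2.1¹⁵ + small)/D, and since 2.1¹⁵ ≈ 8·10⁵ is
negligible against A ≈ 5·10¹¹, any large population's cut-off lands near
100·A/D ≈ 34.0246. The calibration is still computed, never assumed.

*Gating*: after calibration, a child whose score falls below the cut-off is
reassigned to "No failure" before tabulation, regardless of indicators.
Gating can only move probability mass into "No failure", so gated prevalence
is ≤ ungated prevalence for every indicator and every failure group — a
property the tests check. Specificity of the gate (no conventionally-healthy
child called Failure) is an empirical property of a population, not a
structural guarantee; the confusion audit reports it rather than asserting
it. The standard definitions sensitivity = tp/(tp+fn) and specificity =
tn/(tn+fp) are used throughout; published confusion tables for this kind of
audit do not always match their own cells under these definitions, so the
audit recomputes everything from the data.

The score is a population-description template. It must not be used to find
children with severe or moderate acute malnutrition: a child with low WHZ
but high HAZ can receive a low composite score.

## Taxonomies

Indicators are strict: stunted HAZ < −2, wasted WHZ < −2, underweight
WAZ < −2, overweight WHZ > +2; a child at exactly ±2 fails nothing. Wasted
and overweight partition disjoint WHZ ranges and can never co-occur, so 12
of the 16 boolean combinations are realisable.

Group labels are assigned by exact row-matching against the published
tables: Svedberg (A–F, Y; the table ignores overweight), Kuiti (adds G
"Stunting and overweight" and H "Overweight only"), and the ten-group model
(adds I "Stunting, underweight, and overweight"). Two combinations match no
row of the ten-group table — wasting + stunting without underweight, and
underweight + overweight without stunting (conjectured biologically
implausible, as underweight with overweight appears to require a stunted
frame). Whether either can occur in real data is open; both are surfaced as
`Unclassified`, never folded into another group.

Kuiti's model ships in two modes because the motivating discrepancy is only
explicable under a non-strict operationalization: *strict* (row-matching;
S+U+O → Unclassified) and *legacy-sequential* (label by the Svedberg table,
then reassign any overweight child to G if stunted, H if otherwise
failure-free; S+U+O → G). The cross-model audit checks the identities
Svedberg E = proposed E + proposed I, legacy-Kuiti G = proposed G +
proposed I, and legacy-Kuiti E = proposed E, plus totals conservation.

## Exclusion pipeline

Records are screened in a fixed order: (1) missing height/weight, (2)
height out of bounds, (3) age out of bounds, (4) missing z-scores, then
z-scores flagged strictly beyond the plausibility limits (checked HAZ, WAZ,
WHZ). Stages 2–3 are DHS-internal screens with no published bounds and
default off (configurable; age bounds are given in days, converted at
30.4375 days/month). Each record is attributed to exactly one reason — its
first failing stage — so input = retained + Σ exclusions always balances,
and the pipeline is idempotent on its own output. Boundary z-scores
(exactly ±6/±5) are retained: "beyond plausible limits" reads as strict,
matching WHO flagging convention. Missing z-scores with measured
height/weight get their own reason code rather than being lumped with
missing anthropometry.

## Survey-weighted estimation

Proportions are ratio estimators p = Σwᵢyᵢ/Σwᵢ. When stratum and PSU
identifiers are present, the 95% CI uses the first-order Taylor-linearized
design variance under with-replacement sampling of PSUs within strata
(single-PSU strata contribute nothing); otherwise a normal approximation on
the Kish effective sample size n_eff = (Σw)²/(Σw²). CIs are clipped to
[0, 100]. Weighted frequencies and percentages are kept at full precision
internally; display rounding (integers for frequencies, 1 decimal for
percentages) happens only at render time. Reproducing a specific survey's
design-based CIs requires that survey's design variables and is out of
scope.

## Synthetic populations

The generator emulates the z-score structure of a DHS-style under-five
sample:

* (HAZ, WHZ) ~ bivariate normal; defaults mean (−1.2, −0.8), SD (1.6, 1.3),
  correlation 0.1. The means/correlation reflect a high-burden under-five
  population; the SDs were chosen so the implied marginal prevalences land
  in the realistic range for such settings (≈30% stunting, ≈18% wasting,
  ≈2% overweight).
* WAZ = 0.55·HAZ + 0.55·WHZ + ε, ε ~ N(0, 0.35²): weight-for-age was
  introduced to fold together linear and ponderal deficit, so it is
  generated structurally rather than as a third free normal. The default
  loadings keep marginal WAZ variance near 1 and let coherent rare
  combinations (very low HAZ and WAZ with WHZ > +2) arise naturally.
* Triples outside the plausibility box are rejection-sampled (not clipped,
  so the limits carry no boundary atoms); a >99% rejection rate raises an
  error instead of looping.
* Survey weights are lognormal(0, 0.5) by default (or constant 1); stratum
  and PSU labels are drawn from small pools so design-based CIs are
  exercised.
* *Planting*: records for any ten-group category are drawn uniformly from
  group-consistent z-boxes kept 0.01 SD clear of the ±2 thresholds, so
  classification recovers planted counts exactly. Group I uses the
  empirical ranges reported for that category in national data
  (HAZ −6.00..−3.82, WAZ −4.03..−2.01, WHZ +2.01..+4.82).
* The *messy* variant corrupts disjoint subsets — dropping height/weight at
  one rate, pushing one z-score out of the box at another — and returns the
  injected counts, so the exclusion report can be verified reason-by-reason.
* Heights/weights are cosmetic monotone functions of age and the z-scores;
  nothing recomputes z-scores from them.

What the generator does **not** emulate: real age/sex-specific z-score
heteroscedasticity, cluster-level correlation of nutrition status, weight
calibration to population margins, or measurement error. Passing tests
therefore demonstrate the pipeline's internal correctness (conservation,
partition, calibration, gating monotonicity, exact plant recovery), not
agreement with any real survey's estimates, which would require the
registered-access microdata.

## Default problem sizes

Property suites run on 10,000 random triples; generator checks use
populations of 1,000–10,000 children; the full-pipeline example uses 5,000.
These sizes make the sampling properties (e.g. empirical HAZ–WHZ correlation
within ±0.05 of the configured value) sharp while keeping the whole suite
fast on a single CPU.

## Known limitations

* The three z-scores have different plausibility ranges, which distorts the
  score at the extremes; the ranges are fixed by convention and kept as-is.
  The score is a template for further development, not a finished clinical
  instrument.
* WAZ partly duplicates HAZ and WHZ; including it in the score weights
  combined failure more heavily by construction.
* The cut-off depends on z-score precision in the input file (2 decimals in
  DHS recodes); bit-exact reproduction of a published cut-off is not
  promised even with the same data.
* `Unclassified` is reported, not resolved: the taxonomy's claim to cover
  all combinations rests on the biological-implausibility conjecture above.
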