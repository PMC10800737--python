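# anthrofail

Composite anthropometric-failure scoring and CIAF classification for
under-five child anthropometry.

## The problem

Child malnutrition surveillance rests on three WHO growth-standard z-scores:
height-for-age (HAZ), weight-for-age (WAZ) and weight-for-height (WHZ), with
the conventional cut-offs stunting HAZ < −2, underweight WAZ < −2, wasting
WHZ < −2 and overweight WHZ > +2. Reported separately, these overlap — the
same child can be stunted, underweight *and* overweight — so marginal
prevalences neither sum to a total burden nor reveal which combinations
dominate. The Composite Index of Anthropometric Failure (CIAF) addresses
this by partitioning children into mutually exclusive failure groups, but
its successive taxonomies (Svedberg's seven groups, Kuiti's nine) miss the
combination "stunting + underweight + overweight", which makes sequential
operationalizations of Kuiti's model silently shuffle counts between groups.
Separately, a child in a slow phase of saltatory linear growth can cross a
single −2 SD line and be misclassified as malnourished even though the
overall anthropometric picture is unremarkable.

This package implements:

* **A 0–100 composite failure score** combining the three z-scores with
  sign-preserving powers, so that severe deviations dominate and deficits on
  any axis (including high WHZ) raise the score:

  ```
  score = 100 / (3·6ⁿ + 2·5ⁿ) · [ (6ⁿ + 5ⁿ) − sp(HAZ) − sp(WAZ) + |WHZ|ⁿ ]
  sp(z) = sign(z)·|z|ⁿ,   default n = 15
  ```

  The constants come from the WHO plausibility box (HAZ ∈ [−6, +6],
  WAZ ∈ [−6, +5], WHZ ∈ [−5, +5]): the score is exactly 0 at the most
  favourable point (+6, +5, 0) and exactly 100 at the worst (−6, −6, −5).
  At n = 1 this is the familiar `(100/28)·(11 − (HAZ + WAZ ± WHZ))`.

* **Empirical cut-off calibration**: the failure threshold is the lowest
  score among children with HAZ < −2.10; scores at or above it classify as
  Failure. Children whose score falls below the cut-off can be *gated* to
  "No failure" before group tabulation.

* **Three CIAF taxonomies** (Svedberg, Kuiti — strict and legacy-sequential
  — and the ten-group model adding group I, "Stunting, underweight, and
  overweight"), with a cross-model audit of the counting identities that
  link them.

* **Survey-weighted prevalence** with 95% CIs (Taylor-linearized when
  stratum/PSU design fields are present, Kish effective-sample-size normal
  approximation otherwise).

* **WHO plausibility screening** (flagging z-scores beyond the limits above)
  and a staged exclusion pipeline with balanced bookkeeping.

* **A seeded synthetic population generator** (correlated HAZ/WHZ, WAZ built
  structurally from both, rejection-sampled into the plausibility box, with
  plantable rare categories), so the whole pipeline is testable without
  registered-access DHS microdata.

Intended users: nutrition epidemiologists and survey analysts working with
DHS-style child recode files, and methodologists studying composite
anthropometric indices.

## Worked example

```python
from anthrofail import (
    SyntheticConfig, generate_population, run_full_pipeline, RunConfig,
)

records = generate_population(
    SyntheticConfig(n_children=5000, seed=1, planted_records=[("I", 6)])
)
report = run_full_pipeline(records, RunConfig(n=15))
print(report["calibration"])
print(report["group_counts"]["gated"])
print(report["confusion"])
```

prints (exactly, for this seed):

```
{'cutoff': 34.02459881406433, 'haz_threshold': -2.1, 'qualifying_count': 1428}
{'A': 2926, 'B': 277, 'C': 237, 'D': 320, 'E': 568, 'F': 549, 'Y': 53,
 'G': 19, 'H': 46, 'I': 6, 'Unclassified': 5}
{'tp': 2080.0, 'fp': 0.0, 'fn': 132.0, 'tn': 2794.0,
 'sensitivity_pct': 94.03254972875226, 'specificity_pct': 100.0}
```

Reading this: the cut-off calibrated on 1,428 children with HAZ < −2.10 is
≈ 34.02 (at n = 15 the cut-off is structurally pinned near
100·(6¹⁵+5¹⁵)/(3·6¹⁵+2·5¹⁵) ≈ 34.0246, because a child just below the HAZ
threshold contributes negligibly through WAZ and WHZ at that power). All 6
planted "stunting + underweight + overweight" children are recovered in
group I. Gating moved 132 conventionally-failing children (borderline on a
single indicator) into "No failure" — the score's sensitivity against the
conventional any-indicator definition is 94.0% here — while no child free
of conventional failure was called Failure (specificity 100%).

The same flow is available from a shell:

```sh
anthrofail simulate --n 5000 --seed 1 --out pop.csv
anthrofail score pop.csv --out scored.csv
anthrofail calibrate pop.csv
anthrofail run pop.csv --out report.json
```

## Scope notes

The package assumes z-scores are already computed (as in DHS files); it does
not evaluate WHO growth standards from raw height/weight/age. The score is a
population-description template, not a clinical screen: it must not be used
for SAM/MAM case-finding, since a child with acute malnutrition but high HAZ
can score low. See `docs/methods.md` for the model details, the synthetic
generator's assumptions, and known limitations.
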