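# Methods

## The estimation problem

Confiscation reports of pangolin derivatives are collated by several
independent monitors; the quantity of scientific interest is how many
animals the confiscated scale mass represents. Because a scale set cannot
identify an individual, the package estimates a *minimum* number of
individuals (MNI): the smallest count of animals whose complete scale sets
could produce the observed mass, assuming every scale of each contributing
animal is present in the shipments. The chain has four stages — curation,
composition estimation, bootstrap uncertainty, and mass-to-count conversion
— each implemented as an independently testable module.

## Curation and deduplication

Reports are harmonised to kilograms (unit dialect kg, g, t/tonnes, lb;
canonical precision 3 decimals) and validated: year-mandatory partial
dates, ordered ISO-3166 alpha-3 routes containing the seizure country,
transport mode in {air, land, sea, warehouse, unknown}. Premises
confiscations with no route information are *warehouse* seizures and carry
a single-country route. A shipment's transport mode is the mode of the
longest leg of its route.

Duplicate reports of one event are linked transitively when they share the
seizure country, fall within a **date window** (default ±7 days; partial
dates are compared at their mid-year/mid-month representative) and agree on
quantity (total masses within a **relative tolerance**, default 10%, or
equal item counts; if only one side carries a quantity, date and country
decide). Cross-database mass disagreement is common in this reporting
domain, and neither threshold has a canonical value, so both are exposed in
configuration. Within a merged cluster the reference database's identity
and date are kept and the lowest reported mass wins — totals err downward,
consistent with a minimum estimator. Merging only lowers cluster masses, so
total mass never increases, and the operation is idempotent on realistic
inputs (re-linking merged records creates no new matches).

## Trend statistics

Seizure masses span roughly four orders of magnitude, so location
differences across transport modes are tested non-parametrically:
Kruskal–Wallis on midranks with tie correction, followed by Dunn's
pairwise z tests with tie-corrected pooled variance. Dunn p-values are
reported **unadjusted** by default (Holm/Bonferroni available behind a
flag): the downstream use is descriptive comparison of three modes, and
the unadjusted convention matches how such seizure analyses are usually
reported.

The year trend is modelled as Gaussian-identity OLS on log10 mass — the
log10 transform addresses residual normality, and no link-function
machinery is needed beyond that. Year enters as a continuous covariate,
mode as a categorical with alphabetical baseline (air), optionally with a
year×mode interaction. Candidate formulas are ranked by AIC (AICc behind a
flag for small samples), ties within 1e-9 broken toward fewer parameters.
Analyses default to complete calendar years (2010–2020); an incomplete
final year would bias the trend. Rank-deficient designs raise an error
naming the collinear columns rather than silently dropping terms.

## Trade-flow roles

The first country of a route is the shipment origin, the last (when the
route has ≥ 2 stops) the import country, intermediates are transit stops;
each country counts at most once per role per record. A route that stops in
Nigeria with no onward leg therefore records Nigeria as import — analysts
can treat those separately since the route itself flags the missing onward
journey. Warehouse and unknown-mode records carry no route information and
are excluded from flow aggregation. Role counts are aggregated over closed
calendar intervals (defaults 2010–12, 2013–15, 2016–18, 2019–Sep 2021, the
last truncated by date rather than year) and normalised to barycentric
coordinates for ternary composition plots. Territories that act as distinct
trade nodes (e.g. Hong Kong) keep their own codes.

## Relative proportional mass and the bootstrap

For each sampled sack, `p_rm` of a species group is the group's sorted
scale mass divided by the sack's **total sorted mass**, including scales
sorted but not identified to species. This keeps each sack's composition on
the simplex; the unidentified fraction is carried as its own group but has
no conversion factor and therefore no MNI.

The statistic bootstrapped is the **unweighted mean of per-sack p_rm**
(equal sack weighting), which treats each sack as one draw from the
population of trafficked sacks; it deliberately differs from the pooled
mass-weighted composition, and both are computable (the pooled pathway via
`composition_shares`). Each group's p_rm vector is resampled independently
by default, mirroring a per-group bootstrap design; a joint mode (one sack
resample shared by all groups) is available for sensitivity analysis.

The 95% interval is bias-corrected and accelerated (BCa), implemented from
first principles because it is the estimator's core:

* bias correction `z0 = Φ⁻¹(#{θ*_b < θ̂}/B)`, with the proportion clipped
  to `[1/(2B), 1 − 1/(2B)]` (with a warning) when all replicates fall on
  one side;
* acceleration `a = Σ(θ̄₋ − θ₋ᵢ)³ / (6[Σ(θ̄₋ − θ₋ᵢ)²]^{3/2})` from the
  jackknife (leave-one-out means computed in closed form for the mean
  statistic);
* interval endpoints are linear-interpolation quantiles of the bootstrap
  distribution at the adjusted levels
  `Φ(z0 + (z0 + z_q)/(1 − a(z0 + z_q)))`.

Defaults: B = 1000 replicates, α = 0.05. A constant input returns the
degenerate interval [c, c] with a warning — a legitimate outcome for a
single-species sample, not an error. Results are exact functions of the
seed. The test-suite checks the implementation three ways: against an
independently written straight-line BCa sharing the resampling stream
(agreement to 1e-9), against scipy's BCa within Monte-Carlo tolerance, and
by interval coverage under the synthetic sack model.

## Mass-to-individual conversion

Group masses are `p_rm` (mean and CI bounds) × `m_cs`, with `m_cs` the
total confiscated scale mass of the curated database (default 190,404 kg,
configurable). MNI divides by the group's conversion factor CF (kg dried
scales + claws per individual). The aggregated *Smutsia* group (giant
ground and Temminck's pangolins, indistinguishable by scale inspection)
uses the arithmetic mean of the two species' factors. **CF uncertainty is
not propagated**: the CI bounds are the p_rm bounds pushed through the
deterministic equation with the mean CF. This matches how such tables are
conventionally reported, and CF sampling variation (n = 6–7 animals for the
*Phataginus* species) is acknowledged as a limitation instead. MNI values
are real-valued internally and rounded only for display.

The packaged conversion factors (0.177380, 0.198910, 2.934940
kg/individual) are **derived** fixtures — published per-group estimated
masses divided by published MNIs — because the field-measured values are
not published; the file is labelled accordingly. The packaged pooled
composition carries a documented internal inconsistency of the source
reporting (identified total 291 kg vs component sum 247.87 kg); the
composition function takes an explicit denominator so both arithmetics are
reproducible and the mismatch is surfaced, not guessed away.

## Synthetic data: what it emulates and what it does not

`SeizureSimConfig` draws per-record masses lognormally (base 10) per mode
with linear log10 trends (defaults: sea +0.15/yr from baseline 3.0, air
−0.08/yr from 2.4, land −0.05/yr from 2.6, sd 0.45), a mode mix of
air 0.25 / land 0.18 / sea 0.30 / warehouse 0.12 / unknown 0.15, routes of
1–4 countries with Nigeria forced onto every multi-stop route, and a small
mass-unknown fraction. These defaults reproduce the qualitative study
conditions — maritime shipments large and growing, air/land small and
declining — and are recoverable by the year×mode model at large n.

`SackSimConfig` defaults to the 67-sack design: sack masses uniform on
6–104 kg, single-species white-bellied sacks with probability 43/67,
single black-bellied 3/67, the remaining mixed sacks Dirichlet with mean
(0.09, 0.21, 0.67, 0.03) over (white-bellied, black-bellied, *Smutsia*,
unidentified) and concentration 3 — low concentration makes most mixed
sacks dominated by one or two groups, as observed when sorting. The
implied overall mean composition is (0.670, 0.111, 0.210, 0.009),
available in closed form via `mean_composition()` for coverage and
recovery experiments. The sampled sub-sample is a Beta(2, 8) fraction of
the sack (ten-handful scooping samples a minority of each sack).

Not emulated: within-sack spatial layering (scooping top and bottom is
assumed to mix the sack adequately), correlation between sack mass and
composition, inter-warehouse differences, reporting-effort changes over
time, and co-seized products. Passing tests on synthetic data therefore
demonstrate the *estimator's* statistical behaviour under the assumed
sampling design, not the representativeness of any real warehouse sample.

## Validation experiments

* **Coverage** — 1000 replicates of the 67-sack design; the nominal 95%
  BCa interval for the white-bellied mean p_rm is checked against the
  analytic generating mean, with acceptance band 95% ± 2%.
* **Bias** — signed error of the bootstrap mean against the generating
  mean, averaged over 200 seeds at 67 sacks (single-dataset error is
  dominated by ~0.05 sampling SE; averaging isolates bias).
* **Deduplication precision** — 100 corruption experiments: a synthetic
  database is reduced to a subset pairwise separated beyond a widened
  envelope (so within-tolerance jitter cannot bridge distinct true
  records), near-duplicates with jittered dates (≤5 d) and masses (≤5%)
  are injected with known ground truth, and every merge decision is scored.
  Precision is correct merges over all merges.

These problem sizes (1000 replicates, 100 seeds, 200 seeds, B = 1000) keep
the full validation run to a few seconds while leaving Monte-Carlo error
well inside the acceptance bands.

## Known limitations

* Curated totals depend on reporting and detection effort; the MNI is a
  floor for the *detected* trade only.
* The lowest-mass merge rule and the all-scales-shipped assumption both
  bias the MNI downward by design.
* CF uncertainty and geographic morphology differences are not propagated
  into the intervals.
* Dedup tolerances are module defaults, not measured reporting error; the
  linkage is transitive, so a chain of borderline matches can overmerge in
  dense report clusters.
* The pipeline treats the published interval of the final study year
  (truncated at September) by date filtering; partial-year masses are
  excluded from trend fits entirely.
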