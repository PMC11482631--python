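# Methods

## Problem and model

`feedsid` analyses marker-based ileal digestibility trials in pigs, the
standard assay behind the amino-acid values in feed-ingredient tables.
An inert, indigestible marker (titanium dioxide at 0.30% of the diet)
traces dry-matter disappearance: if the marker is `T_r` in the diet and
`T_d` in ileal digesta (both g/kg DM), a component at `AA_r` in the diet
and `AA_d` in digesta has apparent ileal digestibility

    AID = [1 − (AA_d · T_r) / (AA_r · T_d)] · 100  (%)

AID confounds undigested dietary protein with endogenous secretions.
Feeding a nitrogen-free diet isolates the basal endogenous flow

    IAA_end = AA_d · (T_r / T_d)   (g per kg DM intake)

and the standardized ileal digestibility corrects AID upward:

    SID = AID + 100 · IAA_end / AA_diet  (%)

where `AA_diet` is the **dietary** concentration of the component in
g/kg DM. Some sources write the SID denominator with the same symbol as
the digesta concentration; the dietary reading is the conventional one
and the only one consistent with the bundled reference tables (lot RSC1
crude protein: 70.29 + 100·21.24/194.93 = 81.19), so it is what
`compute_sid` implements. SID values are additive across ingredients,
which is why they — not AID — go into diet formulation.

Basis handling is explicit: ingredient and diet assays are air-dry
percentages, digesta assays are g/kg DM, and every quantity is converted
to g/kg DM (`value_airdry·10 / (DM/100)`) before entering a marker ratio.
No digestibility is clamped: AID may be negative, and SID exceeds 100
for proline, whose endogenous flow is large relative to its dietary
supply.

## Treatment summaries

Per-replicate values (one per pig-period) are compared across ingredient
lots by one-way ANOVA. The table reports per-lot means, a single pooled
SEM `sqrt(MSE/n)` with `n` the per-lot replicate count (the convention in
digestibility tables, which print one SEM per row), the F-test p-value,
and compact-letter groups from all-pairwise Tukey HSD at α = 0.05 (the
multiple-comparison procedure is a package choice; sources rarely name
theirs). Before summarising, values with |Z| > 3 within a lot×component
cell are excluded (the threshold is configurable; screening can be
disabled). Pig and period blocking terms are not fitted by default: with
6 replicates per diet spread over two squares and three periods the
one-way model is the defensible minimum, and the reference tables do not
state a blocking structure.

## Composition variability

Across-lot summaries use the sample (n−1) standard deviation;
`CV% = 100·SD/mean`. Components with CV strictly above 10% are flagged
as highly variable, the customary screen for "this ingredient needs
lot-specific values". The bundled dataset stores the published per-lot
rows and the published Mean/CV columns **separately**: for ether extract
and total glucosinolates (and, less dramatically, total phosphorus) the
printed CV cannot be recovered from the printed rows, and the package
deliberately reproduces rather than reconciles that inconsistency.

## Prediction equations

Candidate predictors are the proximate components (DM, GE, CP, EE, Ash,
CF, NDF, ADF, Ca, TP, TGS) plus the processing-temperature midpoint HT
(°C). Temperature and duration ranges ("130 ± 10 °C", "60~120 min") enter
as midpoints — the only symmetric reduction of a range to a scalar.

Selection is classical forward/backward stepwise OLS: the excluded
candidate with the smallest partial-F p-value enters while p ≤ 0.05, then
any included predictor with p ≥ 0.10 leaves; ties break by input order,
so the procedure is deterministic. Reported metrics are R², adjusted R²,
the residual standard error `sqrt(SSE/(n−p−1))` (printed as "RSD" in the
digestibility literature — it is not a mean-scaled quantity; the
reference equations' 2.88/4.39/4.69/8.04 reproduce under this
definition), and the regression F-test p-value. Both R² flavours are
emitted because published tables mix them (the reference HT equation
prints adjusted R² 0.51 where raw R² is 0.56, while its NDF/TGS rows
print raw R²).

With 10 lots, n = 10 is small; equations fitted on the bundled data are
descriptive of these lots, and the stepwise runs select single
predictors (NDF for SID_CP and SID_Lys, TGS for SID_Val).

## Synthetic trial generator

Pig-level assay data for such trials are effectively never published, so
validation uses a generative stand-in emulating the reference design:
22 cannulated pigs in two incomplete 11×3 Latin squares — 11 diets (one
40% inclusion test diet per lot in a protein-free maize-starch/sucrose
carrier, plus a nitrogen-free diet), 3 periods, each diet once per
square-period, 6 pig-period replicates per diet. The square construction
is cyclic with distinct random period offsets, then pig labels are
shuffled; every seed yields a balanced design (property-tested).

Generation inverts the estimation arithmetic. Defaults, chosen to match
the study conditions or typical physiology where unstated: marker 0.30%
air-dry; carrier DM 90.3% (the nitrogen-free diet's assayed DM); true
dry-matter digestibility 0.75 for test diets and 0.90 for the
starch/sucrose nitrogen-free diet; assay noise multiplicative lognormal
with unit mean and CV 5% (concentrations are positive and assay error is
roughly proportional), drawn per pig-period-component from a single seed
with a documented stream order. The digesta marker is
`T_d = T_r/(1 − DM digestibility)`; a component's undigested flow is
`diet_conc_dm·(1 − SID_true/100) + IAA_end_true` (floored at zero with a
warning if a supra-100 true SID with no endogenous flow implies a
negative flow), and its digesta concentration is the flow times
`T_d/T_r` times the noise factor. Carrier amino-acid contributions are
zero by construction (the trace cystine/proline seen in real nitrogen-free
diet assays are not modelled).

At noise CV 0 the full chain — AID, endogenous losses from the simulated
nitrogen-free replicates, SID — returns the configured truth to machine
precision; this identity is the simulator's calibration check and is
enforced in the tests.

What the generator does not emulate: feed-intake refusals, period or pig
effects, correlated assay errors within a sample, marker recovery below
100%, and any physiology of digestion. Passing recovery tests therefore
show the *estimator chain* is correct and unbiased under the stated
error model, not that real trials are free of those influences.

## Slope recovery and weighted inference

The recovery harness plants a linear truth (SID_Lys = 100 − 1.2·NDF),
simulates at 5% assay CV, re-estimates per-lot SID means and regresses
them on NDF. Because the noise is multiplicative on the undigested flow,
the variance of an estimated SID mean scales with the squared undigested
fraction `(1 − SID/100)²` — under the planted slope, exactly the high-NDF,
high-leverage lots are noisiest, and an unweighted OLS confidence interval
for the slope is anticonservative (≈85% empirical coverage at the nominal
95%). `fit_sid_slope` therefore weights the fit by `1/(1 − SID/100)²`,
the generative variance model, which restores nominal coverage (≈94–95%
over 400 seeds) while leaving the slope estimate unbiased. An unweighted
fit remains available via `weighted=False`.

## Numerical choices

- CSV floats are written at 17 significant digits so write/read
  round-trips are exact; report tables round half-up to 2 decimals
  (3 for regression coefficients).
- Missing CSV cells are surfaced as absent keys, never zero; the
  nitrogen-free diet simply lacks most amino-acid entries.
- Degenerate inputs raise early with context: zero marker or dietary
  concentrations (undefined ratios), DM outside (0, 100], fewer than two
  replicates per treatment group, rank-deficient design matrices (the
  collinear columns are named), `p_remove < p_enter` (cycling risk).
- A constant treatment cell passes the Z-screen untouched; identical
  groups (zero MSE) short-circuit the ANOVA to p = 1 and a shared letter.

## Problem sizes

Default validation sizes: the bundled 10-lot dataset for all
deterministic checks; 100 seeds for slope-recovery Monte Carlo and 1,000
seeds for design-balance property checks — sizes at which the Monte-Carlo
standard error of the recovered slope (<0.01) is an order of magnitude
below the 0.1 bias tolerance.

## Known limitations

- Letter displays assume non-significance is interval-like on the
  mean-sorted ordering; pathological Tukey patterns could in principle
  need non-contiguous letter sets, which the compact algorithm would
  approximate.
- The stepwise procedure inherits the usual caveats of stepwise
  inference (post-selection p-values are optimistic); it is implemented
  because it is the field's reporting convention, not as a recommendation.
- `sid_from_summary` applies the SID correction to already-averaged AID
  values; with rounded published inputs this reproduces published SID to
  about ±0.05.
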