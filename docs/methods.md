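# Methods

This note documents the models, conventions and design choices behind
`ldlkit`: what is computed, under which assumptions, and what the synthetic
cohort can and cannot tell you about real laboratory data.

## LDL-C estimation

All estimation is done in mg/dL. The canonical decomposition of total
cholesterol is

    TC = LDL-C + HDL-C + VLDL-C (+ Lp(a)-C),

with TC and HDL-C measured and VLDL-C estimated. Friedewald-type equations
estimate VLDL-C as TG/k (Friedewald: k = 5) and set
LDL-C = TC − HDL-C − TG/k. The Martin/Hopkins approach keeps this
structure but draws k from a 2-D lookup table indexed by TG and non-HDL-C
strata, reflecting that the true TG:VLDL-C ratio rises with TG and falls
with non-HDL-C. Linear equations regress LDL-C directly on (TC, HDL-C,
TG), some with an intercept, some omitting HDL-C entirely; quadratic
equations (Sampson, Saiedullah) add TG·non-HDL-C and TG² terms.

Conventions, applied uniformly:

* Equations published in mmol/L are converted once, at registry-build time
  (cholesterol ×38.67, TG ×88.57, intercepts ×38.67, with the induced
  rescaling of TG and interaction coefficients); the engine never branches
  on units.
* Estimates are returned at full floating-point precision, unrounded and
  unclipped; a negative estimate classifies into the lowest guideline
  category. No rounding happens before classification — only report
  writers round (to 0.1) for display.
* Fixed-ratio, linear and quadratic equations are by default valid for
  TG < 400 mg/dL (Sampson: < 800), matching how these equations are used
  clinically; an explicit `override_tg_domain` flag exists for research
  use. The standard factor table covers TG < 400, the extended table
  400–799, and a convenience composite switches between them at 400.
* All strata and category bins are half-open `[low, high)`: a value exactly
  on a boundary falls in the upper interval. A TG of exactly 400 therefore
  belongs to the extended table, and an LDL-C of exactly 70 to the
  70–99 mg/dL category.

### Provenance of coefficients and table cells

The equation registry and factor tables are plain-text assets
(`src/ldlkit/data/*.tsv`) with content digests recorded in the code and
verified by the test suite, so any transcription fix is deliberate and
visible. Coefficients were transcribed from the primary publications where
the published form is well established (Friedewald, DeLong, Hattori,
Anandaraja, Chen, de Cordova, Ahmadi, Puavilai, Vujovic, Sampson, the
Martin/Hopkins standard table); the remaining entries could not be checked
against their originals and are reconstructions consistent with each
equation's documented structure (family, intercept presence, variable
usage) and reported direction of bias. The extended-TG factor table's
cells are likewise a monotone reconstruction spanning the standard table's
top row and the published high-TG factors; its domain and monotonicity are
tested, its individual cells should not be treated as published values.
Users with access to the original publications can correct any cell or
coefficient in place — the invariant tests (3.1–9.5 range, strata tiling,
family structure) will catch accidental damage.

## Accuracy metrics

* **Concordance** — the proportion of paired estimated/reference LDL-C
  values falling in the same guideline category. Per-category proportions
  are stratified by the *reference* category by default (of the patients
  truly in a bin, how many were estimated into it); stratification by
  estimated category is available via `by="estimate"`, and reports name
  the orientation used. The overall proportion is identical under both.
* **Error summaries** — error = estimate − reference (underestimation
  negative); relative error = 100·error/reference, requiring strictly
  positive references. Quantiles use linear interpolation between order
  statistics (numpy's default); the rule is recorded in the summary
  because tiny fixtures are sensitive to it. "Within tolerance" uses a
  strict inequality, |error| < 5 mg/dL by default.
* **Upward reclassification** — among records with Friedewald estimate
  below the cutpoint (default 70 mg/dL) and TG in a chosen band, the
  fraction whose alternative estimate *and* reference are both ≥ the
  cutpoint. "≥" is used on both so the dichotomy partitions all values.
  Incorrect reclassifications (alternative ≥ cutpoint, reference below)
  are counted separately, as is the secondary ratio with the denominator
  restricted to reference-≥-cutpoint records; an empty denominator yields
  a flagged NaN result rather than an exception.

## Synthetic cohort generator

Lipid distributions in clinical populations are right-skewed and are
conventionally summarized by median (IQR), so each directly drawn quantity
(reference LDL-C, HDL-C, TG, Lp(a)-C, TG:VLDL-C ratio) follows a
log-normal law parameterized from a (median, q25, q75) triple:
location = ln median, scale = ln(q75/q25)/(2·z₀.₇₅). The median is then
exact by construction; the IQR is exact when the quantiles are
geometrically symmetric and otherwise the two one-sided scales are
averaged (the IQR *ratio* q75/q25 is always exact). Defaults: LDL-C
114 (90–141), HDL-C 51 (42–63), TG 114 (81–164), Lp(a)-C 6 (4–10) mg/dL,
ratio 5.0 (4.4–5.9).

The TG:VLDL-C ratio r is the scientifically load-bearing part. Its
log-location is shifted by

    0.3 · (ln TG − ln 114)  −  0.25 · (ln(LDL + Lp(a)) − median thereof),

and the result is clipped to [3, 13] (keeping VLDL-C physiologic; ~1% of
mass sits on the lower bound, shifting the sample median by ≈ +0.3%).
Both coupling strengths are read off the published adjustable-factor
table itself, which is an empirical map of ratio medians: the ln-factor
vs ln-TG slope of a mid non-HDL-C column is ≈ 0.3, and the ln-factor vs
ln-non-HDL slope of a mid TG row is ≈ −0.25. The non-HDL-direction
coupling uses LDL + Lp(a)-C (the non-VLDL, non-HDL cholesterol burden) to
avoid circularity with VLDL-C = TG/r, and is centred on its sample median
so the marginal ratio median stays at 5.0. With these couplings the
generator reproduces the two qualitative phenomena the metrics are
designed to detect: Friedewald's signed error grows negative with rising
TG at low LDL-C, and the adjustable-factor equation is more concordant
than the fixed divisor.

VLDL-C = TG/r and TC = LDL + HDL + VLDL + Lp(a)-C hold exactly per
record, so TC is emergent; its median comes out near 200 mg/dL — somewhat
above the sum of the component medians (193) because medians of sums of
right-skewed variables exceed sums of medians. Covariates: women 53.7%;
fasting 19.4% / non-fasting 11.9% / unknown 68.7%; age bands 1.2% (<18),
58.3% (18–59), 39.8% (≥60), 0.7% unreported, with ages uniform within
bands. Clinical labs (eGFR, hsCRP, TSH, A1c, fasting glucose) are drawn
from simple parametric laws whose parameters put the flag prevalences at
realistic population values (kidney disease 7.3%, inflammation 8.5%, TSH
< 0.5 at 0.8%, > 4.5 at 0.55%, diabetes union ≈ 4.4%); each lab is
present with probability 0.5 so missing-covariate accounting paths are
exercised. One `numpy.random.default_rng` stream seeded from the config
drives all draws in a fixed order; identical config + seed reproduces the
cohort exactly.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: joint lipid–comorbidity correlations (flags are
independent of lipids), fasting-dependent TG shifts, assay noise in TC and
HDL-C, and the true (unpublished) joint law of the TG:VLDL-C ratio. Because
the ratio couplings are modeling choices, cross-equation rankings on
synthetic cohorts are directional checks on the machinery, not estimates of
any equation's real-world accuracy; only the calibrated marginals
(medians, proportions) are quantitative targets.

## Numerical and engineering choices

* Category, TG-stratum and non-HDL-stratum lookups use binary search over
  edge arrays (`numpy.searchsorted`, right-closed side), which implements
  the half-open convention and makes the 100,000 × 23 evaluation run in
  seconds on one CPU. The problem sizes used in the shipped tests and the
  acceptance script (100,000 panels) were chosen to make Monte-Carlo error
  on medians ≈ 0.2% while keeping a full run under a minute.
* Validation is vectorised for cohorts and record-wise for single panels,
  with one rejection reason per record, assigned in a fixed precedence
  order (missing → negative → TC < HDL).
* The evaluation pipeline masks each equation to its TG domain (NaN
  outside) instead of raising, and reports per-stratum accounting so every
  input record is traceable to included / excluded-by-stratum /
  domain-excluded / rejected.
* The run-config hash in report provenance excludes the output directory,
  so re-running the same scientific configuration into a different folder
  yields byte-identical reports.

## Known limitations

* Seventeen of the 23 equations could not be verified against their
  original publications in this environment; see "Provenance" above.
* No mmol/L user-facing mode, no direct (homogeneous-assay) LDL-C
  emulation, no Lp(a)-corrected LDL estimation, and no Bland–Altman
  plotting (a figure hook would sit naturally on `ErrorSummary` but is not
  shipped).
* Only the 8-bin guideline scheme ships, though `CategoryScheme` is
  pluggable.
* The fasting-status stratum "unknown" is its own subgroup; there is no
  imputation.
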