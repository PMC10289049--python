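# ldlkit

Estimation of low-density lipoprotein cholesterol (LDL-C) from standard
lipid panels, and systematic evaluation of how accurate each estimate is.

Clinical laboratories rarely measure LDL-C directly — ultracentrifugation
(beta quantification or the vertical auto profile method) is too costly for
routine use — so LDL-C is computed from total cholesterol (TC), HDL-C and
triglycerides (TG). Dozens of closed-form equations have been proposed for
this since 1972, and choosing among them has real consequences: patients
near treatment thresholds (70 mg/dL in very-high-risk patients) can be
classified into the wrong guideline category by an inaccurate equation.
`ldlkit` is aimed at laboratory scientists, lipidologists and
epidemiologists who want to apply these equations to tabular lipid panels
and quantify their agreement with a reference measurement.

## What's inside

**23 published equations + 1 extended-TG variant**, shipped as data-driven
definitions in four structural families (all concentrations mg/dL):

* *fixed TG:VLDL-C ratio* — `LDL = TC − HDL − TG/k`; Friedewald (k = 5),
  DeLong, Puavilai, Vujovic, Ephraim, Ghasemi, Bauer;
* *linear* — `LDL = α·TC + β·HDL + γ·TG + δ`; Hattori, Anandaraja, Chen,
  de Cordova, Teerakanchana, Ahmadi, Rao, Dansethakul, Rasouli, Lee & Hu,
  Choi, Orejón, Molavi;
* *adjustable factor* — Martin/Hopkins: Friedewald's structure with the
  divisor replaced by a patient-specific factor from a TG × non-HDL-C
  lookup table (3.1–9.5 below TG 400 mg/dL; an extended table covers TG
  400–799);
* *quadratic* — Sampson (NIH equation 2, with TG·non-HDL and TG² terms) and
  Saiedullah.

**Accuracy machinery**: classification into the eight guideline categories
(<40, 40–54, 55–69, 70–99, 100–129, 130–159, 160–189, ≥190 mg/dL),
concordance between estimated and reference categories (overall and per
category, stratified by either reference or estimated category), median
(IQR) signed and relative error, the fraction of patients within a 5 mg/dL
tolerance, and confirmed upward reclassification across the 70 mg/dL
cutpoint when switching from Friedewald to an alternative. Named subgroup
filters reproduce the usual stratified analyses (age bands, sex, fasting
status, TG bands, ASCVD, hypertension, kidney disease, diabetes,
inflammation, thyroid dysfunction).

**A calibrated synthetic-cohort generator**: log-normal lipid marginals
parameterized by median/IQR (defaults: LDL-C 114 (90–141), HDL-C 51
(42–63), TG 114 (81–164), Lp(a)-C 6 (4–10) mg/dL), a heterogeneous
TG:VLDL-C ratio with median 5.0 coupled to TG and to the non-VLDL
cholesterol burden, an exact accounting identity
`TC = LDL + HDL + VLDL + Lp(a)-C`, and covariates at realistic proportions
(53.7% women, …). It exists so the entire pipeline is testable and
demonstrable without access to proprietary clinical-laboratory data; see
`docs/methods.md` for what it does and does not emulate.

## Worked example

```bash
ldlkit simulate --out demo.csv --n 20000 --seed 42
ldlkit evaluate --input demo.csv --outdir reports \
    --equations friedewald,martin_hopkins,sampson,chen \
    --strata all,tg_lt_400,tg_150_399
```

`reports/category_concordance.csv` begins:

```
stratum,equation,orientation,n,overall_pct,cat_<40_pct,cat_40-54_pct,...
all,friedewald,reference,19848,71.1,46.2,48.5,50.8,69.1,72.1,71.7,68.6,98.9
all,martin_hopkins,reference,19848,71.7,53.8,42.4,42.7,67.4,73.5,75.3,73.4,98.9
```

Each row is one equation in one stratum: `n` panels had a usable estimate
and reference, `overall_pct` is the percentage of panels whose estimated
LDL-C fell in the same guideline category as the reference, and the
`cat_*` columns break that down by reference category. Here the
adjustable-factor equation classifies 71.7% of panels correctly against
71.1% for Friedewald, with the largest gain in the lowest (<40 mg/dL)
category — the region where Friedewald's fixed divisor is known to be
weakest. `reports/reclassification.csv` shows the clinical consequence:

```
equation,tg_lo,tg_hi,cutpoint,denominator,correct,incorrect,proportion_pct
martin_hopkins,0.0,400.0,70.0,1215,240,235,19.8
martin_hopkins,150.0,400.0,70.0,564,213,167,37.8
```

Of the 1,215 panels with Friedewald LDL-C < 70 mg/dL, 19.8% are moved to
≥ 70 mg/dL by Martin/Hopkins *and* confirmed correct by the reference
value — rising to 37.8% among panels with TG 150–399 mg/dL, where the fixed
TG/5 divisor underestimates most.

The same analysis is available as a library:

```python
from ldlkit import generate_cohort, estimate_ldl, concordance

cohort = generate_cohort(n=20_000, seed=42)
sub = cohort[cohort.tg < 400]
est = estimate_ldl(sub, "martin_hopkins")
print(concordance(est, sub["ldl_ref"]).overall)  # 0.717...
```

All numbers above are what the code prints for these seeds; being
synthetic-cohort results they illustrate the machinery and the direction of
the effects, not any real population's accuracy figures.

## Layout

* `src/ldlkit/registry.py`, `factor_table.py` — equation definitions and the
  estimation engine; `data/` holds the plain-text equation and factor-table
  assets (with recorded content digests).
* `classification.py`, `error_metrics.py`, `reclassification.py`,
  `strata.py` — the accuracy metrics and subgroup filters.
* `synth.py` — the synthetic cohort generator; `io.py`, `pipeline.py`,
  `cli.py` — file I/O, the evaluation pipeline and the `ldlkit` command.
* `docs/methods.md` — model assumptions, parameter choices, numerical
  conventions and known limitations.
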