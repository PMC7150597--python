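# afcost

Incidence-based cost-of-illness analysis for atrial fibrillation (AF), built
for health economists working with linked administrative health records.  The
package covers the full analysis chain:

1. **Cohort construction** — clean hospital episode records, identify the
   incident AF cohort (ICD-10 code I48 in any of six diagnostic positions,
   with a 5-year lookback so only first events count), and assemble a
   patient-year follow-up panel over five years, keeping the year containing
   death and dropping later years.
2. **Sectoral costing** — chain episodes into continuous inpatient stays
   (CIS) and price them per spell with a per-specialty maximum rule; price
   outpatient attendances by (specialty, consultant- vs nurse-led clinic);
   compute prescription costs as (item price ÷ pack size) × (quantity ×
   instalments); price care-home residency per day at the weekly charge ÷ 7.
3. **Two-part cost model** — because annual healthcare costs mix a mass of
   zeros with a right-skewed positive distribution, the mean annual cost per
   patient is estimated as

   E[y | x] = Φ(xβ) · exp(xγ)

   where part one is a **probit** for the probability of any resource use and
   part two a **gamma GLM with log link** for cost conditional on use.  The
   second part is compared against OLS and log-OLS by AIC and checked with a
   four-test battery (modified Park, Pregibon link, modified Hosmer–Lemeshow,
   residual–fitted correlation).  Uncertainty comes from a nonparametric
   bootstrap resampling patients; alive/dead sensitivity refits drop the
   mortality terms.
4. **Synthetic linked data** — the real NHS Scotland linked extracts are
   confidential, so a first-class generator produces the five record streams
   (episodes, outpatient, prescribing, care home, deaths) from a known
   ground-truth (β, γ, gamma shape, sector split), letting every stage be
   verified against a closed-form oracle.

The model adjusts for age band, sex, admission year, deprivation quintile
(SIMD), eightfold urban–rural class, the 14 Scottish health boards, a 3-level
Charlson comorbidity count and 5-year vital status, plus age×comorbidity and
mortality×SIMD interactions.

## Worked example

```bash
python examples/full_pipeline.py
```

generates records for 1,000 synthetic patients, runs the whole pipeline and
prints:

```
mean annual cost per patient: £2322.42
  95% bootstrap CI: £2212.51 to £2452.31 (B=200, resampling patients)
  alive at 5 years: £1933.46
  dead at 5 years: £4364.99

second-part family selection: gamma_glm (lowest AIC among gamma GLM / OLS / log-OLS)
```

The headline number is the recycled prediction — Φ(xβ̂)·exp(xγ̂) averaged over
the sample's covariates — of the mean annual cost per patient with AF.
Decedents cost more per year than survivors (their fitted use probability and
conditional costs are higher), and the gamma/log GLM beating OLS and log-OLS
on AIC is exactly what should happen on skewed cost data.  The stratified
table printed below those lines gives per-sector means and percentage shares
by sex; on the default synthetic configuration inpatient care carries ~79% of
total costs.

Other examples: `examples/simulate_records.py` (the record streams and their
ground truth), `examples/costing_walkthrough.py` (the costing arithmetic on
hand-checkable cases), `examples/fit_two_part_model.py` (model fit, AIC
comparison, diagnostics, oracle check).

A thin CLI wraps the same pipeline:

```bash
afcost all --seed 7 --outdir my_run          # full pipeline
afcost simulate --seed 7 --outdir my_run     # record streams only
afcost fit --config my_config.yaml           # with a YAML configuration
```

## Layout

```
src/afcost/
  synthetic.py    # ground-truth DGP and linked-record generator
  cohort.py       # cleaning, incident identification, covariates, panel
  costing.py      # tariffs, CIS chaining, sector costing, aggregation
  design.py       # reference-coded design matrix shared by DGP and model
  twopart.py      # probit + gamma GLM, AIC comparators, bootstrap, sensitivity
  diagnostics.py  # modified Park / Pregibon / Hosmer-Lemeshow / correlation
  reporting.py    # cohort summaries, stratified cost tables, shares
  pipeline.py     # end-to-end orchestration from a YAML config
  cli.py          # click CLI (simulate / cohort / cost / fit / report / all)
```

The published study's exact £ figures require the confidential NHS Scotland
linked cohort and are not reproducible here; what the package reproduces is
the published tables' internal arithmetic and, on synthetic data, the
statistical behaviour the method promises.  See `docs/methods.md` for the
model, the generator's assumptions and known limitations.
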