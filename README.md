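# polypen

Polygenic background modifies the penetrance of rare monogenic risk
variants: a carrier of a familial-hypercholesterolemia, hereditary
breast/ovarian cancer, or Lynch-syndrome variant can face anywhere from
near-population to several-fold risk depending on where they fall in the
polygenic score distribution. `polypen` is a Python toolkit for running
that joint analysis end to end — for statistical geneticists and
epidemiologists who want the estimators, and for methodologists who want
them validated against synthetic cohorts with known truth.

## What it computes

- **Score engine** — raw scores `PS_i = Σ_v w_v d_iv` from dosages and
  PLINK-style weight files; ancestry correction by OLS residualization on
  principal components (`PS ~ PC1 + … + PC4`); standardization and integer
  percentiles 1–100; sensitivity surgeries (drop variants within 1 Mb of
  given gene footprints; residualize one score on another).
- **Variant screen** — consequence / subpopulation-allele-frequency
  (> 0.005) / region-quality filters on an annotated variant table;
  per-individual carrier status from surviving P/LP variants; per-gene
  logistic associations with a Firth fallback for sparse cells.
- **Association models** — six-level carrier × score-stratum odds ratios
  (reference: noncarriers, middle three quintiles); OR per score SD within
  carriers and noncarriers; Wald test of the score × carrier product term;
  percentile-wise predicted OR curves referenced to noncarriers at the
  median score; linearity LRT (linear vs cubic) and 20-bin calibration.
- **Penetrance** — Cox model with age as the time-scale and Breslow
  baseline; absolute risk `F(75) = 1 − exp(−H0(75) e^{x'β})` across score
  percentiles for carriers and noncarriers, with delta-method CIs.
- **Retrospective power** — exact conditional-Bernoulli phenotype
  simulation with the case total fixed; Monte-Carlo power of the
  interaction test; detectable carrier-OR bounds at 80% power by
  noise-aware bisection.
- **Synthetic cohorts** — Balding–Nichols ancestry structure, rare
  single-variant carriers, logistic prevalence, Weibull onset ages, and
  case-control sampling, all with retained ground truth.

See `docs/methods.md` for the models, assumptions, and numerical choices.

## Worked example

Simulate a cohort in which carriers (0.5% of individuals) have a threefold
odds ratio and the score carries OR 1.7 per SD, then run the full analysis:

```python
from polypen import PipelineConfig, run_pipeline
from polypen.simulate import SimConfig

cfg = PipelineConfig(sim=SimConfig(n_individuals=8000, n_score_variants=60,
                                   seed=3), seed=3)
res = run_pipeline(cfg)
print(round(res.or_per_sd["noncarrier"]["or_per_sd"], 2))   # 1.64
print(round(res.interaction["p"], 2))                       # 0.11
f = res.penetrance_curve
print(round(f.query("not carrier and percentile == 1")["F"].iloc[0], 3))  # 0.029
print(round(f.query("carrier and percentile == 100")["F"].iloc[0], 3))    # 0.67
```

The noncarrier OR per SD (1.64) recovers the generating 1.7 within
sampling error; the interaction p-value is non-significant, as it should
be for an additive generator; and the age-75 penetrance spans 2.9% for
noncarriers at the lowest score percentile to 67% for carriers at the
highest — the risk-gradient pattern the analysis is designed to expose.

The detectable-effect-size machinery runs from the CLI, e.g.:

```
polypen power --n 12852 --n-cases 6432 --n-carriers 56 \
    --noncarrier-or 1.74 --seed 1 --out pw/
```

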