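# mmdnet

Multiple micronutrient deficiency (MMD) — the co-existence of more than one
of anemia, iron, zinc, or vitamin-A deficiency — affects roughly half of
children reaching their second birthday in many low- and middle-income
settings. Understanding which exposures drive it (diet, water/sanitation
and hygiene, enteric infections, environmental enteric dysfunction) requires
multi-country cohort data that are rarely redistributable. `mmdnet` is a
tested re-implementation of that analysis pipeline for epidemiologists and
biostatisticians, built around a calibrated synthetic cohort so every stage
is exercisable, reproducible, and verifiable without any restricted data.

The package provides:

- **`mmdnet.cohort`** — a seeded generator of seven-site longitudinal
  cohorts (child, monthly diet, monthly stool, 24-month blood, morbidity
  tables). Site marginals are log-normal, calibrated to published
  median/IQR summaries; structural effects are planted on within-site
  z-scores of the derived analysis variables; the MMD outcome is generated
  as a Bernoulli-logit in its parents and realized as blood-biomarker
  values through a one-factor Gaussian copula, so that threshold
  classification reproduces the planted outcome while biomarker marginals
  stay calibrated.
- **`mmdnet.status`** — deficiency classification at 24 months: anemia
  (hemoglobin < 11.0 g/dL), iron deficiency (ferritin < 12.0 µg/L **and**
  TfR > 8.3 mg/L), zinc (< 9.9 µmol/L), vitamin A (retinol < 0.70 µmol/L);
  MMD ⇔ at least two indicators.
- **`mmdnet.exposures`** — longitudinal derivation over months 9–24:
  `log_window_mean` (= ln of the geometric mean) for stool biomarkers,
  mean daily intakes, per-sample enteropathogen scores, breastfeeding
  percentage, diarrheal incidence per 100 child-months, and the
  complete-case filter.
- **`mmdnet.glmm`** — logistic regression with a random country intercept
  (maximum likelihood by adaptive Gauss–Hermite quadrature, verified
  against lme4), the p < 0.20 bivariate entry screen, and Spearman/VIF
  collinearity gatekeeping.
- **`mmdnet.network`** — a hybrid Bayesian network (linear-Gaussian nodes,
  a Bernoulli-logit MMD sink) fit by an exact Gibbs sampler: conjugate
  normal/inverse-gamma sweeps for linear nodes and Polya-Gamma
  augmentation for the logistic node (the PG(1, z) sampler is implemented
  in-repo with the alternating-series rejection method). Arcs are retained
  when the central 95% credibility interval of their coefficient excludes
  zero.
- **`mmdnet.pipeline` / `mmdnet.cli`** — an orchestrated
  simulate → derive → screen → fit pipeline with checksummed manifests and
  a `mmdnet` command-line entry point.

## Model

For continuous node $y_j$ with parents $\mathrm{pa}(j)$ (all within-site
z-scores):

$$y_j = \alpha_j + \sum_{k \in \mathrm{pa}(j)} \beta_{kj}\, y_k + \varepsilon_j,
\qquad \varepsilon_j \sim \mathcal N(0, \sigma_j^2)$$

and for the binary sink, with per-site intercepts $\alpha_{s}$:

$$\mathrm{logit}\, P(\mathrm{MMD}_i = 1) = \alpha_{s(i)} +
\sum_{k} \beta_k x_{ik}.$$

Priors are weakly informative ($\beta \sim \mathcal N(0, 10^2)$,
$\sigma^2 \sim \mathrm{InvGamma}(0.01, 0.01)$). Because the DAG factorizes
and the data are complete-case, the node posteriors are independent; they
are sampled in one joint Gibbs sweep per iteration. Coefficients on arcs
into MMD are log odds ratios per SD of the (log-scale) exposure, or female
vs male for sex.

## Worked example

```python
from mmdnet import (default_truth, generate_cohort, apply_missingness,
                    assemble_analysis_table, mmd_prevalence,
                    default_network, fit_network, select_arcs, SamplerSettings)

truth = default_truth()                                # calibrated study conditions
cohort = generate_cohort(truth, scale=1.0, seed=3, attrition=True)
cohort.blood_table = apply_missingness(cohort.blood_table, truth, seed=4)
table, dropped = assemble_analysis_table(cohort)       # complete-case analysis table

per_site, pooled = mmd_prevalence(table)
spec = default_network()
posterior = fit_network(spec, table,
                        SamplerSettings(chains=4, iterations=2000, warmup=1000, seed=3))
edges = {e.arc: e for e in select_arcs(posterior, spec)}
```

printing the headline quantities gives:

```
analytic sample: 1093 children (201 dropped for missing blood values)
pooled MMD prevalence: 45.7%
  BGD: 37.9%, BRF: 6.2%, INV: 67.7%, NPB: 37.4%, PEL: 18.7%, PKN: 88.7%, TZH: 45.4%
    female -> mmd      OR 0.72 (95% CrI 0.54, 0.97)  retained=True
 vitamin_c -> mmd      OR 0.73 (95% CrI 0.62, 0.84)  retained=True
   log_mpo -> mmd      OR 1.21 (95% CrI 1.04, 1.40)  retained=True
   protein -> log_mpo  beta -0.50 (95% CrI -0.55, -0.45)  retained=True
```

The 1093/201 split reproduces the study's complete-case accounting exactly
(missingness counts are planted per site and drawn disjointly). Prevalences
are the classification of each child's simulated blood panel. The network
recovers the planted effects — protective female sex and vitamin-C intake,
harmful fecal myeloperoxidase (MPO, the intestinal-inflammation biomarker)
— within single-study sampling noise at this n; recovery is exact in
expectation and tightens at larger `scale`.

The same steps run from the shell:

```bash
mmdnet simulate --scale 1.0 --seed 3 --out run/cohort
mmdnet derive   --in run/cohort --out run/analysis.csv
mmdnet screen   --in run/analysis.csv --out run/screen.json
mmdnet fit-bn   --in run/analysis.csv --chains 4 --iters 5000 --seed 3 --out run/fit
```

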