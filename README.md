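# gripmir

Two-part ("hurdle") mixed-model association of censored qPCR miRNA panels
with hand grip strength, with permutation calibration, FDR screening,
miRNA–mRNA coexpression and gene-set enrichment — exercised end-to-end on a
synthetic family cohort generator.

## Who this is for

Epidemiologists and biostatisticians analysing whole-blood miRNA panels in
community cohorts. qPCR quantifies expression as a quantification cycle
(Cq, lower = more expression) and cannot call expression beyond a detection
limit (27 cycles here), so many miRNAs are undetected in much of the sample.
Dropping the undetected majority wastes the detection signal; imputing it
biases the quantitative model. `gripmir` implements the standard remedy —
model the detection indicator and the detected values separately, then
combine — for a grip-strength phenotype in family-clustered data.

## The statistic

For each miRNA, with X = 1 if Cq > 27 (undetected) and 0 otherwise, two
linear mixed models with a family random intercept are fitted:

    model 1 (everyone assayed):      grip ~ X  + sex + age + height + BMI + technical covariates
    model 2 (detected subset, X=0):  grip ~ Cq + sex + age + height + BMI + technical covariates

and routed by the detected fraction *d*: miRNAs detected in fewer than 5% of
the cohort are ineligible; *d* < 10% uses model 1 alone; *d* ≥ 90% uses
model 2 alone; in between, the two Wald statistics W = (β/SE)² are summed
and referred to χ² with 2 df (the "adaptive p-value"). q-values are
Benjamini–Hochberg across eligible miRNAs. Since higher Cq means lower
expression, **negative β means expression and grip rise together**. A
permutation scheme that reorders the clinical block (grip, covariates,
family ID) against the miRNA matrix and reruns everything provides an
empirical type-I-error check. Downstream, genes coexpressed with the top
miRNAs (mixed-model fits, FDR < 0.05) are tested for over-representation in
gene sets with a one-sided hypergeometric test and reported with the ratio
of enrichment (observed / expected overlap).

Because real cohorts of this kind are access-restricted, the package ships a
calibrated generator (`gripmir.simulate`) producing family-clustered
covariates, censored Cq panels with planted effects on the kg-per-Cq scale,
grip strength with a sex-specific quadratic age decline, and
miRNA-correlated mRNA blocks — every stage is testable offline. See
`docs/methods.md` for the model, calibration and limitations.

## Worked example

Run the demo pipeline (simulate → associate → permute → coexpress → enrich
→ report; ~2 minutes on one core):

```
gripmir run --out runs/demo --seed 11
```

`runs/demo/report.md` then contains, among other sections, the association
summary:

> Among 37 miRNAs interrogated, 4 (11%) had FDR q value < 0.1, 4 (11%) had
> FDR q value < 0.05, 2 (5%) had FDR q value < 0.01, 2 (5%) had FDR q value
> < 0.001.

| mirna | n | beta_cont | se_cont | p_cont | branch | adaptive_p | fdr_q |
| --- | --- | --- | --- | --- | --- | --- | --- |
| miR-sim-0022 | 2000 | -0.3464 | 0.08168 | 2.221e-05 | continuous_only | 2.221e-05 | 0.0005494 |
| miR-sim-0032 | 2000 | -0.3181 | 0.07617 | 2.97e-05 | continuous_only | 2.97e-05 | 0.0005494 |
| miR-sim-0021 | 2000 | -0.2684 | 0.08373 | 0.001345 | continuous_only | 0.001345 | 0.01659 |
| miR-sim-0030 | 2000 | -0.2201 | 0.07523 | 0.003445 | continuous_only | 0.003445 | 0.03187 |

Reading the first row: miR-sim-0022 was assayed in all 2000 participants and
detected in ≥ 90% of them, so only the continuous model is used; each 1-cycle
increase in Cq (i.e. *lower* expression) predicts 0.35 kg *less* grip
strength (SE 0.08) — the generator planted a negative kg/Cq effect there,
and three of the four discoveries are planted effects of the largest
magnitude. The permutation section of the same report shows the calibration
on 100 replicates:

> 100 permutation replicates, 3700 pooled null tests: fraction of adaptive
> p < 0.05 = 0.0508, < 0.01 = 0.0103; KS vs Uniform(0,1) = 0.0082 (p = 0.964).

The individual stages are also exposed (`gripmir simulate|associate|permute|
coexpress|enrich|report`, see `--help`), and everything is callable as a
library:

```python
from gripmir import SimulationParams, simulate_participants, simulate_cq_matrix, \
    simulate_grip, associate_all, results_to_frame

params = SimulationParams(seed=1)           # full-scale defaults: n=5668, 299 miRNAs
cohort = simulate_participants(params)
cq = simulate_cq_matrix(cohort, params)
cohort = simulate_grip(cohort, cq, params)
results = associate_all(cohort, cq,
                        ["sex", "age", "height_in", "bmi",
                         "rna_conc", "ratio_260_280", "rna_quality"])
print(results_to_frame(results).nsmallest(5, "fdr_q"))
```

## Layout

| path | contents |
|---|---|
| `src/gripmir/simulate.py` | synthetic cohort / Cq / mRNA / fixture generators |
| `src/gripmir/lmm.py` | profiled-REML random-intercept solver |
| `src/gripmir/association.py` | indicator, branching, adaptive combination, PLS cell-count imputation |
| `src/gripmir/multiple_testing.py` | BH q-values, threshold summaries, permutation calibration |
| `src/gripmir/coexpression.py` | pairwise coexpression, overlaps, hypergeometric enrichment |
| `src/gripmir/pipeline.py`, `cli.py`, `report.py` | orchestration, CLI, Markdown reporting |
| `docs/methods.md` | model, generator calibration, numerical choices, limitations |
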