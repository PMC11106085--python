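# comodbn

Dynamic Bayesian network modelling of the onset and interaction of
cardio-metabolic comorbidities — type 2 diabetes, hypertension and heart
problems — in longitudinal ageing-panel data, together with probabilistic
follow-up simulation, survival-based validation and risk stratification.

## Who this is for

Epidemiologists and biostatisticians working with panel studies of ageing
(interview waves roughly every two years, mixed categorical / ordinal /
continuous variables, design missingness in biomarkers, and absorbing
disease-onset outcomes).  The package reimplements a complete analysis
pipeline of this kind as a tested, reusable library.  Because the panel
study it targets (the English Longitudinal Study of Ageing, ELSA) is
registration-restricted, a synthetic-data generator with a **known**
ground-truth network stands in for the real data: every stage of the
pipeline can be validated by recovering what generated it.

## The model

The joint process is a discrete two-slice dynamic Bayesian network.  Each
dynamic variable X appears at slices *t−1* and *t*; the distribution of a
slice-*t* child is a conditional probability table (CPT)
P(X_t | Pa(X_t)), with parents drawn from slice *t−1*, the static
variables, and the time-since-baseline (TSB) node.  A six-layer ordering
constrains the admissible edges:

| layer | nodes | may take parents from |
|---|---|---|
| 1 | sex, baseline age | — |
| 2 | education | 1 |
| 3 | dynamic variables at *t−1* | — |
| 4 | dynamic variables at *t* | 1, 2, 3, 6 |
| 5 | survival (death within 4 years) | 1, 2, 3, 4, 6 |
| 6 | TSB | — |

Continuous variables are quantised at clinical thresholds (e.g. BMI at
25 / 30 kg/m², fasting glucose at 5.6 mmol/l), half-open `[a, b)`
intervals.  Structure is learned by a hybrid scheme: a G² conditional-
independence skeleton restricts candidate parents, greedy hill-climbing
maximises the BIC

&nbsp;&nbsp;&nbsp;&nbsp;BIC = Σ_families [ log L̂ − ½ (r_child − 1) · q_parents · ln N ],

and a subject-wise k-fold consensus (edges kept when present in ≥ 80% of
fold networks) seeds the final search.  CPTs are posterior means under a
symmetric Dirichlet prior.  The learned network then acts as a simulator:
from a complete baseline record, 2-year steps are sampled forward until
death or the horizon, outcomes clamped once entered ("experienced until
now" is absorbing).  Calibration is checked by log-rank comparison of
observed and simulated Kaplan–Meier curves; discrimination by
time-dependent AU-ROC / AUC-PR of the per-subject risk score
1 − (area under the subject's repetition-wise KM curve)/horizon, averaged
over the 2-year grid (iAU-ROC, iAUC-PR).  Finally, cohorts defined by the
baseline levels of an outcome's parents are simulated, their KM curves
min–max normalised and clustered (Ward, Euclidean), and the number of risk
groups chosen by majority vote of five cluster-validity indices over
k = 2…6.

## Worked example

```python
import comodbn as cb

# ground-truth network and an ELSA-shaped panel sampled from it
truth = cb.make_ground_truth_dbn(n_dynamic=10, n_static=3, seed=0)
panel = cb.apply_missingness(cb.sample_panel(truth, 2000, 6, seed=1),
                             cb.MissingnessPattern(seed=2))

# align waves, filter subjects, impute, quantise, 75/25 split
disc, imp, stats = cb.preprocess_pipeline(panel, seed=3)
print(f"train {disc.train.n_subjects} / test {disc.test.n_subjects} subjects")

learned = cb.learn_dbn(disc.train, cb.LearnConfig(k_folds=10, seed=4),
                       imputed=imp.train)
tp = len(truth.dag.edges & learned.dag.edges)
print(f"learned {len(learned.dag)} edges "
      f"(precision {tp/len(learned.dag):.2f}, recall {tp/len(truth.dag.edges):.2f} vs truth)")

res = cb.evaluate_model(learned, disc.test,
                        cb.EvalConfig(n_reps=25, horizon_years=10.0, seed=5))
for outcome, m in res.metrics.items():
    p = res.curves[outcome][3]
    print(f"{outcome:15s} iAU-ROC {m.iauroc:.3f}  iAUC-PR {m.iaucpr:.3f}  log-rank p {p:.2f}")
```

prints

```
train 1454 / test 484 subjects
learned 27 edges (precision 0.93, recall 1.00 vs truth)
Diabetes        iAU-ROC 0.709  iAUC-PR 0.459  log-rank p 0.61
Hypertension    iAU-ROC 0.711  iAUC-PR 0.794  log-rank p 0.80
Heart problems  iAU-ROC 0.742  iAUC-PR 0.691  log-rank p 0.14
Survival        iAU-ROC 0.686  iAUC-PR 0.167  log-rank p 0.51
```

The learned network recovers the generating structure almost exactly; all
log-rank p-values sit above 0.05, i.e. simulated and observed onset curves
are statistically indistinguishable (the model is well calibrated), and
every iAU-ROC is clearly above the 0.5 chance level.

The same pipeline is available from a shell:

```bash
comodbn simulate-data --n-subjects 2000 --seed 1 --out raw.csv --truth truth.json
comodbn preprocess --in raw.csv --catalog catalog.yaml --seed 3 \
        --out-train train.csv --out-test test.csv
comodbn learn --train train.csv --catalog catalog.yaml --k-folds 10 --out model.json
comodbn evaluate --model model.json --test test.csv --out metrics.csv
comodbn stratify --model model.json --panel train.csv --outcome Diabetes --out strat.json
```

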