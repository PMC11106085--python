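# Methods

This note documents the model, the conventions the implementation commits
to where several readings were possible, the synthetic-data generator and
what it does and does not emulate, and the problem sizes the test suite and
the reproduction script run at.

## The two-slice DBN

The process over interview waves is modelled as a discrete two-slice
dynamic Bayesian network.  Nodes are variables-at-a-slice: every dynamic
variable appears at *t−1* (layer 3, root) and at *t* (layer 4); static
demographics occupy layers 1–2; survival ("will death occur within four
years of this interview?") is layer 5; the quantised time since baseline
(TSB, cut at 4 and 8 years) is layer 6, also a root.  A child in layer 2
may take parents only from layer 1; layer 4 from {1, 2, 3, 6}; layer 5 from
{1, 2, 3, 4, 6}.  This matrix makes every admissible graph acyclic by
construction and fixes every edge's direction, so the hill-climb move set
is {add, delete}: reversal is meaningless across fixed slices.

Time is exactly two years per wave step.  Real panels have waves roughly
two years apart; the model commits to the idealised spacing, which is also
what the forward simulation uses.

### Structure learning

1. **Skeleton.** For each child, candidate parents are screened with the G²
   likelihood-ratio test of conditional independence (degrees of freedom
   (r_x−1)(r_y−1) per conditioning configuration, counting only
   configurations actually observed).  Candidates are admitted greedily by
   maximal minimum association, the minimum taken over conditioning subsets
   of the current candidate set up to `max_cond` (default 2) members, and a
   shrink pass removes members that turn independent given a subset of the
   others.  This is a max-min parents-children surrogate: the exact variant
   used by any particular legacy implementation is unspecified, and no
   claim of equivalence is made.  Default α = 0.05.
2. **Score.** Families are scored with the BIC under natural log,
   log L̂ − ½ (r_child−1) q_parents ln N, where q_parents is the full
   product of parent cardinalities and N the number of complete instances
   for the family.  The score is decomposable; family scores are cached.
3. **Search.** Greedy hill-climbing over skeleton-permitted additions and
   arbitrary deletions, deterministic tie-break on lexicographic
   (child, parent).  On 3–4-node problems the search provably attains the
   exhaustive per-family optimum (tested), because the layer matrix makes
   family optimisations independent.
4. **Consensus.** The training subjects are split into k folds (k = 50 by
   default; the desk-scale experiments use k = 10); each fold's network is
   learned on the other k−1 folds from the empty graph; edges present in at
   least ⌈0.8 k⌉ fold networks form the consensus graph (any residual cycle
   — impossible under the layer matrix, but checked defensively — would be
   broken by dropping minimum-count edges).  The consensus seeds a final
   hill-climb on the full training set.
5. **Parameters.** CPT rows are posterior means under a symmetric Dirichlet
   prior, (count + c)/(total + c·r) with pseudo-count c = 1 by default; an
   unobserved parent configuration yields the uniform row.  The prior is
   configurable since only "maximum a posteriori" is specified by the
   analysis this reimplements, not the prior itself.

Transition instances are pairs of consecutive waves; static variables are
repeated, survival and TSB are taken at the later wave.  Missing outcome
values (the only columns never imputed) exclude an instance from families
that use them, not from the table.

## Preprocessing

* **Alignment.** Each subject keeps the longest run of consecutive waves
  starting at their first participated wave ("consecutive visits" read
  strictly); the first kept wave is baseline 0.
* **Filters.** (i) ≥ 2 visits; (ii) baseline age strictly greater than 40;
  (iii) at least one biomarker observed at least once.
* **Imputation** is intra-subject by design (cross-subject methods were
  deliberately rejected for this kind of data): interior gaps of dynamic
  continuous series are linearly interpolated on the time axis; leading and
  trailing gaps use next/last-observation propagation; categorical and
  ordinal dynamic series use propagation only — interpolating an ordinal
  score would invent data, so ADL/IADL and drink counts are propagated even
  though they are quantised like continuous variables; a variable never
  observed for a subject, and any missing static variable, falls back to
  the training-population median or mode.  Outcomes, survival, sex,
  baseline age and TSB are never imputed.
* **Quantisation.** Thresholds belong to the upper level (half-open
  [a, b)), matching the "< a", "[a, b[" convention of the published cut
  tables.  Baseline-age tertile cuts (55, 65) are kept fixed in the
  packaged catalog; re-estimation on new data is possible by supplying a
  different `QuantizationScheme`.
* **Split.** Subject-level 75/25, stratified by baseline-age level, seeded;
  strata with fewer than two subjects go wholly to train with a warning.
  Balance is checked with Kruskal-Wallis (continuous/ordinal) and χ²
  (categorical, asymptotic, no continuity correction) on baseline
  distributions.  The split precedes imputation so the fallback statistics
  are fitted on training subjects only.

## Simulation

From a complete baseline record the simulator advances in 2-year steps:
slice-t variables are sampled from their CPTs given the previous wave, the
statics and the deterministically advanced TSB level; survival is sampled
last (it may condition on slice-t values).  Outcomes are clamped to "yes"
once entered even if a learned CPT leaks probability the other way —
onset variables are defined "until now", so reversion is semantically
impossible.  A trajectory ends at death or when the next step would pass
the horizon.  Death time is recorded as the offset of the wave at which
survival turns yes (the start of its 4-year window); the window midpoint is
a defensible alternative the data do not adjudicate.

Every (subject, repetition) draws from its own counter-based substream
(Philox keyed by master seed, subject index and repetition), so cohorts are
bit-identical regardless of processing order.  Within a step, slice-t nodes
have no intra-slice parents, so their update order is irrelevant.

De-quantisation draws uniformly from the pool of training continuous values
observed at the sampled level, guaranteeing that re-quantisation recovers
the level; an empty pool falls back, with a warning, to a uniform draw over
the level interval truncated at the catalog's plausible bounds.

## Evaluation

Event records take the first wave offset at which an outcome is "yes";
baseline-prevalent subjects are excluded from onset analyses; everyone else
is censored at their last observed or simulated offset.  The Kaplan-Meier
estimator is computed directly (product-limit with the events-before-
censorings tie convention) with the log-transformed Greenwood pointwise
interval clamped to [0, 1]; the implementation is cross-checked against
lifelines in the test suite, and the log-rank test is lifelines'.

The per-subject risk score is 1 − area/horizon, where the area is under
the KM curve of the subject's simulation repetitions: bounded in [0, 1] and
ranking-equivalent to the negated area.  Time-dependent classification uses
cumulative cases (event ≤ t) versus event-free controls still under
observation at t; subjects censored before t are excluded — the only
convention consistent with a total count that shrinks over the grid.
AU-ROC is the Mann-Whitney pair-counting statistic (ties half-credited);
AUC-PR is interpolation-free step integration (average precision).
Integrated metrics are unweighted means over the defined grid points
(2-year steps, to 8 years for comorbidities, 4 for death).  With random
scores the expected AUC-PR approaches the positive rate only as the class
counts grow; the suite checks this at a few hundred subjects.

One deliberate deviation: a plausible-sounding invariant — "adding an
event-bearing repetition never decreases the risk score" — is false for the
KM-area score (a late event enlarges early risk sets and can raise the
curve).  What holds, and what is tested, is that turning any censored
repetition into an event never decreases the risk.

## Stratification

For an outcome, cohorts are the observed baseline combinations of its
parents (excluding its own persistence loop), coded as digit strings in
catalog order.  Each cohort is simulated (100 repetitions per subject by
default), its onset KM curve sampled on the 2-year grid, min-max normalised
per time point (a time point where all curves agree maps to zero), and
clustered with Ward's criterion on Euclidean distances.  The number of risk
groups is a majority vote over five validity indices — silhouette,
Calinski-Harabasz and Dunn (maximised), Davies-Bouldin and the
Hubert-Levin C-index (minimised) — over k = 2…6, ties resolved toward the
smallest k.  The published analysis used a 26-index panel from a legacy
package; that set is package-specific and unspecified, so a documented
five-index surrogate keeps the majority rule and range.  Cohorts below 10
subjects are simulated but excluded from clustering: their KM curves are
too noisy to compare.

## The synthetic-data generator

`make_ground_truth_dbn` builds a random layered network with controlled
effect sizes: every dynamic variable has a persistence self-loop (weight
2–3 on the logit scale), risk variables take up to two extra parents with
effects of magnitude ≥ 1.5, outcomes are absorbing with 2–3 positive-weight
risk parents and baseline hazards matching realistic prevalence (diabetes
7%, hypertension 35%, heart problems 15% at baseline; death ≈ 3% per
window), and survival conditions on current status plus baseline age.
Non-absorbing rows come from an ordered-logistic model, so they sit away
from indifference and the structure is recoverable.  `sample_panel`
ancestrally samples complete trajectories, decorates each discrete level
with a continuous value uniform within the level's interval (outer
intervals truncated at plausible bounds, so re-quantisation is exact), and
stops a subject at death.  `apply_missingness` re-imposes the design
cadence — biomarkers observed only every other wave — plus
category-specific completely-at-random blanking (defaults 2–10%), never
touching outcomes, survival, sex, baseline age or TSB.

The generator emulates the *shape* of the target study — variable counts
and kinds, wave spacing, absorbing outcomes, design missingness, baseline
prevalence — not its real marginal distributions or effect estimates.
Passing recovery tests therefore demonstrates that the pipeline's machinery
is correct under known truth, not that it would reproduce any particular
published network; missingness here is (by construction) ignorable, whereas
real panel dropout need not be.

The two-regime variant gives each outcome one dominant parent (weight 4
versus 0.3 for the others) and a three-parent set, producing two tight
bundles of cohort curves with a within-bundle continuum — the configuration
in which a two-cluster partition is the right answer.  With very few
cohorts (say six), several validity indices legitimately prefer singleton
splits, which is why the scenario uses twelve.

## Problem sizes and seeds

The default scenario is 10 dynamic + 3 static variables, 2,000 subjects,
6 waves, k = 10 folds — minutes-scale on one CPU, and the scale at which
structure recovery (precision and recall ≥ 0.8 against truth) is tested.
Parameter recovery is checked at the emulated study's training size
(8,328 subjects), where every CPT row with ≥ 100 supporting observations
has enough support for the ±0.05 tolerance to be meaningful.  Calibration
closure uses 1,000 subjects, 5 repetitions and 20 seeds; stratification
recovery 1,500 subjects and 25 repetitions.  All randomness flows from
explicit integer seeds; the reproduction script derives its sub-seeds from
a single `--seed`.

## Known limitations

* Discrete-state modelling loses within-level information; de-quantisation
  restores the training distribution within a level, not the subject's
  value.
* The skeleton surrogate bounds conditioning-set size; very high-order
  interactions could be missed (none exist in the generator).
* No competing-risk or IPCW correction in the time-dependent metrics; no
  interventional (do-operator) simulation; no continuous-time semantics.
* The log-rank calibration comparison pools simulation repetitions and
  shares baselines between groups, which makes the test somewhat
  conservative; this mirrors the published procedure.
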