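# Methods

## Model and assumptions

`omgnet` implements a discrete Bayesian network over a suspected-OMG
diagnostic work-up. Twelve categorical variables factorise as
`p(x) = ∏ p(xᵢ | pa(xᵢ))` along a fixed DAG (no structure learning):

- roots: `age` (bins 18–50, 50–70, 70+; right-closed intervals (0,50],
  (50,70], (70,120]) and `sex`;
- `omg` (the diagnosis) with parent `sex`;
- `achr` (AChR-antibody serology) with parents `omg` and `age` — the
  age dependence captures the markedly lower seropositivity of younger
  patients;
- `diplopia`, `ptosis`, `upgaze`, `ice`, `edrophonium`, `rns`, `sfemg`
  (binary negative/positive) and `besinger` (severity score binned
  [−1,1], (1,4], (4,8], (8,24]), each with sole parent `omg`. Besinger
  and QMG severity scores are treated as one variable.

This is the minimal structure consistent with the published conditional
tables; conditional on disease status the tests are assumed independent.
That assumption is clinically imperfect (e.g. the two electrophysiologic
tests plausibly co-vary), but it is what the available per-test counts can
identify.

## Estimation

Each CPT row gets a symmetric Dirichlet prior with concentration 1.0 per
state (configurable via `prior_strength`). The posterior row is
Dirichlet(prior + counts); a single entry's marginal is a Beta
distribution, and `cpd_summary` reports its **exact** equal-tailed
quantiles (0.025, 0.5, 0.975) via `scipy.stats.beta.ppf` — no sampling for
single-entry queries. The uniform prior was chosen because it reproduces
the published posterior summaries of the training cohort from the printed
counts (e.g. 29 positive / 2 negative edrophonium results among
OMG-positive cases → Beta(30, 3) → median 91.7%, interval ≈ (79%, 98%)).
Published interval endpoints occasionally differ from the exact quantiles
by up to ~0.4 percentage points with mixed signs, the signature of
Monte-Carlo quantile jitter in the original computation; this package
prefers the exact values.

**Missing data.** Complete-case analysis is applied per CPT, not per
record: a record informs the table of `X` iff `X` and all parents of `X`
are observed. This uses every available observation and reproduces the
cohort's per-test available-case totals (71 edrophonium, 51 ice, 84
upgaze, 87 RNS, 86 sfEMG of 89). No imputation.

## Inference and prediction

`conditional_query` computes `P(query | evidence)` by exhaustive
enumeration restricted to the ancestral closure of evidence ∪ query;
unobserved descendants sum out of the joint exactly, so most queries touch
only a handful of variables (the full joint has 12,288 cells — small
enough that transparency beats cleverness). Equality with a brute-force
full-joint tabulation is tested to 1e-10.

`predict` propagates posterior parameter uncertainty: it draws `n_samples`
full CPT parameter sets (every row independently from its Dirichlet
posterior — exact under the conjugate model), evaluates the conditional
under each draw, and reports the empirical median and 2.5/97.5 percentiles
of those probabilities. Defaults: `n_samples = 10,000` (credible-interval
endpoints stable to roughly ±0.005) and seed `20160101`. Classification is
positive iff the median strictly exceeds 0.5; an exact 0.5 is negative.
Zero-probability evidence is impossible under a positive prior and raises
an explicit error if degenerate plug-in parameters are supplied.

## Validation machinery

`evaluate` restricts to records complete for the chosen predictor set and
the outcome, scores each by the median predicted probability given only
those predictors, classifies at 0.5, and reports the misclassification
fraction and the rank-based AUC (Mann–Whitney with mid-ranks, so tied
scores count ½). Training-data evaluation scores the model on its own
training records without refitting. `cross_validate` shuffles the eligible
records with a seed, splits them into k near-equal unstratified folds,
refits on k−1 folds and scores the held-out fold; it reports unweighted
fold means, with single-class folds excluded from the AUC mean but not the
error mean. `sens_spec` reads sensitivity and specificity directly off the
observed two-by-two tables.

## The packaged training fixture

The training cohort ships as per-CPT counts with per-stratum missingness
tallies. The AChR-by-age rows within disease strata are not printed as a
joint table; they are reconstructed by integer inversion of the published
posterior medians against the published margins (unique integer solution)
and flagged `derived` in the fixture metadata. `expand_fixture` emits a
record set whose per-CPT counts reproduce the fixture exactly: within each
disease stratum every variable's observed values and missing slots are
dealt to patients by an independent seeded shuffle (serology within
disease-by-age cells). The cross-test joint of the real patients is not
recoverable from the printed margins, so the expansion is *one admissible*
reconstruction: single-predictor evaluations on it are exact, while
multi-predictor joint behaviour is synthetic and is validated only through
the property-based tests.

## Synthetic cohorts

`generate` draws records by ancestral sampling from explicit CPT vectors
(typically plug-in posterior means) and then masks each variable
independently at configurable rates — missingness completely at random,
with the outcome never masked. Real referral cohorts are unlikely to be
MCAR (tests are skipped *because of* serology results or
contraindications), so passing recovery tests demonstrates correctness of
the machinery, not robustness to informative missingness. Test problem
sizes were chosen to keep checks sharp but quick: 10,000 records for
parameter recovery (binomial error well under the ±0.03 check), 890
records and 10 folds for the cross-validation-versus-analytic-error check
(±3 points ≈ 3 standard deviations of cohort sampling noise), 100,000
posterior draws for Monte-Carlo-versus-exact quantile convergence.

## Numerical and design choices

- Bin boundaries are right-closed; the published bin labels overlap at the
  boundaries, so the convention here is the package's own.
- Quantiles of Monte-Carlo draws use `numpy.quantile`'s default linear
  interpolation.
- Fold assignment is a seeded uniform permutation, unstratified.
- All randomness flows through `numpy.random.default_rng` seeds; identical
  seeds give bitwise-identical draws, cohorts, folds and predictions.
- The CLI serialises models as plain YAML documents of concentration
  parameters, keeping the fitted object human-auditable.

## Known limitations

- The conditional-independence structure is fixed and minimal; no edges
  among tests.
- The fixture expansion fabricates cross-test joints (see above).
- MCAR masking only; no informative-missingness or referral-bias
  simulation.
- External cohorts can be evaluated via `evaluate`/`cross_validate` on any
  CSV in the record schema, but none are packaged.
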