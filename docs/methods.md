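# Methods

## The model in brief

The package treats chemotherapy-response prediction as a three-class
classification problem learned on a small cell-line screen and transferred
to patient cohorts. The response phenotype is the *activity area* of each
cell line's dose–response curve (larger = more sensitive). Because the
discovery sample is tiny (default 25 cell lines) the pipeline leans on
rank-based and margin-based methods throughout: a Kruskal–Wallis filter, an
SVM classifier, and log-rank/proportional-hazards survival analysis.

## Preprocessing

**Quantile normalization.** Each sample column is replaced rank-by-rank with
the across-sample mean of the order statistics. Ties within a column receive
the mean of the rank means over the tied span (the "ties = average"
dialect), which keeps the operation idempotent. Requires ≥ 2 samples.

**Probe collapse.** Probes mapping to zero or multiple gene symbols are
dropped. Among probes annotating the same gene, the one with the largest
coefficient of variation (sample sd / mean, computed on the post-quantile
intensity scale) is kept — the most variable probe is the most likely to
carry signal. CV requires a positive mean, so this step runs on raw
intensities, never on z-scores.

**Z-scoring.** Every gene row is standardized to mean 0, sd 1, with the
n−1 (sample) denominator — the natural choice at n = 25. A constant gene is
an error naming the gene; `drop_constant=True` drops and logs instead.

## Response groups

Samples are sorted ascending by activity area and cut into near-equal
ordinal tertiles; sizes are ⌊n/3⌋ with the remainder distributed one each
starting from the low group (25 → 9/8/8, 26 → 9/9/8). Ties in activity area
break by stable input order, making the rule deterministic. The cut points
are data realizations, not parameters: only ranks matter.

## Gene filter

Per-gene Kruskal–Wallis across the three groups, χ² approximation with
2 degrees of freedom and tie correction (delegated to `scipy.stats.kruskal`;
an independent rank-statistic oracle checks it in the tests). Constant genes
get H = 0, p = 1. Genes with p < α (default 0.01) form the candidate pool.
At n = 25 the χ² approximation is slightly conservative (measured type-I
rate ≈ 0.6–0.8% at nominal 1% in the null simulation); exact enumeration is
infeasible at group sizes 9/8/8 and is not attempted.

## Panel search

A wrapper selection: each candidate is an unordered set of exactly K = 10
genes (K is fixed because prediction deteriorates with fewer predictors and
the panel is meant to be assayable by QRT-PCR at fixed cost); the fitness is
the LOOCV accuracy of a three-class SVM (linear kernel, C = 1, the
smallest-assumption choice at n = 25, p = 10; kernel and C are
configurable). The genetic algorithm uses:

- population 100, generations 10 (the search stabilizes well before that at
  this scale), both configurable;
- fitness-proportional (roulette) parent selection, uniform if all fitness
  is zero;
- single-point crossover on the gene list (rate 0.9) followed by repair of
  duplicate genes with uniform draws from the unused pool;
- per-position mutation to a random pool gene (rate 0.05);
- elitism 1 within the population plus a *global* best-so-far memory, so the
  reported best fitness is non-decreasing by construction;
- a single integer seed driving every random draw; identical seeds give
  byte-identical runs.

The crossover rate had no externally fixed value; 0.9 is a conventional GA
default and is exposed in `GAConfig`.

A caveat worth knowing: when the class signal is strong, LOOCV accuracy
saturates at 1.0 for many panels that contain only a handful of informative
genes, and the wrapper has no gradient beyond that point. The returned panel
is then *a* perfect classifier, not a complete list of the informative
genes. The tests document this: on the planted-signal fixture ~4 of 10
planted genes already separate the groups perfectly, so the search reliably
returns accuracy-1.0 panels that mix planted and hitchhiker genes.

**Training.** The final model stores per-gene training means/sds, the fitted
SVM, and its LOOCV accuracy. Serialization stores the standardized training
features and labels and refits the (deterministic) SVM on load, avoiding a
fragile hand-rolled dump of SVM internals.

## Permutation empirical null

Each trial draws K genes uniformly without replacement from the pool
(default: the filter-passing pool; optionally the full array) and scores
them with the *same* LOOCV protocol used as the GA fitness. The empirical
p-value is the fraction of trials reaching the observed accuracy. Trials are
independent, so a combination may recur — the estimate is then exactly
binomial with standard error √(p(1−p)/n_trials), and on an exhaustively
enumerable pool (12 genes → 66 combinations) the Monte-Carlo estimate is
checked against full enumeration.

## Cohort transfer and survival analysis

**Filtering.** Only treated patients surviving strictly longer than 30 days
enter the analysis (a patient at exactly 30 days is excluded).

**Classification.** Panel genes are z-scored across the *cohort's own*
patients by default before prediction; this removes platform location/scale
and makes predictions invariant to any positive per-gene affine transform.
Standardizing with the training statistics instead is available
(`standardize='training'`) for same-platform settings, since per-cohort
scaling discards absolute level information.

**Survival.** Kaplan–Meier curves, the two-sided log-rank test and Cox
proportional-hazards fits are delegated to `lifelines` (Efron tie handling);
the tests check them against a brute-force product-limit oracle, a null
calibration (uniform p-values) and planted-hazard-ratio recovery. The panel
enters Cox models coded medium+high (= 1) vs low (reference) by default,
matching the convention that responders are contrasted against the
low-response reference; high-vs-low coding is available and is what the
two-group KM display uses. Histology enters as indicators against a serous
reference; levels absent from a cohort are dropped with a logged warning.
Time-to-event is accepted precomputed; the package does not adjudicate
recurrence from dates or marker kinetics.

**Sample-size planning.** The Schoenfeld events formula
E = (z₁₋α/₂ + z_power)²/(p(1−p)(ln HR)²), n = ⌈E/P(event)⌉. For HR 0.52,
two-sided α 0.05, power 0.70, event probability ≈ 1 and allocation 0.776 it
gives n = 84.

## Synthetic data

**Cell-line screen.** Activity areas are Uniform(2, 7) — continuous, hence
almost surely tie-free under the tertile rule. Gene baselines are
Uniform(5, 9) (positive, so CV is defined), noise is Gaussian with sd 1, and
the planted signal genes are shifted by −e·sd, 0, +e·sd for the low, medium
and high groups (e = 3 by default, a clearly separable screen). Defaults:
25 cell lines, 2000 genes, 10 planted.

**Patient cohort.** Group labels are drawn with high responders a minority
(15/25/60 high/medium/low by default). Panel-gene expression is drawn from
the trained model's group-conditional training distributions, with the
between-group separation scaled by `expression_effect`. Survival is
exponential with group-specific hazards — either given directly or derived
from a high-vs-low hazard ratio (default 0.52, a clinically plausible
protective effect) with the medium group at the geometric mean — and
censoring is independent exponential with its rate solved per patient so the
expected censored fraction equals `censoring_rate`. Clinical covariates are
drawn independently of the group unless the confounding flag is set.

What the generators deliberately do **not** emulate: microarray platform
artifacts (probe GC bias, batch structure), non-proportional hazards,
informative censoring, correlated gene–gene noise, and non-Gaussian
expression heavy tails. Tests passing on these fixtures therefore
demonstrate the *machinery* (calibration, invariants, recovery of planted
effects under the assumed models), not performance on real cohorts. Both
noise models are the simplest consistent with the pipeline's rank-based and
proportional-hazards assumptions and sit behind interfaces that could take
log-normal expression or Weibull survival.

## Problem sizes used in the test and acceptance suites

These are the package's own choices of desk-scale experiments: the
separable discovery fixture is 25 × 50 with 10 planted genes; the GA check
runs population 100 for 10 generations; permutation machinery is verified on
the 66-combination enumerable pool plus a 200–400-trial Monte-Carlo; the
log-rank null calibration uses 1000 replicates of 30 + 30 exponential
samples; Cox recovery uses 100 cohorts of n = 300 at true HR 0.52 with a
balanced two-arm allocation (at a 15%-high allocation the standard error of
log HR is ~0.18, and a ±0.27-wide log band is only a ±1.5-SE statement — the
balanced design makes the recovery check sharp); the null filter calibration
uses 10 screens of 400 genes. The KW filter's measured type-I rate at these
sizes is slightly below nominal, as noted above.

## Known limitations

- The wrapper selects *one* perfect-fitting panel; gene membership is not
  stable across seeds once fitness saturates (see the panel-search caveat).
- Empirical p-values are granular at 1/n_trials; reporting p = 0 means "no
  success in n trials", not impossibility.
- Per-cohort z-scoring assumes the cohort is large and heterogeneous enough
  for its own mean/sd to be stable; very small cohorts should use training
  statistics.
- The Cox stage assumes proportional hazards and complete covariates;
  patients with missing covariate rows are dropped by the model-frame
  construction rather than imputed.
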