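# Methods

## Overview

`immusub` implements a cohort-integration and immune-subtyping workflow
for bulk expression data: merge cohorts on a curated immune gene list,
remove cohort batch effects, discover gene modules and sample subtypes by
consensus clustering, transfer subtypes to further cohorts, and relate
subtypes to time-to-event outcome. This note records the models, the
parameters that matter, the numerical conventions, and what the bundled
synthetic generator does and does not emulate.

## Synthetic data model

`generate_cohort` draws, for gene *g* (module *m*), sample *s* (subtype
*k*), cohort *b*:

```
x_gs = (base_g + A[k, m] + shift_bg) * scale_bg + eps,   eps ~ N(0, noise_sd^2)
```

Genes outside any module ("noise genes") omit the activity term `A[k, m]`.
Survival times are exponential with hazard
`h0 * exp(log_hazard[k])` — constant hazard, so proportional hazards
holds exactly and Cox fits have a known truth — censored by an
independent administrative time drawn uniform on `(0, censor_time_max)`.
Treatment response is Bernoulli per subtype, independent of survival
given the subtype.

Defaults (chosen once as a realistic desk-scale cohort and fixed):

| parameter | default | units / rationale |
|---|---|---|
| modules × genes | 4 × 50 + 300 noise genes | immune panel of ~500 genes, most uninformative |
| subtypes | 5 × 60 samples per cohort | two cohorts ≈ 600 samples |
| activity amplitude | ±1 (mild entries ±0.5) | ~1 log₂-unit shifts |
| `noise_sd` | 0.5 | residual biological + technical spread |
| `base_expr_mean/sd` | 7 / 1 | log₂-FPKM-like baselines |
| `baseline_hazard` | 0.015 /month | median OS ≈ 46 months in the worst subtype |
| `log_hazard_by_subtype` | (−0.35, −0.74, −0.35, 0, −0.35) | best-vs-worst HR ≈ 0.48 |
| `censor_time_max` | 120 months | ~40 % event fraction |
| `response_prob_by_subtype` | (0.5, 0.7, 0.5, 0.35, 0.5) | best subtype responds more often |

The default activity pattern gives each characteristic subtype one high
and one low module (IS1: +GM3/−GM4; IS2: +GM2/−GM4; IS4: +GM4/−GM1;
IS5: +GM1/−GM2−GM3) and leaves IS3 intermediate everywhere. Two mild
−0.5 entries (IS1/GM2 and IS2/GM3) make the four module columns mutually
uncorrelated; without them two modules are partial copies of each other
and no clustering method can separate them — distinctness of the module
columns is part of what "distinct co-expression modules" means.

What the generator does **not** emulate: count noise and library-size
effects (values are Gaussian on the log scale), gene–gene correlation
beyond module membership, overlapping or hierarchical modules, non-
proportional hazards, informative censoring, and cohort differences in
case mix. Passing tests therefore demonstrate correctness of the
machinery under the model's assumptions, not robustness to real-data
violations of them.

## Batch correction

`combat_adjust` is the parametric empirical-Bayes location/scale model:
per-gene standardization against a grand-mean model (no biological
covariates — none are available at this stage of the design), normal
shrinkage of per-batch gene means, inverse-gamma shrinkage of per-batch
gene variances via the standard iterative posterior update, adjustment,
and back-transformation. It reproduces R's `sva::ComBat` to ~2e-5 on
shared fixtures. Conventions worth knowing:

- per-batch variances use ddof = 1 against the MLE pooled variance, so
  even identically distributed batches are rescaled by (n−1)/n — an
  exact finite-sample property, tested as such;
- a gene with zero variance inside some batch falls back to the
  unshrunk location estimate with unit scale for that batch (warned);
- `mean_only=True` adjusts locations only;
- a single batch is a no-op by contract.

Input is assumed log-scale; `log2p1` (CLI `--log2p1`) handles
linear-scale FPKM-style input. Gene standardization for clustering uses
the population-SD convention (divide by n) so small fixtures are exact,
and is idempotent.

## Consensus clustering

`consensus_matrix` subsamples `item_fraction` (default 0.8) of the items
`n_bootstrap` times (default 500 as commonly printed; tests and the
bundled studies use 50–100, which is ample at these sizes) **without**
replacement (`replace=True` gives classical bootstrap draws), clusters
each subsample by agglomerative clustering (Euclidean; average linkage
by default, complete/Ward selectable), and accumulates pair
co-clustering and co-draw counts. Conventions:

- consensus of a pair never co-drawn is 0 with a warning (possible at
  very small B);
- resample draws depend only on the seed and item count, never on k, so
  per-k matrices are comparable and `consensus_sweep` can cut one
  linkage tree per resample at every k at a fraction of the cost — the
  results are bit-identical to independent per-k calls;
- the CDF of the upper-triangle consensus values is evaluated on a 0.01
  grid and integrated by the trapezoid rule;
- `select_k` uses the relative Δ-area rule: Δ(k_min) = A(k_min),
  Δ(k) = (A(k) − A(k−1))/A(k−1), choosing the largest k with Δ above a
  threshold (default 0.05). The full curve is always returned so the
  user can fix k manually;
- the final partition is an average-linkage cut on 1 − consensus;
  cluster ids are renumbered by decreasing size (ties: smallest member
  position), giving the GM1../IS1.. naming.

`discover` clusters gene rows and sample columns of the same
standardized matrix, with independent resample streams.

## Subtype transfer

Module activity is the unweighted mean expression of a module's genes;
subtype centroids are unweighted means of member activities. Assignment
uses Pearson correlation (Spearman is nearly degenerate with only four
modules); it is invariant to per-sample affine rescaling with positive
slope. The intermediate subtype (IS3 by convention) has no
characteristic signature, so its centroid is excluded from matching by
default; `ambiguity_threshold` optionally routes samples whose best
correlation falls below it to that subtype instead. A zero-variance
activity vector has no defined correlation: the sample is flagged
unassigned rather than guessed.

`cluster_then_match` first clusters the new cohort's activities
(Euclidean, average linkage, k clusters) and then matches cluster
centroids to discovery centroids greedily from the highest correlation
down, each subtype usable once unless reuse is allowed — greedy rather
than Hungarian because it is deterministic, transparent, and adequate at
k ≤ 5.

Whether a validation cohort should be batch-corrected against the
discovery cohorts before computing activities is genuinely open; the
pipeline corrects first (merging validation with the corrected discovery
matrix and re-running the EB adjustment) and records the choice in the
manifest.

## Multinomial classifier

A softmax regression on the module activities with the reference class
pinned at zero: coefficients form a (C−1) × (M+1) grid (intercept
first). The fit maximizes the multinomial log-likelihood with a small
ridge penalty on the weights (default 1e-4; intercepts unpenalized),
which keeps coefficients finite on separable data — with five
well-separated subtypes and four features, separability is the rule, not
the exception. Features are standardized internally and the transform
stored with the model. Convergence requires gradient sup-norm < 1e-6
(else the model is returned flagged unconverged). Evaluation is
one-vs-rest: AUROC is the Mann–Whitney statistic with ties counted ½,
AUPRC the step-interpolated precision-recall area (both via
scikit-learn, whose conventions match); classes absent from the truth
are reported as missing, not zero.

## Survival machinery

- **KM**: product-limit estimator via lifelines; subjects censored
  exactly at an event time count as at risk at that time (standard
  convention). All-censored groups yield a flat curve, flagged.
- **Log-rank**: unweighted k-group form (observed − expected with
  hypergeometric variance, χ² with k−1 df) via lifelines.
- **Cox**: partial likelihood via statsmodels `PHReg`, Efron ties by
  default (less biased with ties; Breslow available — the two agree
  exactly without ties). Newton iterations with a BFGS fallback when the
  Hessian is singular (near-separation); levels with runaway
  coefficients are reported with an `unstable` flag rather than hidden.
  95 % Wald intervals, HR = exp(logHR).
- Categorical covariates require an explicitly declared baseline level —
  the natural reference changes between analyses (worst-prognosis
  subtype, stage III vs IV), so nothing is defaulted silently.
  `subtype_survival_report` defaults the Cox baseline to the
  worst-prognosis subtype, identified by restricted mean survival time
  up to the shortest per-group follow-up.

## Group comparisons

Kruskal–Wallis (midrank tie correction; an all-identical sample returns
H = 0, p = 1 by convention), Dunn's pairwise z on pooled midranks with
tie correction and Bonferroni multiplication capped at 1 (written
in-package; no installed dependency provides Dunn), Wilcoxon rank-sum
(exact enumeration when n₁+n₂ ≤ 12 without ties, else normal
approximation with tie-corrected variance and continuity correction),
Fisher's exact test (two-sided by the probability-mass rule) and Pearson
χ² without continuity correction by default; `auto` picks Fisher for
2×2 tables with any expected count < 5. Zero-margin tables return p = 1
with a warning.

## Pipeline and reproducibility

`run_pipeline` executes simulate → preprocess → discover → transfer →
classify → survival → compare from one config, writing every
intermediate artifact as TSV/JSON plus a manifest with per-stage seeds
(derived from the root seed and the stage name, so stages are
individually reproducible) and file checksums. Reruns with the same
config and seed are bit-identical on the same platform. Stage failures
abort with the failing stage named; partial outputs are retained.

## Problem sizes

The bundled studies use 500 genes × 300 samples per cohort with B = 50–100
consensus resamples, and 200 replicates for the Cox recovery and
calibration checks — sizes at which every estimate above is stable while
the full validation suite completes in minutes on a single CPU. B = 500,
as often printed for this design, changes none of the conclusions at
these item counts.

## Known limitations

- Consensus clustering assigns *every* gene to a module; noise genes are
  absorbed into the nearest module rather than left unassigned, which
  dilutes module-activity magnitudes (recovery is scored on the genes
  with a planted module). A tightness filter would be a natural
  extension.
- The Δ-area threshold 0.05 is a heuristic; `select_k` therefore always
  exposes the full curve.
- No proportional-hazards diagnostics, time-varying covariates, or
  competing risks.
- Fisher's exact test is 2×2 only; r×c tables use χ².
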