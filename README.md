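# immusub

Immune subtyping of bulk tumour expression cohorts: discover co-expressed
immune **gene modules** (GMs) and sample **immune subtypes** (ISs) by
bootstrap consensus clustering, transfer the subtypes to new cohorts, and
quantify their association with survival.

The workflow mirrors a common design in tumour-microenvironment studies
(e.g. ovarian-cancer cohorts profiled on mixed RNA-seq/microarray
platforms): several cohorts are merged on a curated immune-gene list,
cohort/platform batch effects are removed with parametric empirical-Bayes
adjustment (ComBat), genes and samples are clustered by subsampled
consensus clustering, and each subtype's prognostic effect is measured by
Kaplan–Meier/log-rank analysis and Cox proportional-hazards regression.
Because real cohorts of this kind live behind external downloads, the
package ships a first-class synthetic-data generator that reproduces the
statistical structure of such a study — planted modules, subtype activity
signatures, batch effects, and subtype-dependent survival — with full
ground truth, so every stage is testable end to end.

## The method in brief

**Consensus clustering (Monti et al.).** For a chosen cluster count *k*,
draw *B* subsamples of 80 % of the items, run agglomerative clustering
(Euclidean distance, average linkage) on each, and record for every item
pair (i, j)

&nbsp;&nbsp;&nbsp;&nbsp;M(i, j) = (# subsamples where i, j co-cluster) / (# subsamples containing both),

the *consensus matrix*. The empirical CDF of the off-diagonal consensus
values and the relative gain in its area as *k* grows (the Δ-area curve)
select *k*; the final partition is an average-linkage cut on 1 − M.
Applied to gene rows it yields modules GM1..GMk; to sample columns,
subtypes IS1..ISk.

**Module activity and transfer.** A module's activity in a sample is the
mean expression of its genes; a subtype's centroid is the mean activity
vector of its samples. New cohorts are labelled by maximal Pearson
correlation with the discovery centroids (per sample, or per cluster via
cluster-then-match). A subtype without a characteristic activity
signature is excluded from correlation matching. A multinomial (softmax)
logistic model on the activities provides an alternative transferable
classifier, evaluated by one-vs-rest AUROC/AUPRC.

**Survival.** Kaplan–Meier product-limit curves, the unweighted k-group
log-rank test, and Cox proportional-hazards fits (Efron ties by default)
with explicitly declared baseline levels, reporting HR = exp(β) with 95 %
Wald intervals. Feature differences between subtypes use Kruskal–Wallis
with Dunn–Bonferroni post hoc, Wilcoxon rank-sum, and Fisher/χ² tests;
derived microenvironment quantities (stromal fraction = 1 − purity,
absolute cell proportions = relative proportions × leukocyte fraction)
are provided as helpers.

## Worked example

```python
import immusub as im

config = im.SimulationConfig(
    seed=1, batch_specs={"cohortB": im.BatchSpec(shift=1.0, scale=1.1)}
)
expr_a, surv_a, truth_a = im.generate_cohort(config, "cohortA")
expr_b, surv_b, truth_b = im.generate_cohort(config, "cohortB")

genes = im.curate_genes([expr_a, expr_b], im.GeneSet(list(expr_a.gene_ids)))
std = im.standardize_genes(im.combat_adjust(im.merge_cohorts([expr_a, expr_b], genes)))

scheme = im.ResamplingScheme(n_bootstrap=100, item_fraction=0.8, seed=2)
modules, subtypes, *_ = im.discover(std, k_genes=4, k_samples=5, scheme=scheme)

sweep = im.consensus_sweep(std.values.T.to_numpy(), range(2, 9), scheme)
print(im.select_k(sweep).deltas)
```

prints the relative Δ-area gains

```
{2: 0.324, 3: 0.738, 4: 0.283, 5: 0.11, 6: 0.001, 7: 0.001, 8: 0.001}
```

— the gain collapses after k = 5, so five subtypes are selected, matching
the five planted signatures. Continuing with survival on the first cohort
(`examples/04_survival_analysis.py`):

```
overall log-rank: chi2=11.72, df=4, p=0.0196
best vs worst prognosis: IS2 vs IS4, p=0.0015
Cox fit (baseline = worst-prognosis subtype):
subtype[IS2]  hr 0.386  ci [0.209, 0.712]  p 0.002
```

The protective subtype's hazard ratio (0.39 against the worst-prognosis
baseline) recovers the planted log-hazard contrast (e^-0.74 ≈ 0.48)
within sampling error, and the contrast persists within
treatment-response strata — prognosis is independent of response status,
as planted.

The `examples/` directory has one short script per capability
(discovery, transfer, classification, survival, full pipeline); each
prints the numbers it computes and what they mean. A thin CLI wraps the
same functions: `immusub simulate|preprocess|discover|assign|classify|survival|compare|run`.

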