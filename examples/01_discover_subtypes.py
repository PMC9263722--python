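"""Discover immune gene modules and sample subtypes in a two-cohort study.

Simulates two cohorts with planted structure (4 gene modules, 5 subtypes,
a gene-wise batch effect on cohort B), merges and batch-corrects them,
then runs bootstrap consensus clustering on genes and samples.
"""

from sklearn.metrics import adjusted_rand_score

import immusub as im

config = im.SimulationConfig(
    seed=1, batch_specs={"cohortB": im.BatchSpec(shift=1.0, scale=1.1)}
)
expr_a, surv_a, truth_a = im.generate_cohort(config, "cohortA")
expr_b, surv_b, truth_b = im.generate_cohort(config, "cohortB")
print(f"cohort A: {expr_a.n_genes} genes x {expr_a.n_samples} samples")

genes = im.curate_genes([expr_a, expr_b], im.GeneSet(list(expr_a.gene_ids)))
merged = im.merge_cohorts([expr_a, expr_b], genes)
corrected = im.combat_adjust(merged)          # empirical-Bayes batch removal
standardized = im.standardize_genes(corrected)

scheme = im.ResamplingScheme(n_bootstrap=100, item_fraction=0.8, seed=2)
modules, subtypes, gene_res, sample_res = im.discover(standardized, 4, 5, scheme)

print("\nmodule sizes: ", modules.module_of_gene.value_counts().to_dict())
print("subtype sizes:", subtypes.subtype_of_sample.value_counts().to_dict())

# the delta-area curve justifies k=5 for samples
sweep = im.consensus_sweep(
    standardized.values.T.to_numpy(), range(2, 9), scheme,
    item_ids=standardized.sample_ids,
)
sel = im.select_k(sweep)
print(f"\ndelta-area curve selects k={sel.k} for samples")
print("relative area gains:", {k: round(d, 3) for k, d in sel.deltas.items()})

# score recovery against the planted truth (possible only on synthetic data)
mask = truth_a.module_of_gene.notna()
print(
    "\ngene-module ARI vs truth:",
    round(adjusted_rand_score(
        truth_a.module_of_gene[mask], modules.module_of_gene[mask]
    ), 3),
    "(1.0 = planted modules recovered exactly)",
)
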