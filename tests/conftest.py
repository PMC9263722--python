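"""Shared fixtures: a small two-cohort synthetic study processed once.

The `study` fixture runs simulate -> merge -> ComBat -> standardize ->
discover at a reduced bootstrap count, and downstream module tests reuse
it instead of re-clustering.
"""

from dataclasses import dataclass

import pandas as pd
import pytest

import immusub as im


@dataclass
class Study:
    config: im.SimulationConfig
    expr_a: im.ExpressionMatrix
    expr_b: im.ExpressionMatrix
    surv_a: im.SurvivalData
    surv_b: im.SurvivalData
    truth_a: im.SyntheticTruth
    truth_b: im.SyntheticTruth
    genes: im.GeneSet
    corrected: im.ExpressionMatrix
    standardized: im.ExpressionMatrix
    modules: im.ModuleSet
    subtypes: im.SubtypeLabels
    activity: im.ActivityMatrix
    centroids: im.CentroidModel

    @property
    def true_subtypes(self) -> pd.Series:
        return pd.concat(
            [self.truth_a.subtype_of_sample, self.truth_b.subtype_of_sample]
        )

    @property
    def clinical(self) -> im.SurvivalData:
        tab = pd.concat([self.surv_a.table, self.surv_b.table])
        base = dict(self.surv_a.baselines)
        base["cohort"] = "cohortA"
        return im.SurvivalData(tab, base)


@pytest.fixture(scope="session")
def study() -> Study:
    config = im.SimulationConfig(
        seed=11,
        batch_specs={"cohortB": im.BatchSpec(shift=1.0, scale=1.1)},
    )
    expr_a, surv_a, truth_a = im.generate_cohort(config, "cohortA")
    expr_b, surv_b, truth_b = im.generate_cohort(config, "cohortB")
    genes = im.curate_genes([expr_a, expr_b], im.GeneSet(list(expr_a.gene_ids)))
    merged = im.merge_cohorts([expr_a, expr_b], genes)
    corrected = im.combat_adjust(merged)
    standardized = im.standardize_genes(corrected)
    scheme = im.ResamplingScheme(n_bootstrap=50, item_fraction=0.8, seed=17)
    modules, subtypes, _, _ = im.discover(standardized, 4, 5, scheme)
    activity = im.module_activity(standardized, modules)
    centroids = im.subtype_centroids(activity, subtypes)
    return Study(
        config=config,
        expr_a=expr_a,
        expr_b=expr_b,
        surv_a=surv_a,
        surv_b=surv_b,
        truth_a=truth_a,
        truth_b=truth_b,
        genes=genes,
        corrected=corrected,
        standardized=standardized,
        modules=modules,
        subtypes=subtypes,
        activity=activity,
        centroids=centroids,
    )


@pytest.fixture(scope="session")
def label_map(study) -> dict:
    """Discovered subtype name -> planted subtype name (majority vote)."""
    ct = pd.crosstab(
        study.true_subtypes.reindex(study.subtypes.subtype_of_sample.index),
        study.subtypes.subtype_of_sample,
    )
    return ct.idxmax(axis=0).to_dict()
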