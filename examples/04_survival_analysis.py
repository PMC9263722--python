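"""Quantify the subtype-survival association.

KM curves per subtype, an overall log-rank test, the best-vs-worst
pairwise contrast, and a Cox proportional-hazards fit with the
worst-prognosis subtype as baseline — the planted hazards make one
subtype protective (HR ~ 0.48 vs the worst), mirroring the spread an
immunoreactive-vs-mesenchymal contrast shows in real cohorts.
"""

import pandas as pd

import immusub as im
from immusub.consensus import SubtypeLabels

config = im.SimulationConfig(seed=1)
_, surv, truth = im.generate_cohort(config, "cohortA")
labels = SubtypeLabels(truth.subtype_of_sample)  # ground-truth labels

report = im.subtype_survival_report(surv, labels, adjust=())
print("samples per subtype:", report["n_per_subtype"])
ov = report["overall_logrank"]
print(f"overall log-rank: chi2={ov['statistic']:.2f}, df={ov['df']}, p={ov['p']:.4f}")
pw = report["pairwise_logrank"]
print(f"best vs worst prognosis: {pw['best']} vs {pw['worst']}, p={pw['p']:.4f}")

print("\nCox fit (baseline = worst-prognosis subtype):")
cols = ["hr", "ci_low", "ci_high", "p"]
print(report["cox"].summary[cols].round(3))
print("(HR < 1: protective relative to the baseline subtype)")

# does the contrast persist within treatment-response strata?
strat = im.response_stratified_survival(
    surv, labels, subtype_pair=(pw["best"], pw["worst"])
)
print("\nsubtype x response counts:\n", strat["counts"])
for stratum, res in strat["strata"].items():
    if not res["skipped"]:
        print(f"stratum {stratum}: log-rank p = {res['logrank']['p']:.4f}")
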