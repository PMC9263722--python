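"""End-to-end orchestration: simulate -> preprocess -> discover ->
transfer/classify -> survival -> compare, with a reproducible manifest.

Every stage writes its artifacts as TSV/JSON under the output directory
and the manifest records the config, the per-stage derived seeds, and a
checksum of every file, so a run is reproducible bit-for-bit from the
manifest's config and root seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify, compare, preprocess, simulate, survival, transfer
from .consensus import ResamplingScheme, SubtypeLabels, discover
from .containers import ExpressionMatrix, GeneSet, SurvivalData

__all__ = ["RunConfig", "run_pipeline", "stage_seed"]

log = logging.getLogger(__name__)


def stage_seed(root_seed: int, stage: str) -> int:
    """Per-stage seed derived from the root seed and the stage name."""
    return (int(root_seed) * 2654435761 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class RunConfig:
    """One self-contained pipeline run.

    Either ``simulation`` drives a synthetic two-cohort study, or
    ``expr_paths`` (+ optional ``genes_path``, ``clinical_path``) point at
    user TSV inputs of the same shape.
    """

    out_dir: str = "immusub_run"
    seed: int = 0
    simulation: simulate.SimulationConfig | None = None
    expr_paths: list = field(default_factory=list)
    genes_path: str | None = None
    clinical_path: str | None = None
    k_genes: int = 4
    k_samples: int = 5
    n_bootstrap: int = 100
    item_fraction: float = 0.8
    linkage: str = "average"
    assignment_method: str = "centroid"  # centroid | cluster-match
    adjust_covariates: tuple = ("cohort",)
    validation_batch_shift: float = 1.0

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        doc = yaml.safe_load(text)
        sim = doc.pop("simulation", None)
        cfg = cls(**doc)
        if sim is not None:
            if "activity_pattern" in sim:
                sim["activity_pattern"] = np.asarray(sim["activity_pattern"], float)
            for key in ("subtype_sizes", "log_hazard_by_subtype", "response_prob_by_subtype"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            cfg.simulation = simulate.SimulationConfig(**sim)
        return cfg

    def to_dict(self) -> dict:
        doc = dataclasses.asdict(self)
        if self.simulation is not None:
            sim = dataclasses.asdict(self.simulation)
            sim["activity_pattern"] = self.simulation.activity_pattern.tolist()
            sim["batch_specs"] = {
                k: dataclasses.asdict(v) for k, v in self.simulation.batch_specs.items()
            }
            doc["simulation"] = sim
        return doc


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return (and write) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "seed": config.seed, "stages": {}}
    artifacts: dict[str, Path] = {}

    def record(stage: str, **files) -> None:
        manifest["stages"][stage] = {
            "seed": stage_seed(config.seed, stage),
            "outputs": {name: str(p) for name, p in files.items()},
        }
        artifacts.update(files)

    try:
        # ---- stage 1: simulate or load ------------------------------------
        if config.simulation is not None:
            sim_cfg = dataclasses.replace(
                config.simulation, seed=stage_seed(config.seed, "simulate")
            )
            expr_a, surv_a, truth = simulate.generate_cohort(sim_cfg, "cohortA")
            expr_b, surv_b, _ = simulate.generate_cohort(sim_cfg, "cohortB")
            matrices = [expr_a, expr_b]
            clinical = SurvivalData(
                pd.concat([surv_a.table, surv_b.table]), dict(surv_a.baselines)
            )
            clinical.baselines["cohort"] = "cohortA"
            immune_genes = GeneSet(list(expr_a.gene_ids))
            p_expr_a, p_expr_b = out / "cohortA.tsv", out / "cohortB.tsv"
            expr_a.to_tsv(p_expr_a)
            expr_b.to_tsv(p_expr_b)
            p_clin = out / "clinical.tsv"
            clinical.to_tsv(p_clin)
            p_truth = out / "truth_subtypes.tsv"
            truth.subtype_of_sample.rename("subtype").to_csv(
                p_truth, sep="\t", index_label="sample_id"
            )
            record("simulate", cohortA=p_expr_a, cohortB=p_expr_b,
                   clinical=p_clin, truth=p_truth)
        else:
            if not config.expr_paths:
                raise ValueError("either a simulation config or expr_paths required")
            matrices = [
                ExpressionMatrix.from_tsv(p, cohort=f"cohort{i + 1}")
                for i, p in enumerate(config.expr_paths)
            ]
            immune_genes = (
                GeneSet.from_txt(config.genes_path)
                if config.genes_path
                else GeneSet(sorted(set.union(*(set(m.gene_ids) for m in matrices))))
            )
            clinical = (
                SurvivalData.from_tsv(config.clinical_path)
                if config.clinical_path
                else None
            )
            truth = None
            record("simulate")

        # ---- stage 2: preprocess ------------------------------------------
        genes = preprocess.curate_genes(matrices, immune_genes)
        merged = preprocess.merge_cohorts(matrices, genes)
        corrected = preprocess.combat_adjust(merged)
        standardized = preprocess.standardize_genes(corrected)
        p_merged = out / "merged_corrected.tsv"
        standardized.to_tsv(p_merged)
        record("preprocess", merged=p_merged)

        # ---- stage 3: discover --------------------------------------------
        scheme = ResamplingScheme(
            n_bootstrap=config.n_bootstrap,
            item_fraction=config.item_fraction,
            seed=stage_seed(config.seed, "discover"),
            linkage=config.linkage,
        )
        modules, subtypes, gene_res, sample_res = discover(
            standardized, config.k_genes, config.k_samples, scheme
        )
        p_mod, p_sub = out / "modules.tsv", out / "subtypes.tsv"
        modules.to_tsv(p_mod)
        subtypes.to_tsv(p_sub)
        p_cons = out / "sample_consensus.tsv"
        pd.DataFrame(
            sample_res.consensus, index=sample_res.item_ids, columns=sample_res.item_ids
        ).to_csv(p_cons, sep="\t")
        record("discover", modules=p_mod, subtypes=p_sub, sample_consensus=p_cons)
        for name, c in subtypes.subtype_of_sample.value_counts().items():
            log.info("discover: %s has %d samples", name, c)

        # ---- stage 4: transfer --------------------------------------------
        activity = transfer.module_activity(standardized, modules)
        centroids = transfer.subtype_centroids(activity, subtypes)
        p_act, p_cent = out / "activities.tsv", out / "centroids.tsv"
        activity.to_tsv(p_act)
        centroids.to_tsv(p_cent)
        if config.simulation is not None:
            val_expr, val_surv, val_truth = simulate.generate_validation_cohort(
                sim_cfg, truth, simulate.BatchSpec(shift=config.validation_batch_shift),
                cohort_id="validation",
            )
            val_merged = preprocess.merge_cohorts(
                [corrected, val_expr.restrict_genes(list(genes))], genes
            )
            val_std = preprocess.standardize_genes(preprocess.combat_adjust(val_merged))
            val_cols = val_expr.sample_ids
            val_activity = transfer.ActivityMatrix(
                transfer.module_activity(val_std, modules).activities[val_cols]
            )
            if config.assignment_method == "cluster-match":
                assigned = transfer.cluster_then_match(
                    val_activity, centroids, k=max(2, config.k_samples - 1)
                )
            else:
                assigned = transfer.assign_by_centroid(val_activity, centroids)
            p_assigned = out / "validation_subtypes.tsv"
            assigned.to_tsv(p_assigned)
            record("transfer", activities=p_act, centroids=p_cent,
                   validation_subtypes=p_assigned)
        else:
            record("transfer", activities=p_act, centroids=p_cent)

        # ---- stage 5: classify --------------------------------------------
        counts = subtypes.subtype_of_sample.value_counts()
        trainable = subtypes.subtype_of_sample[
            subtypes.subtype_of_sample.isin(counts.index[counts >= 2])
        ]
        if trainable.nunique() < counts.size:
            log.warning(
                "classify: dropping %d singleton subtype(s) from training",
                counts.size - trainable.nunique(),
            )
        model = classify.fit_multinomial(
            transfer.ActivityMatrix(activity.activities[trainable.index]),
            SubtypeLabels(trainable, provenance=subtypes.provenance),
        )
        proba = classify.predict_proba(model, activity)
        ev = classify.evaluate_ovr(
            subtypes.subtype_of_sample.reindex(proba.index), proba
        )
        p_model, p_eval = out / "classifier.json", out / "classifier_eval.tsv"
        model.to_json(p_model)
        ev.to_tsv(p_eval)
        record("classify", model=p_model, eval=p_eval)

        # ---- stage 6: survival --------------------------------------------
        if clinical is not None:
            report = survival.subtype_survival_report(
                clinical, subtypes, adjust=config.adjust_covariates
            )
            p_cox = out / "cox_summary.tsv"
            p_surv = out / "survival_report.json"
            if report["cox"] is not None:
                report["cox"].summary.to_csv(p_cox, sep="\t", index_label="term")
            summary = {
                "n_per_subtype": report["n_per_subtype"],
                "overall_logrank": report["overall_logrank"],
                "pairwise_logrank": report["pairwise_logrank"],
            }
            p_surv.write_text(json.dumps(summary, indent=1, default=float))
            record("survival", cox=p_cox, report=p_surv)
        else:
            record("survival")

        # ---- stage 7: compare ---------------------------------------------
        if clinical is not None and "response" in clinical.table:
            rep = report["pairwise_logrank"]
            pair = (rep["best"], rep["worst"]) if rep else ("IS2", "IS4")
            strat = compare.response_stratified_survival(
                clinical, subtypes, subtype_pair=pair
            )
            p_cmp = out / "response_stratified.json"
            doc = {
                "counts": strat["counts"].to_dict(),
                "association_p": strat["association"].p,
                "strata": {
                    str(r): (
                        {"skipped": True}
                        if s["skipped"]
                        else {"skipped": False, "logrank_p": s["logrank"]["p"]}
                    )
                    for r, s in strat["strata"].items()
                },
            }
            p_cmp.write_text(json.dumps(doc, indent=1, default=float))
            record("compare", response_stratified=p_cmp)
        else:
            record("compare")
    except Exception as err:  # annotate the failing stage, keep partial output
        done = list(manifest["stages"])
        stage = "simulate preprocess discover transfer classify survival compare".split()[
            len(done)
        ] if len(done) < 7 else "finalize"
        raise RuntimeError(f"pipeline failed at stage '{stage}': {err}") from err

    for stage_entry in manifest["stages"].values():
        stage_entry["checksums"] = {
            name: _checksum(Path(p)) for name, p in stage_entry["outputs"].items()
        }
    p_manifest = out / "manifest.json"
    p_manifest.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
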