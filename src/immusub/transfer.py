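"""Cross-cohort subtype transfer via module activities and centroids.

Module activity is the per-sample mean expression of a module's genes; a
subtype centroid is the per-subtype mean activity vector.  New cohorts are
labelled either sample-by-sample (maximal Pearson correlation with the
discovery centroids) or cluster-then-match (hierarchically cluster the new
cohort's activities, then greedily match cluster centroids to discovery
centroids).

The intermediate subtype (by convention IS3) has no characteristic
activity signature, so its centroid is excluded from matching by default;
an optional ambiguity threshold routes low-confidence samples to it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage

from .consensus import ModuleSet, SubtypeLabels
from .containers import ExpressionMatrix

__all__ = [
    "ActivityMatrix",
    "CentroidModel",
    "module_activity",
    "subtype_centroids",
    "assign_by_centroid",
    "cluster_then_match",
]

log = logging.getLogger(__name__)


@dataclass
class ActivityMatrix:
    """Module-by-sample mean expression (module activity)."""

    activities: pd.DataFrame  # modules x samples

    def __post_init__(self):
        if not np.isfinite(self.activities.to_numpy(float)).all():
            raise ValueError("activities must be finite")

    @property
    def module_ids(self) -> pd.Index:
        return self.activities.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.activities.columns

    def to_tsv(self, path) -> None:
        self.activities.to_csv(path, sep="\t", index_label="module")

    @classmethod
    def from_tsv(cls, path) -> "ActivityMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0))


@dataclass
class CentroidModel:
    """Subtype-by-module centroid table from a discovery cohort."""

    centroids: pd.DataFrame  # subtypes x modules
    source_cohort: str = "discovery"

    def __post_init__(self):
        if not np.isfinite(self.centroids.to_numpy(float)).all():
            raise ValueError("centroids must be finite")

    @property
    def subtype_ids(self) -> pd.Index:
        return self.centroids.index

    @property
    def module_ids(self) -> pd.Index:
        return self.centroids.columns

    def to_tsv(self, path) -> None:
        self.centroids.to_csv(path, sep="\t", index_label="subtype")

    @classmethod
    def from_tsv(cls, path, source_cohort="discovery") -> "CentroidModel":
        return cls(pd.read_csv(path, sep="\t", index_col=0), source_cohort)


def module_activity(expr: ExpressionMatrix, modules: ModuleSet) -> ActivityMatrix:
    """Average expression of each module's genes, per sample."""
    rows = {}
    for m in modules.module_ids:
        genes = [g for g in modules.genes_in(m) if g in expr.gene_ids]
        if not genes:
            raise ValueError(f"module {m} has no genes present in the matrix")
        rows[m] = expr.values.loc[genes].mean(axis=0)
    return ActivityMatrix(pd.DataFrame(rows).T)


def subtype_centroids(
    activity: ActivityMatrix, labels: SubtypeLabels, source_cohort: str = "discovery"
) -> CentroidModel:
    """Per-subtype mean of the activity columns."""
    lab = labels.subtype_of_sample.reindex(activity.sample_ids)
    if lab.isna().any():
        raise ValueError("labels missing for some samples")
    cent = {}
    for s in sorted(lab.unique()):
        members = lab.index[lab == s]
        if len(members) == 0:
            raise ValueError(f"subtype {s} has no samples")
        cent[s] = activity.activities[members].mean(axis=1)
    return CentroidModel(pd.DataFrame(cent).T, source_cohort)


def _pearson(u: np.ndarray, v: np.ndarray) -> float:
    su, sv = u.std(), v.std()
    if su == 0 or sv == 0:
        return np.nan
    return float(np.corrcoef(u, v)[0, 1])


def assign_by_centroid(
    activity_new: ActivityMatrix,
    model: CentroidModel,
    ambiguity_threshold: float = -1.0,
    exclude: tuple = ("IS3",),
    ambiguous_label: str = "IS3",
) -> SubtypeLabels:
    """Label each sample by maximal Pearson correlation with the centroids.

    Subtypes in ``exclude`` (default the signature-less intermediate
    subtype) do not compete; a sample whose best correlation falls below
    ``ambiguity_threshold`` receives ``ambiguous_label`` instead (disabled
    by default).  Samples with a zero-variance activity vector have no
    defined correlation and are left unassigned (NaN).
    """
    missing = set(model.module_ids) - set(activity_new.module_ids)
    if missing:
        raise ValueError(f"activity matrix lacks modules: {sorted(missing)}")
    if len(model.module_ids) < 3:
        raise ValueError("need >= 3 modules for a meaningful correlation")
    cents = model.centroids
    candidates = [s for s in cents.index if s not in exclude] or list(cents.index)
    A = activity_new.activities.loc[cents.columns]
    out = {}
    for sid in A.columns:
        v = A[sid].to_numpy(float)
        cors = [(_pearson(cents.loc[s].to_numpy(float), v), s) for s in candidates]
        best_r, best_s = max(cors, key=lambda t: (np.nan_to_num(t[0], nan=-2.0), -candidates.index(t[1])))
        if np.isnan(best_r):
            log.warning("sample %s has zero-variance activities; unassigned", sid)
            out[sid] = np.nan
        elif best_r < ambiguity_threshold:
            out[sid] = ambiguous_label
        else:
            out[sid] = best_s
    return SubtypeLabels(
        pd.Series(out).reindex(A.columns), provenance="centroid"
    )


def cluster_then_match(
    activity_new: ActivityMatrix,
    model: CentroidModel,
    k: int,
    allow_reuse: bool = False,
    exclude: tuple = ("IS3",),
) -> SubtypeLabels:
    """Cluster the new cohort on activities, then match clusters to subtypes.

    Hierarchical (Euclidean, average linkage) clustering into k clusters;
    each cluster centroid is matched to the discovery subtype with maximal
    Pearson correlation, greedily from the highest correlation down.  By
    default each subtype is used at most once; ``allow_reuse`` lifts that.
    """
    A = activity_new.activities.loc[model.module_ids]
    n = A.shape[1]
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} samples")
    Z = scipy_linkage(A.T.to_numpy(float), method="average", metric="euclidean")
    cl = fcluster(Z, t=k, criterion="maxclust")
    clusters = pd.Series(cl, index=A.columns)

    cents = model.centroids
    candidates = [s for s in cents.index if s not in exclude] or list(cents.index)
    pairs = []  # (correlation, cluster, subtype)
    for c in np.unique(cl):
        v = A.loc[:, clusters == c].mean(axis=1).to_numpy(float)
        for s in candidates:
            r = _pearson(cents.loc[s, model.module_ids].to_numpy(float), v)
            pairs.append((np.nan_to_num(r, nan=-2.0), int(c), s))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))

    match: dict[int, str] = {}
    used: set[str] = set()
    for r, c, s in pairs:
        if c in match:
            continue
        if not allow_reuse and s in used:
            continue
        match[c] = s
        used.add(s)
    # leftover clusters (more clusters than subtypes, reuse disabled):
    for c in np.unique(cl):
        if int(c) not in match:
            best = max(
                (p for p in pairs if p[1] == int(c)), key=lambda t: t[0]
            )
            match[int(c)] = best[2]

    labels = clusters.map(lambda c: match[int(c)])
    return SubtypeLabels(labels, provenance="cluster_match")
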