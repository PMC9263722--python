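"""Monti-style consensus clustering for gene modules and sample subtypes.

The stability evidence for a partition into k clusters is built by
repeatedly subsampling items, running agglomerative (Euclidean)
clustering on each subsample, and recording for every item pair the
fraction of co-draws in which the pair landed in the same cluster.  The
empirical CDF of these consensus values, and the relative gain in its
area as k grows (the delta-area curve), drive the choice of k; the final
partition is a tree cut on consensus dissimilarity.

Applied twice per discovery run: to gene rows (-> gene modules GM1..GMk)
and to sample columns (-> immune subtypes IS1..ISk).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import squareform

from .containers import ExpressionMatrix

__all__ = [
    "ResamplingScheme",
    "ConsensusResult",
    "ModuleSet",
    "SubtypeLabels",
    "consensus_matrix",
    "consensus_sweep",
    "consensus_cdf",
    "select_k",
    "cut_consensus",
    "discover",
]

log = logging.getLogger(__name__)

_LINKAGES = ("average", "complete", "ward")


@dataclass(frozen=True)
class ResamplingScheme:
    """Subsampled-clustering settings for one consensus run.

    ``item_fraction`` of items are drawn per resample, without replacement
    by default (set ``replace=True`` for classical bootstrap draws).  The
    resample draws depend only on ``seed`` and the item count, never on k,
    so consensus matrices for different k are computed on identical draws.
    """

    n_bootstrap: int = 500
    item_fraction: float = 0.8
    seed: int = 0
    linkage: str = "average"
    distance: str = "euclidean"
    replace: bool = False

    def __post_init__(self):
        if not 0 < self.item_fraction <= 1:
            raise ValueError("item_fraction must lie in (0, 1]")
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")
        if self.linkage not in _LINKAGES:
            raise ValueError(f"linkage must be one of {_LINKAGES}")
        if self.distance != "euclidean":
            raise ValueError("only Euclidean distance is supported")


@dataclass
class ConsensusResult:
    """Consensus evidence for one value of k."""

    k: int
    item_ids: pd.Index
    consensus: np.ndarray  # item x item, in [0, 1], symmetric, unit diagonal
    co_cluster_counts: np.ndarray  # pairs co-clustered
    co_sample_counts: np.ndarray  # pairs co-drawn
    labels: pd.Series | None = None  # filled by cut_consensus / discover
    cdf_grid: np.ndarray | None = None
    cdf_values: np.ndarray | None = None
    area_under_cdf: float | None = None


@dataclass
class ModuleSet:
    """Gene -> module assignment (GM1..GMK, largest module first)."""

    module_of_gene: pd.Series
    n_modules: int

    def genes_in(self, module_id: str) -> pd.Index:
        return self.module_of_gene.index[self.module_of_gene == module_id]

    @property
    def module_ids(self) -> list:
        return [f"GM{i + 1}" for i in range(self.n_modules)]

    def to_tsv(self, path) -> None:
        self.module_of_gene.rename("module").to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path) -> "ModuleSet":
        s = pd.read_csv(path, sep="\t", index_col=0)["module"]
        return cls(s, s.nunique())


@dataclass
class SubtypeLabels:
    """Sample -> subtype label with assignment provenance."""

    subtype_of_sample: pd.Series
    provenance: str = "discovery"  # discovery | centroid | cluster_match | classifier

    @property
    def subtype_ids(self) -> list:
        return sorted(self.subtype_of_sample.dropna().unique())

    def to_tsv(self, path) -> None:
        out = self.subtype_of_sample.rename("subtype").to_frame()
        out["provenance"] = self.provenance
        out.to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, path) -> "SubtypeLabels":
        df = pd.read_csv(path, sep="\t", index_col=0)
        prov = df["provenance"].iloc[0] if "provenance" in df else "discovery"
        return cls(df["subtype"], prov)


def _resample_indices(n: int, scheme: ResamplingScheme) -> list[np.ndarray]:
    rng = np.random.default_rng(int(scheme.seed) % (2**31))
    m = int(np.ceil(scheme.item_fraction * n))
    return [
        rng.choice(n, size=m, replace=scheme.replace)
        for _ in range(scheme.n_bootstrap)
    ]


def _cluster_subsample(X: np.ndarray, scheme: ResamplingScheme):
    """Linkage tree for one subsample; cut later at any k."""
    return scipy_linkage(X, method=scheme.linkage, metric="euclidean")


def consensus_sweep(
    X, ks, scheme: ResamplingScheme, item_ids=None
) -> dict[int, ConsensusResult]:
    """Consensus matrices for several k on shared resample draws.

    Each resample's linkage tree is built once and cut at every requested
    k, so the per-k results are identical to separate ``consensus_matrix``
    calls with the same scheme, at a fraction of the cost.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("X must be an items-by-features matrix")
    n = X.shape[0]
    ks = sorted(set(int(k) for k in ks))
    for k in ks:
        if k < 2:
            raise ValueError("k must be >= 2")
        if k > n:
            raise ValueError(f"k={k} exceeds the {n} items")
    if item_ids is None:
        item_ids = pd.RangeIndex(n)
    item_ids = pd.Index(item_ids)

    conn = {k: np.zeros((n, n), dtype=np.int64) for k in ks}
    cnt = np.zeros((n, n), dtype=np.int64)
    for idx in _resample_indices(n, scheme):
        uniq = np.unique(idx)
        Z = _cluster_subsample(X[uniq], scheme)
        grid = np.ix_(uniq, uniq)
        cnt[grid] += 1
        for k in ks:
            lab = fcluster(Z, t=min(k, len(uniq)), criterion="maxclust")
            same = lab[:, None] == lab[None, :]
            conn[k][grid] += same

    results = {}
    never = (cnt == 0) & ~np.eye(n, dtype=bool)
    if never.any():
        log.warning(
            "consensus: %d item pairs never co-drawn; their consensus is 0",
            int(never.sum() // 2),
        )
    for k in ks:
        with np.errstate(invalid="ignore"):
            C = np.where(cnt > 0, conn[k] / np.maximum(cnt, 1), 0.0)
        np.fill_diagonal(C, 1.0)
        res = ConsensusResult(
            k=k,
            item_ids=item_ids,
            consensus=C,
            co_cluster_counts=conn[k],
            co_sample_counts=cnt.copy(),
        )
        consensus_cdf(res)
        results[k] = res
    return results


def consensus_matrix(X, k: int, scheme: ResamplingScheme, item_ids=None) -> ConsensusResult:
    """Consensus matrix for a single k (see :func:`consensus_sweep`)."""
    return consensus_sweep(X, [k], scheme, item_ids=item_ids)[int(k)]


def consensus_cdf(result: ConsensusResult):
    """Empirical CDF of upper-triangle consensus values on a 0.01 grid.

    Area under the CDF by the trapezoid rule; cached on the result.
    """
    iu = np.triu_indices_from(result.consensus, k=1)
    vals = result.consensus[iu]
    grid = np.round(np.linspace(0.0, 1.0, 101), 2)
    cdf = np.searchsorted(np.sort(vals), grid, side="right") / max(len(vals), 1)
    area = float(np.trapezoid(cdf, grid))
    result.cdf_grid, result.cdf_values, result.area_under_cdf = grid, cdf, area
    return grid, area


@dataclass
class KSelection:
    k: int
    areas: dict
    deltas: dict
    threshold: float


def select_k(results: dict[int, ConsensusResult], threshold: float = 0.05) -> KSelection:
    """Choose k from the relative delta-area of the consensus CDF.

    Delta(k_min) = A(k_min); Delta(k) = (A(k) - A(k-1)) / A(k-1).  The
    chosen k is the largest one whose relative gain exceeds ``threshold``;
    the full curve is returned for manual override.
    """
    ks = sorted(results)
    if len(ks) < 2 or any(b - a != 1 for a, b in zip(ks, ks[1:])):
        raise ValueError("need results for >= 2 consecutive k values")
    areas = {}
    for k in ks:
        r = results[k]
        if r.area_under_cdf is None:
            consensus_cdf(r)
        areas[k] = r.area_under_cdf
    deltas = {ks[0]: areas[ks[0]]}
    for prev, k in zip(ks, ks[1:]):
        if areas[prev] > 0:
            deltas[k] = (areas[k] - areas[prev]) / areas[prev]
        else:
            deltas[k] = np.inf if areas[k] > 0 else 0.0
    above = [k for k in ks if deltas[k] > threshold]
    chosen = max(above) if above else ks[0]
    return KSelection(k=chosen, areas=areas, deltas=deltas, threshold=threshold)


def cut_consensus(result: ConsensusResult, k: int) -> pd.Series:
    """Final partition: average-linkage tree cut on 1 - consensus.

    Cluster ids are renumbered by decreasing size (ties broken by the
    smallest member position) so label 1 is always the largest cluster.
    """
    n = result.consensus.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} items")
    D = 1.0 - result.consensus
    D = np.clip((D + D.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(D, 0.0)
    Z = scipy_linkage(squareform(D, checks=False), method="average")
    raw = fcluster(Z, t=k, criterion="maxclust")
    labels = _renumber_by_size(raw)
    result.labels = pd.Series(labels, index=result.item_ids, name="cluster")
    return result.labels


def _renumber_by_size(raw: np.ndarray) -> np.ndarray:
    ids, counts = np.unique(raw, return_counts=True)
    first_member = {i: int(np.argmax(raw == i)) for i in ids}
    order = sorted(ids, key=lambda i: (-counts[list(ids).index(i)], first_member[i]))
    mapping = {old: new + 1 for new, old in enumerate(order)}
    return np.array([mapping[v] for v in raw])


def discover(
    expr: ExpressionMatrix,
    k_genes: int = 4,
    k_samples: int = 5,
    scheme: ResamplingScheme = ResamplingScheme(),
    gene_scheme: ResamplingScheme | None = None,
) -> tuple[ModuleSet, SubtypeLabels, ConsensusResult, ConsensusResult]:
    """Joint discovery of gene modules and sample subtypes.

    Genes are clustered as rows (features = samples) and samples as columns
    (features = genes) of the same standardized matrix.  The gene run uses
    ``gene_scheme`` when given, otherwise the sample scheme with an offset
    seed so the two runs draw independent resamples.
    """
    if gene_scheme is None:
        gene_scheme = replace(scheme, seed=scheme.seed + 104729)
    X = expr.values.to_numpy(dtype=float)

    gene_res = consensus_matrix(X, k_genes, gene_scheme, item_ids=expr.gene_ids)
    gene_labels = cut_consensus(gene_res, k_genes)
    modules = ModuleSet(
        module_of_gene=gene_labels.map(lambda c: f"GM{c}"), n_modules=k_genes
    )

    sample_res = consensus_matrix(X.T, k_samples, scheme, item_ids=expr.sample_ids)
    sample_labels = cut_consensus(sample_res, k_samples)
    subtypes = SubtypeLabels(
        subtype_of_sample=sample_labels.map(lambda c: f"IS{c}"), provenance="discovery"
    )
    return modules, subtypes, gene_res, sample_res
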