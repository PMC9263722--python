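"""Cohort merging and batch correction ahead of clustering.

Cohorts measured on different platforms (RNA-seq vs microarray) are merged
on a curated immune-gene set and adjusted with parametric empirical-Bayes
location/scale batch correction (the ComBat model): per-gene
standardization against a grand-mean model, normal shrinkage of per-batch
gene means and inverse-gamma shrinkage of per-batch gene variances via the
standard iterative posterior update, then adjustment and back-transform.
No biological covariates enter the design; a mean-only mode is available.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GeneSet

__all__ = ["curate_genes", "merge_cohorts", "combat_adjust", "standardize_genes", "log2p1"]

log = logging.getLogger(__name__)


def curate_genes(matrices: list[ExpressionMatrix], immune_genes: GeneSet) -> GeneSet:
    """Intersect a curated gene list with the genes measured in every cohort.

    Returns the sorted intersection; raises if it is empty, naming the
    first cohort that removed the final genes.
    """
    if not matrices:
        raise ValueError("need at least one expression matrix")
    kept = set(immune_genes)
    for i, m in enumerate(matrices):
        cohort = m.cohort_of_sample.iloc[0] if m.n_samples else f"matrix{i}"
        before = len(kept)
        kept &= set(m.gene_ids)
        log.info("curate_genes: %s retains %d/%d genes", cohort, len(kept), before)
        if not kept:
            raise ValueError(
                f"no curated genes remain after intersecting with cohort '{cohort}'"
            )
    return GeneSet(sorted(kept))


def merge_cohorts(matrices: list[ExpressionMatrix], genes: GeneSet) -> ExpressionMatrix:
    """Column-concatenate cohorts restricted to a shared gene set."""
    restricted = [m.restrict_genes(list(genes)) for m in matrices]
    all_samples = pd.Index(np.concatenate([m.sample_ids for m in restricted]))
    dup = all_samples[all_samples.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate sample ids across cohorts: {list(dup[:5])}")
    values = pd.concat([m.values for m in restricted], axis=1)
    cohorts = pd.concat([m.cohort_of_sample for m in restricted])
    return ExpressionMatrix(values, cohorts)


def combat_adjust(
    expr: ExpressionMatrix,
    batch: pd.Series | None = None,
    mean_only: bool = False,
    max_iter: int = 100,
    tol: float = 1e-4,
) -> ExpressionMatrix:
    """Remove gene-wise batch location/scale effects by empirical Bayes.

    Parameters
    ----------
    expr
        Merged expression matrix (genes x samples).
    batch
        Sample -> batch label; defaults to the cohort labels carried by
        ``expr``.  A single batch makes the call a no-op.
    mean_only
        Shrink and remove only the location effect, leaving scales alone.

    Genes with zero variance inside some batch cannot support the variance
    prior; they fall back to the unshrunk location estimate with unit scale
    for that batch (with a warning).
    """
    if batch is None:
        batch = expr.cohort_of_sample
    batch = pd.Series(batch).reindex(expr.sample_ids)
    if batch.isna().any():
        raise ValueError("every sample needs a batch label")
    levels = batch.unique()
    if len(levels) < 2:
        return ExpressionMatrix(
            expr.values.copy(), expr.cohort_of_sample, expr.log_transformed
        )
    counts = batch.value_counts()
    if (counts < 2).any():
        raise ValueError("each batch needs at least 2 samples")

    X = expr.values.to_numpy(dtype=float)
    n_genes, n = X.shape
    masks = [(batch == lv).to_numpy() for lv in levels]
    n_b = np.array([m.sum() for m in masks])

    # grand-mean model: weighted batch means, pooled residual variance (MLE)
    batch_means = np.stack([X[:, m].mean(axis=1) for m in masks], axis=1)
    grand_mean = batch_means @ (n_b / n)
    resid = X.copy()
    for i, m in enumerate(masks):
        resid[:, m] -= batch_means[:, [i]]
    var_pooled = (resid**2).mean(axis=1)
    degenerate_pool = var_pooled <= 0
    if degenerate_pool.any():
        log.warning("combat: %d genes constant everywhere; left unchanged", degenerate_pool.sum())
        var_pooled = np.where(degenerate_pool, 1.0, var_pooled)

    Z = (X - grand_mean[:, None]) / np.sqrt(var_pooled)[:, None]
    Z_adj = Z.copy()

    for i, m in enumerate(masks):
        Zi = Z[:, m]
        gamma_hat = Zi.mean(axis=1)
        delta_hat = Zi.var(axis=1, ddof=1)
        bad = delta_hat <= 0
        if bad.any():
            log.warning(
                "combat: batch '%s' has %d zero-variance genes; unshrunk fallback",
                levels[i],
                int(bad.sum()),
            )

        # hyperpriors by method of moments
        gamma_bar = gamma_hat.mean()
        tau2 = gamma_hat.var(ddof=1)
        d_mean = delta_hat[~bad].mean() if (~bad).any() else 1.0
        d_var = delta_hat[~bad].var(ddof=1) if (~bad).sum() > 1 else 0.0

        if mean_only or d_var <= 0:
            gamma_star = (
                (n_b[i] * tau2 * gamma_hat + gamma_bar)
                / (n_b[i] * tau2 + 1.0)
                if tau2 > 0
                else gamma_hat
            )
            delta_star = np.ones_like(delta_hat)
        else:
            a_prior = (2 * d_var + d_mean**2) / d_var
            b_prior = (d_mean * d_var + d_mean**3) / d_var
            gamma_star = gamma_hat.copy()
            delta_star = delta_hat.copy()
            delta_star[bad] = 1.0
            for _ in range(max_iter):
                g_new = (n_b[i] * tau2 * gamma_hat + delta_star * gamma_bar) / (
                    n_b[i] * tau2 + delta_star
                )
                ssq = ((Zi - g_new[:, None]) ** 2).sum(axis=1)
                d_new = (b_prior + 0.5 * ssq) / (n_b[i] / 2.0 + a_prior - 1.0)
                change = max(
                    np.abs(g_new - gamma_star).max(), np.abs(d_new - delta_star).max()
                )
                gamma_star, delta_star = g_new, d_new
                if change < tol:
                    break
            gamma_star[bad] = gamma_hat[bad]
            delta_star[bad] = 1.0

        if mean_only:
            Z_adj[:, m] = Zi - gamma_star[:, None]
        else:
            Z_adj[:, m] = (Zi - gamma_star[:, None]) / np.sqrt(delta_star)[:, None]

    X_adj = Z_adj * np.sqrt(var_pooled)[:, None] + grand_mean[:, None]
    X_adj[degenerate_pool, :] = X[degenerate_pool, :]
    return ExpressionMatrix(
        pd.DataFrame(X_adj, index=expr.gene_ids, columns=expr.sample_ids),
        expr.cohort_of_sample,
        expr.log_transformed,
    )


def standardize_genes(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Z-score each gene row to mean 0, SD 1 (population SD, divide by n).

    Constant rows carry no clustering information and are dropped with a
    warning.  The transform is idempotent.
    """
    X = expr.values.to_numpy(dtype=float)
    sd = X.std(axis=1, ddof=0)
    keep = sd > 0
    if not keep.all():
        log.warning("standardize_genes: dropping %d constant genes", int((~keep).sum()))
    X = X[keep]
    Z = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, ddof=0, keepdims=True)
    return ExpressionMatrix(
        pd.DataFrame(Z, index=expr.gene_ids[keep], columns=expr.sample_ids),
        expr.cohort_of_sample,
        expr.log_transformed,
    )


def log2p1(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Apply log2(x + 1) for linear-scale (FPKM-style) input."""
    return ExpressionMatrix(
        np.log2(expr.values + 1.0), expr.cohort_of_sample, log_transformed=True
    )
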