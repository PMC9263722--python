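"""Shared data containers for expression, survival, and label tables.

All tabular data is carried in pandas objects; the thin dataclass wrappers
below add the invariants the pipeline relies on (unique ids, finite values,
cohort bookkeeping) and round-trip to plain TSV so every intermediate
artifact stays inspectable with standard tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "SurvivalData", "GeneSet"]


@dataclass
class ExpressionMatrix:
    """Gene-by-sample log-scale expression with per-sample cohort labels.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample id.
    cohort_of_sample
        Series mapping sample id -> cohort label, aligned with the columns
        of ``values``.
    log_transformed
        Metadata flag recording whether the values are on a log scale.
    """

    values: pd.DataFrame
    cohort_of_sample: pd.Series
    log_transformed: bool = True

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicated gene ids")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicated sample ids")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression values must be finite")
        self.cohort_of_sample = pd.Series(self.cohort_of_sample).reindex(
            self.values.columns
        )
        if self.cohort_of_sample.isna().any():
            raise ValueError("every sample needs a cohort label")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def restrict_genes(self, genes) -> "ExpressionMatrix":
        genes = list(genes)
        missing = set(genes) - set(self.gene_ids)
        if missing:
            raise KeyError(f"genes absent from matrix: {sorted(missing)[:5]}")
        return ExpressionMatrix(
            self.values.loc[genes], self.cohort_of_sample, self.log_transformed
        )

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene_id")
        cohorts = Path(path).with_suffix(".cohorts.tsv")
        self.cohort_of_sample.rename("cohort").to_csv(
            cohorts, sep="\t", index_label="sample_id"
        )

    @classmethod
    def from_tsv(cls, path, cohort_path=None, cohort: str = "cohort1") -> "ExpressionMatrix":
        values = pd.read_csv(path, sep="\t", index_col=0)
        if cohort_path is None:
            candidate = Path(path).with_suffix(".cohorts.tsv")
            cohort_path = candidate if candidate.exists() else None
        if cohort_path is not None:
            cohorts = pd.read_csv(cohort_path, sep="\t", index_col=0)["cohort"]
        else:
            cohorts = pd.Series(cohort, index=values.columns)
        return cls(values, cohorts)


@dataclass
class SurvivalData:
    """Per-sample follow-up time, event indicator, and covariates.

    ``table`` is indexed by sample id and must contain ``time`` (positive,
    finite; months) and ``event`` (0 censored / 1 event).  Any further
    columns are covariates; categorical covariates must have an entry in
    ``baselines`` naming their reference level before they are used in a
    regression.
    """

    table: pd.DataFrame
    baselines: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if "time" not in self.table or "event" not in self.table:
            raise ValueError("survival table needs 'time' and 'event' columns")
        t = self.table["time"].to_numpy(dtype=float)
        if not np.isfinite(t).all() or (t <= 0).any():
            raise ValueError("times must be positive and finite")
        ev = self.table["event"].to_numpy()
        if not np.isin(ev, [0, 1]).all():
            raise ValueError("event indicator must be 0/1")
        if self.table.index.duplicated().any():
            raise ValueError("duplicated sample ids")

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    @property
    def time(self) -> pd.Series:
        return self.table["time"]

    @property
    def event(self) -> pd.Series:
        return self.table["event"]

    def subset(self, sample_ids) -> "SurvivalData":
        return SurvivalData(self.table.loc[list(sample_ids)], dict(self.baselines))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, path, baselines=None) -> "SurvivalData":
        return cls(pd.read_csv(path, sep="\t", index_col=0), baselines or {})


@dataclass
class GeneSet:
    """A curated, duplicate-free collection of gene symbols."""

    symbols: list

    def __post_init__(self) -> None:
        if len(self.symbols) == 0:
            raise ValueError("gene set is empty")
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("gene set contains duplicates")
        self.symbols = list(self.symbols)

    def __len__(self) -> int:
        return len(self.symbols)

    def __iter__(self):
        return iter(self.symbols)

    def to_txt(self, path) -> None:
        Path(path).write_text("\n".join(map(str, self.symbols)) + "\n")

    @classmethod
    def from_txt(cls, path) -> "GeneSet":
        lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
        return cls([ln for ln in lines if ln])
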