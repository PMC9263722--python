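"""Time-to-event analysis tying subtypes to outcome.

Kaplan-Meier product-limit curves and (multi-group) log-rank tests are
delegated to lifelines; Cox proportional-hazards fits use the partial
likelihood machinery of statsmodels (``PHReg``), which supports both the
Efron (default) and Breslow tie conventions.  Categorical covariates are
expanded against explicitly declared baseline levels — nothing is
defaulted silently, because the natural reference level changes between
analyses (e.g. worst-prognosis subtype, stage III vs IV).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from statsmodels.duration.hazard_regression import PHReg

from .consensus import SubtypeLabels
from .containers import SurvivalData

__all__ = [
    "KMCurve",
    "CoxFit",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "subtype_survival_report",
]

log = logging.getLogger(__name__)

_Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class KMCurve:
    """Product-limit estimate over the distinct event times of one group."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    group: object = None
    all_censored: bool = False

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def restricted_mean(self, tau: float) -> float:
        """Area under the curve up to tau (restricted mean survival time)."""
        times = np.concatenate([[0.0], self.event_times, [tau]])
        surv = np.concatenate([[1.0], self.survival, [self.survival_at(tau)]])
        keep = times <= tau
        times, surv = times[keep], surv[keep]
        if times[-1] < tau:
            times = np.append(times, tau)
            surv = np.append(surv, surv[-1])
        return float(np.sum(np.diff(times) * surv[:-1]))


@dataclass
class CoxFit:
    """Cox proportional-hazards results for one set of covariates.

    ``summary`` has one row per covariate column (indicator levels are
    named ``covariate[level]``) with log_hr, se, hr, ci_low, ci_high, p,
    and an ``unstable`` flag for monotone-likelihood levels.
    """

    summary: pd.DataFrame
    ties: str
    n: int
    n_events: int
    baselines: dict = field(default_factory=dict)


def km_estimate(data: SurvivalData, group: pd.Series | None = None):
    """Kaplan-Meier curves, one per group (a single curve when group=None).

    Subjects censored exactly at an event time count as at risk for that
    time (the standard convention).  An all-censored group yields a flat
    curve at 1, flagged via ``all_censored``.
    """
    if len(data.table) == 0:
        raise ValueError("no subjects")
    if group is None:
        return _km_one(data.time, data.event, None)
    group = pd.Series(group).reindex(data.sample_ids)
    return {
        g: _km_one(data.time[group == g], data.event[group == g], g)
        for g in sorted(group.dropna().unique())
    }


def _km_one(time, event, group) -> KMCurve:
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    tbl = kmf.event_table
    ev = tbl[tbl["observed"] > 0]
    all_censored = int(event.sum()) == 0
    if all_censored:
        log.warning("group %r has no events; survival curve is flat at 1", group)
    surv = kmf.survival_function_["KM_estimate"]
    return KMCurve(
        event_times=ev.index.to_numpy(float),
        survival=surv.loc[ev.index].to_numpy(float),
        at_risk=ev["at_risk"].to_numpy(int),
        n_events=ev["observed"].to_numpy(int),
        group=group,
        all_censored=all_censored,
    )


def logrank_test(data: SurvivalData, group: pd.Series):
    """Unweighted k-group log-rank test.

    Returns (chi-square statistic, degrees of freedom, p-value).
    """
    group = pd.Series(group).reindex(data.sample_ids)
    levels = group.dropna().unique()
    if len(levels) < 2:
        raise ValueError("log-rank needs >= 2 groups")
    res = multivariate_logrank_test(
        data.time.to_numpy(float), group.to_numpy(), data.event.to_numpy(int)
    )
    df = len(levels) - 1
    return float(res.test_statistic), df, float(res.p_value)


def _expand_design(data: SurvivalData, covariates) -> pd.DataFrame:
    """Numeric columns pass through; categoricals become indicator columns
    against their declared baseline level."""
    cols = {}
    for cov in covariates:
        if cov not in data.table:
            raise KeyError(f"covariate {cov!r} not in survival table")
        col = data.table[cov]
        if pd.api.types.is_numeric_dtype(col):
            cols[cov] = col.astype(float)
        else:
            if cov not in data.baselines:
                raise ValueError(
                    f"categorical covariate {cov!r} needs an explicit baseline level"
                )
            base = data.baselines[cov]
            levels = sorted(col.dropna().unique())
            if base not in levels:
                raise ValueError(f"baseline {base!r} absent from {cov!r} levels {levels}")
            for lv in levels:
                if lv != base:
                    cols[f"{cov}[{lv}]"] = (col == lv).astype(float)
    X = pd.DataFrame(cols, index=data.sample_ids)
    const = [c for c in X if X[c].nunique() <= 1]
    if const:
        raise ValueError(f"constant covariate columns: {const}")
    return X


def cox_fit(data: SurvivalData, covariates, ties: str = "efron") -> CoxFit:
    """Cox proportional-hazards fit via the partial likelihood.

    ``covariates`` is a list of column names of ``data.table``;
    categorical ones are expanded against the baselines declared on the
    data.  Monotone-likelihood levels (no events on one side, runaway
    coefficient) are reported with ``unstable=True`` rather than hidden.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    if int(data.event.sum()) == 0:
        raise ValueError("no events observed")
    X = _expand_design(data, covariates)
    model = PHReg(
        data.time.to_numpy(float),
        X.to_numpy(float),
        status=data.event.to_numpy(int),
        ties=ties,
    )
    try:
        fit = model.fit(method="newton", maxiter=200, tol=1e-12, disp=False)
    except np.linalg.LinAlgError:
        # singular Hessian: near-separation or a tiny covariate level; fall
        # back to a gradient method and let the unstable flag tell the story
        log.warning("cox_fit: Newton step singular; falling back to BFGS")
        fit = model.fit(method="bfgs", maxiter=500, disp=False)
    log_hr = np.asarray(fit.params, float)
    se = np.asarray(fit.bse, float)
    unstable = (np.abs(log_hr) > 10) | (se > 50) | ~np.isfinite(se)
    if unstable.any():
        log.warning(
            "cox_fit: unstable levels (possible monotone likelihood): %s",
            list(X.columns[unstable]),
        )
    summary = pd.DataFrame(
        {
            "log_hr": log_hr,
            "se": se,
            "hr": np.exp(log_hr),
            "ci_low": np.exp(log_hr - _Z95 * se),
            "ci_high": np.exp(log_hr + _Z95 * se),
            "p": np.asarray(fit.pvalues, float),
            "unstable": unstable,
        },
        index=X.columns,
    )
    return CoxFit(
        summary=summary,
        ties=ties,
        n=len(X),
        n_events=int(data.event.sum()),
        baselines={c: data.baselines[c] for c in covariates if c in data.baselines},
    )


def subtype_survival_report(
    data: SurvivalData,
    labels: SubtypeLabels,
    adjust=(),
    subtype_baseline: str | None = None,
    contrast_pair: tuple | None = None,
    ties: str = "efron",
) -> dict:
    """Full subtype-vs-outcome report.

    KM per subtype, overall log-rank across subtypes, a pairwise log-rank
    between the best- and worst-prognosis subtypes (by restricted mean
    survival unless ``contrast_pair`` names them), and a Cox fit with the
    subtype (baseline defaulting to the worst-prognosis subtype) plus any
    ``adjust`` covariates.
    """
    lab = labels.subtype_of_sample.reindex(data.sample_ids).dropna()
    sub = data.subset(lab.index)
    curves = km_estimate(sub, lab)
    report: dict = {"km": curves, "n_per_subtype": lab.value_counts().to_dict()}

    if len(curves) < 2:
        log.warning("single subtype present; log-rank skipped")
        report.update(overall_logrank=None, pairwise_logrank=None, cox=None)
        return report

    stat, df, p = logrank_test(sub, lab)
    report["overall_logrank"] = {"statistic": stat, "df": df, "p": p}

    tau = min(
        lab.groupby(lab).apply(lambda s: sub.time[s.index].max()).min(),
        sub.time.max(),
    )
    rmst = {g: c.restricted_mean(tau) for g, c in curves.items()}
    if contrast_pair is None:
        best = max(rmst, key=rmst.get)
        worst = min(rmst, key=rmst.get)
    else:
        best, worst = contrast_pair
    mask = lab.isin([best, worst])
    pstat, pdf, pp = logrank_test(sub.subset(lab.index[mask]), lab[mask])
    report["pairwise_logrank"] = {
        "best": best,
        "worst": worst,
        "statistic": pstat,
        "p": pp,
    }

    if subtype_baseline is None:
        subtype_baseline = worst
    cox_data = SurvivalData(
        sub.table.assign(subtype=lab),
        {**sub.baselines, "subtype": subtype_baseline},
    )
    report["cox"] = cox_fit(cox_data, ["subtype", *adjust], ties=ties)
    return report


def plot_km(curves: dict, path, title: str = "") -> None:
    """Export step-style KM curves (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for g, c in curves.items():
        t = np.concatenate([[0.0], c.event_times])
        s = np.concatenate([[1.0], c.survival])
        ax.step(t, s, where="post", label=str(g))
    ax.set_xlabel("time (months)")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize=8)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
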