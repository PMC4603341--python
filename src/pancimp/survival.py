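"""Survival and clinical-covariate association with CIMP status.

Overall survival is summarised with the Kaplan-Meier product-limit
estimator per CIMP class, compared with the two-group log-rank test, and
modelled with Cox proportional hazards (Efron tie handling; default
covariates CIMP + age).  Clinical covariates are tested with Welch's t
(numeric, e.g. age) or the chi-squared test without continuity correction
(categorical: MSI, ER/PR/HER2, T/N/M), dropping missing values per
covariate.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from ._labels import to_binary

NUMERIC_COVARIATES = ("age",)
CATEGORICAL_COVARIATES = ("msi", "er", "pr", "her2", "t_size", "n_node", "m_met")


def kaplan_meier(times, events) -> pd.DataFrame:
    """Product-limit survival estimate.

    Returns a frame indexed by event time with columns ``survival`` and
    ``at_risk``.  Ties between deaths and censorings at the same time are
    resolved events-first (the standard convention).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty input")
    if (times < 0).any():
        raise ValueError("times must be non-negative")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    table = kmf.event_table
    out = pd.DataFrame(
        {
            "survival": kmf.survival_function_["KM_estimate"].reindex(table.index).values,
            "at_risk": table["at_risk"].values,
        },
        index=table.index.rename("time"),
    )
    return out[out.index > 0] if 0 not in times else out


def logrank_test(times, events, groups) -> dict:
    """Two-group log-rank chi-square (1 df) and its p-value."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    res = multivariate_logrank_test(times, groups, events)
    return {"statistic": float(res.test_statistic), "p_value": float(res.p_value)}


@dataclass
class CoxResults:
    """CIMP hazard-ratio estimate from a Cox proportional-hazards fit."""

    log_hr: float
    hr: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    n_events: int
    covariates: list[str]

    def summary(self) -> str:
        return (
            f"Cox PH (Efron ties, covariates: {', '.join(self.covariates)}): "
            f"CIMP+ HR={self.hr:.3f} [{self.ci_low:.3f}, {self.ci_high:.3f}], "
            f"p={self.p_value:.3g} (n={self.n}, events={self.n_events})"
        )


def cox_cimp(times, events, cimp_labels, covariates: pd.DataFrame | None = None) -> CoxResults:
    """Cox PH fit of survival on CIMP status (plus optional covariates).

    Reports the CIMP-positive vs -negative hazard ratio with Wald CI/p.
    """
    y = to_binary(pd.Series(cimp_labels))
    if y.nunique() < 2:
        raise ValueError("both CIMP classes must be present")
    df = pd.DataFrame({"time": np.asarray(times, dtype=float),
                       "event": np.asarray(events, dtype=int),
                       "cimp": y.to_numpy()})
    if (df["time"] < 0).any():
        raise ValueError("times must be non-negative")
    cov_names = []
    if covariates is not None:
        for col in covariates.columns:
            df[col] = np.asarray(covariates[col], dtype=float)
            cov_names.append(col)
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")  # lifelines uses Efron ties
    s = cph.summary.loc["cimp"]
    return CoxResults(
        log_hr=float(s["coef"]),
        hr=float(np.exp(s["coef"])),
        ci_low=float(np.exp(s["coef lower 95%"])),
        ci_high=float(np.exp(s["coef upper 95%"])),
        p_value=float(s["p"]),
        n=len(df),
        n_events=int(df["event"].sum()),
        covariates=["cimp"] + cov_names,
    )


def survival_analysis(clinical: pd.DataFrame, labels: pd.Series,
                      adjust_for_age: bool = True) -> dict:
    """KM curves per class, log-rank test, and the Cox CIMP hazard ratio."""
    common = clinical.index.intersection(labels.index)
    df = clinical.loc[common]
    y = to_binary(labels.loc[common])
    curves = {}
    for name, mask in [("negative", y == 0), ("positive", y == 1)]:
        if mask.any():
            curves[name] = kaplan_meier(df.loc[mask.values, "time"],
                                        df.loc[mask.values, "event"])
    lr = logrank_test(df["time"], df["event"], y)
    cov = df[["age"]] if adjust_for_age and "age" in df else None
    cox = cox_cimp(df["time"], df["event"], y, covariates=cov)
    return {"km": curves, "logrank": lr, "cox": cox}


def clinical_associations(
    labels: pd.Series,
    clinical: pd.DataFrame,
    numeric=NUMERIC_COVARIATES,
    categorical=CATEGORICAL_COVARIATES,
    welch: bool = True,
) -> pd.DataFrame:
    """Per-covariate association tests between CIMP status and clinical data.

    Numeric covariates: two-sample Student t (Welch by default).  Categorical
    covariates: chi-squared on the contingency table, no continuity
    correction, flagged when any expected count falls below 1.  Missing
    values are dropped per covariate; entirely missing covariates are
    flagged untestable.
    """
    common = clinical.index.intersection(labels.index)
    df = clinical.loc[common]
    y = to_binary(labels.loc[common])
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("need >= 2 samples in each CIMP class")
    rows = []
    for cov in numeric:
        if cov not in df:
            continue
        vals = pd.to_numeric(df[cov], errors="coerce")
        ok = vals.notna()
        if ok.sum() == 0:
            rows.append((cov, "t", np.nan, np.nan, 0, "untestable"))
            continue
        a, b = vals[ok & (y == 1)], vals[ok & (y == 0)]
        res = stats.ttest_ind(a, b, equal_var=not welch)
        rows.append((cov, "welch_t" if welch else "t", float(res.statistic),
                     float(res.pvalue), int(ok.sum()), "ok"))
    for cov in categorical:
        if cov not in df:
            continue
        vals = df[cov].astype("object")
        ok = vals.notna()
        if ok.sum() == 0 or vals[ok].nunique() < 2:
            rows.append((cov, "chi2", np.nan, np.nan, int(ok.sum()), "untestable"))
            continue
        table = pd.crosstab(vals[ok], y[ok])
        chi2, p, _, expected = stats.chi2_contingency(table, correction=False)
        flag = "ok" if expected.min() >= 1 else "low_expected_counts"
        rows.append((cov, "chi2", float(chi2), float(p), int(ok.sum()), flag))
    return pd.DataFrame(
        rows, columns=["covariate", "test", "statistic", "p_value", "n", "status"]
    ).set_index("covariate")
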