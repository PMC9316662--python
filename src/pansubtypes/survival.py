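"""Subtype survival analysis and clinical composition summaries.

Kaplan-Meier product-limit curves and the multi-group log-rank test compare
overall survival across subtypes; donors whose samples fall in more than one
subtype are excluded first. Gender/region composition tables summarize the
clinical covariates per subtype. Estimation is delegated to lifelines;
this module owns the donor filtering, table shaping and conventions (deaths
before censorings at tied times, days stored / years reported).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

DAYS_PER_YEAR = 365.25


def filter_consistent_donors(
    sample_to_donor: pd.Series, labels: pd.Series
) -> tuple[pd.Series, list[str]]:
    """Map donors to subtypes, excluding donors spanning > 1 subtype.

    Returns (donor -> subtype, excluded donor ids). Donors with a single
    sample (or several samples all in one subtype) are kept.
    """
    df = pd.DataFrame({
        "donor": sample_to_donor.reindex(labels.index),
        "subtype": labels,
    })
    if df["donor"].isna().any():
        raise ValueError("sample_to_donor must cover every labelled sample")
    per_donor = df.groupby("donor")["subtype"].agg(["nunique", "first"])
    excluded = sorted(per_donor.index[per_donor["nunique"] > 1])
    kept = per_donor.loc[per_donor["nunique"] == 1, "first"]
    kept.name = "subtype"
    return kept.sort_index(), excluded


@dataclass
class KMCurve:
    """Product-limit survival estimate for one group.

    ``times`` are the distinct event times (days); ``survival`` the
    estimate just after each time; ``at_risk`` the risk-set size just
    before it. Survival starts at 1 and is nonincreasing.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def at(self, t: float) -> float:
        """S(t): step function value at time t."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_curve(times: np.ndarray, events: np.ndarray) -> KMCurve:
    """Kaplan-Meier estimate from possibly censored times.

    events: 1 = death observed, 0 = censored. Ties between deaths and
    censorings at the same time are resolved deaths-first (the standard
    convention, as in lifelines).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("need at least one record")
    if (times < 0).any():
        raise ValueError("negative survival time")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    tab = kmf.event_table
    tab = tab[tab["observed"] > 0]
    ev_times = tab.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(ev_times).to_numpy()
    return KMCurve(times=ev_times, survival=surv,
                   at_risk=tab["at_risk"].to_numpy())


def logrank_test(groups: list[pd.DataFrame]) -> tuple[float, int, float]:
    """Multi-group log-rank test; returns (chi_square, df, p_value).

    Each group frame needs 'time' and 'event' columns. With G groups the
    statistic is the usual observed-minus-expected form over pooled event
    times, chi-square with G-1 degrees of freedom. With no events at all
    the statistic is 0 and p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        if len(g) == 0:
            raise ValueError("empty group")
    times = np.concatenate([np.asarray(g["time"], dtype=float) for g in groups])
    events = np.concatenate([np.asarray(g["event"], dtype=int) for g in groups])
    labels = np.concatenate([
        np.full(len(g), i) for i, g in enumerate(groups)])
    df = len(groups) - 1
    if events.sum() == 0:
        return 0.0, df, 1.0
    res = multivariate_logrank_test(times, labels, events)
    return float(res.test_statistic), df, float(res.p_value)


def pairwise_logrank(groups: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """All pairwise log-rank tests with BH-corrected q-values."""
    from statsmodels.stats.multitest import multipletests

    names = sorted(groups)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            chi, _, p = logrank_test([groups[a], groups[b]])
            rows.append({"group_a": a, "group_b": b,
                         "chi_square": chi, "p_value": p})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out


def subtype_survival(
    clinical: pd.DataFrame,
    donor_subtype: pd.Series,
) -> tuple[dict[str, KMCurve], float, int, float, pd.DataFrame]:
    """KM curves per subtype plus the global log-rank test.

    ``clinical`` needs donor_id, survival_days, event. Returns
    (curves, chi_square, df, p_value, per-subtype summary with median
    survival in years).
    """
    df = clinical.set_index("donor_id").join(donor_subtype.rename("subtype"),
                                             how="inner")
    curves: dict[str, KMCurve] = {}
    groups = []
    rows = []
    for subtype, sub in sorted(df.groupby("subtype")):
        t = sub["survival_days"].to_numpy(dtype=float)
        e = sub["event"].to_numpy(dtype=int)
        curves[subtype] = km_curve(t, e)
        groups.append(pd.DataFrame({"time": t, "event": e}))
        kmf = KaplanMeierFitter().fit(t, e)
        med = kmf.median_survival_time_
        rows.append({
            "subtype": subtype,
            "n_donors": len(sub),
            "n_events": int(e.sum()),
            "median_survival_years": (float(med) / DAYS_PER_YEAR
                                      if np.isfinite(med) else np.nan),
        })
    chi, dof, p = logrank_test(groups)
    return curves, chi, dof, p, pd.DataFrame(rows)


def composition_summary(
    clinical: pd.DataFrame,
    donor_subtype: pd.Series,
    attribute: str,
) -> pd.DataFrame:
    """Subtype x category fraction table for a clinical attribute.

    Rows sum to 1 over observed categories; empty/NaN values form a
    "missing" category.
    """
    if attribute not in clinical.columns:
        raise KeyError(f"attribute {attribute!r} not in clinical table")
    df = clinical.set_index("donor_id").join(donor_subtype.rename("subtype"),
                                             how="inner")
    vals = df[attribute].astype(object)
    vals = vals.where(vals.notna() & (vals.astype(str).str.strip() != ""),
                      "missing")
    return pd.crosstab(df["subtype"], vals, normalize="index").sort_index()
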