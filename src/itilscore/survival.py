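"""Survival layer: censoring, Kaplan-Meier/log-rank, Cox models, cut-off search.

Analyses are truncated at five years (any follow-up beyond 1825 days is set
to 1825 days and censored).  Group comparisons use Kaplan-Meier curves with
two-sided log-rank tests; effect sizes come from Cox proportional-hazards
models (univariate and multivariate), fitted with lifelines using Efron tie
handling.

The binary iTIL cut-off is discovered by a five-group jackknife: patients are
randomly split into five equally sized groups (stratified by event status),
the analysis is repeated five times with one group excluded each time, and in
each repeat every candidate cut-off is scored by the log-rank p-value of the
TIL-High vs TIL-Low split.  The consensus cut-off is the one optimal in every
repeat when unanimous, otherwise the modal per-repeat optimum (reported as
non-unanimous).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test

__all__ = [
    "FIVE_YEARS_DAYS",
    "KMResult",
    "CutoffSearchResult",
    "censor_at_5_years",
    "km_logrank",
    "cox_fit",
    "cutoff_search",
    "clinical_risk",
]

FIVE_YEARS_DAYS = 1825


def censor_at_5_years(table: pd.DataFrame, time_col: str = "time_days",
                      event_col: str = "event",
                      horizon_days: int = FIVE_YEARS_DAYS) -> pd.DataFrame:
    """Administrative truncation: follow-up beyond the horizon is censored there.

    Rows with time > horizon get time = horizon and event = 0; a time exactly
    at the horizon is left unchanged.  Idempotent.  Raises on nonpositive
    times, listing the offending patients.
    """
    t = pd.to_numeric(table[time_col], errors="coerce")
    bad = table.index[~(t > 0)]
    if len(bad):
        ids = (table.loc[bad, "patient_id"].tolist()
               if "patient_id" in table.columns else list(bad))
        raise ValueError(f"nonpositive survival times for patients {ids[:10]}")
    out = table.copy()
    over = t > horizon_days
    out.loc[over, time_col] = horizon_days
    out.loc[over, event_col] = 0
    return out


@dataclass
class KMResult:
    curves: dict               # group -> survival-function DataFrame (index: time)
    statistic: float           # log-rank test statistic
    p_value: float
    group_sizes: dict

    def curve_table(self) -> pd.DataFrame:
        """Step-function table: one row per (group, time, survival probability)."""
        rows = []
        for g, sf in self.curves.items():
            for t, s in sf.iloc[:, 0].items():
                rows.append({"group": g, "time": float(t), "survival": float(s)})
        return pd.DataFrame(rows)


def km_logrank(table: pd.DataFrame, group_col: str, time_col: str = "time_days",
               event_col: str = "event") -> KMResult:
    """Kaplan-Meier curves per group with a two-sided log-rank test."""
    groups = table[group_col].dropna().unique()
    if len(groups) < 2:
        raise ValueError(f"log-rank test needs >= 2 groups, found {len(groups)}")
    curves, sizes = {}, {}
    for g in groups:
        sub = table[table[group_col] == g]
        kmf = KaplanMeierFitter(label=str(g))
        kmf.fit(sub[time_col], sub[event_col])
        curves[g] = kmf.survival_function_
        sizes[g] = len(sub)
    res = multivariate_logrank_test(table[time_col], table[group_col], table[event_col])
    return KMResult(curves, float(res.test_statistic), float(res.p_value), sizes)


def cox_fit(table: pd.DataFrame, covariates: Sequence[str],
            time_col: str = "time_days", event_col: str = "event") -> pd.DataFrame:
    """Cox proportional-hazards fit; one row per covariate.

    Pass a single covariate for a univariate model or the full roster for a
    multivariate one.  Boolean/object columns are coerced to numeric 0/1.
    Returns columns ``HR``, ``ci_lower``, ``ci_upper``, ``p``, ``coef``, ``n``.
    """
    covariates = list(covariates)
    df = table[[time_col, event_col, *covariates]].dropna().copy()
    for c in covariates:
        if df[c].dtype == object or df[c].dtype == bool:
            df[c] = pd.factorize(df[c], sort=True)[0] if df[c].dtype == object \
                else df[c].astype(int)
        if df[c].nunique() < 2:
            raise ValueError(f"covariate {c!r} is constant")
    if int(df[event_col].sum()) == 0:
        raise ValueError("no events in table; Cox model undefined")
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col=time_col, event_col=event_col)
    except ConvergenceError as exc:
        raise RuntimeError(f"Cox model failed to converge: {exc}") from exc
    s = cph.summary
    out = pd.DataFrame({
        "HR": np.exp(s["coef"]),
        "ci_lower": np.exp(s["coef lower 95%"]),
        "ci_upper": np.exp(s["coef upper 95%"]),
        "p": s["p"],
        "coef": s["coef"],
    })
    out["n"] = len(df)
    return out


@dataclass
class CutoffSearchResult:
    per_repeat: pd.DataFrame     # repeat, excluded_group, best_cutoff, best_p
    tables: list                 # per-repeat DataFrame (cutoff, p, n_high, n_low)
    consensus_cutoff: float
    unanimous: bool


def _event_stratified_groups(table: pd.DataFrame, k: int, seed: int,
                             event_col: str) -> np.ndarray:
    """Assign each row to one of k groups, stratified by event status.

    Rows are ordered by a stable key first so the assignment is invariant to
    the input row order.
    """
    key = table["patient_id"].astype(str) if "patient_id" in table.columns else \
        table.index.astype(str)
    order = np.argsort(key.to_numpy())
    rng = np.random.default_rng(seed)
    groups = np.empty(len(table), dtype=int)
    events = table[event_col].to_numpy()[order]
    for val in (0, 1):
        idx = np.flatnonzero(events == val)
        idx = rng.permutation(idx)
        for g, chunk in enumerate(np.array_split(idx, k)):
            groups[order[chunk]] = g
    return groups


def cutoff_search(table: pd.DataFrame, grid: Iterable[float] = range(1, 101),
                  k_groups: int = 5, seed: int = 0,
                  score_col: str = "ai_itil_score", time_col: str = "time_days",
                  event_col: str = "event") -> CutoffSearchResult:
    """Five-group jackknife search for the most significant binary cut-off.

    For each repeat (one group excluded) every grid cut-off is scored by the
    log-rank p of score >= cutoff vs score < cutoff; cut-offs leaving either
    side empty are skipped.  Per-repeat optimum is the minimal p (ties broken
    by the larger |log HR| from a univariate Cox fit, then the smaller
    cut-off).  Deterministic given the seed and invariant to row order.
    """
    grid = sorted(set(float(c) for c in grid))
    if not grid:
        raise ValueError("cut-off grid is empty")
    scores = pd.to_numeric(table[score_col])
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    groups = _event_stratified_groups(table, k_groups, seed, event_col)

    repeats, tables = [], []
    for rep in range(k_groups):
        sub = table[groups != rep]
        sc = scores[groups != rep].to_numpy()
        t = sub[time_col].to_numpy()
        e = sub[event_col].to_numpy()
        rows = []
        for c in grid:
            high = sc >= c
            n_high, n_low = int(high.sum()), int((~high).sum())
            if n_high == 0 or n_low == 0:
                continue
            res = multivariate_logrank_test(t, high.astype(int), e)
            rows.append({"cutoff": c, "p": float(res.p_value),
                         "n_high": n_high, "n_low": n_low})
        tab = pd.DataFrame(rows)
        tables.append(tab)
        if tab.empty:
            raise ValueError(f"no valid cut-off in repeat {rep}")
        p_min = tab["p"].min()
        cand = tab[tab["p"] <= p_min * (1 + 1e-12)]
        if len(cand) > 1:
            hrs = []
            for c in cand["cutoff"]:
                d = pd.DataFrame({time_col: t, event_col: e, "high": (sc >= c).astype(int)})
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")  # near-separation fits are fine here
                        hrs.append(abs(float(cox_fit(d, ["high"], time_col, event_col)
                                             .loc["high", "coef"])))
                except (ValueError, RuntimeError):
                    hrs.append(-np.inf)
            cand = cand.assign(abs_log_hr=hrs).sort_values(
                ["abs_log_hr", "cutoff"], ascending=[False, True])
        best = cand.iloc[0]
        repeats.append({"repeat": rep, "best_cutoff": float(best["cutoff"]),
                        "best_p": float(best["p"])})

    per_repeat = pd.DataFrame(repeats)
    optima = per_repeat["best_cutoff"]
    unanimous = optima.nunique() == 1
    consensus = float(optima.iloc[0]) if unanimous else \
        float(optima.mode().sort_values().iloc[0])
    return CutoffSearchResult(per_repeat, tables, consensus, unanimous)


CLINICAL_RISK_FEATURES = ("t4", "grade_high", "emvi", "lvi", "nodes_lt12")


def clinical_risk(covariates: pd.DataFrame | pd.Series | dict,
                  features: Sequence[str] = CLINICAL_RISK_FEATURES):
    """Stage II clinical risk: high if any of T4, high grade, extramural venous
    invasion, lymphovascular invasion, or fewer than 12 nodes examined.

    All five features must be recorded; any missing value yields
    ``unclassified``.  Accepts a patient table (returns a Series) or a single
    record (returns a string).
    """
    single = not isinstance(covariates, pd.DataFrame)
    df = pd.DataFrame([covariates]) if single else covariates
    vals = df.reindex(columns=features)
    any_missing = vals.isna().any(axis=1)
    any_high = np.zeros(len(df), dtype=bool)
    for f in features:
        col = vals[f]
        present = col.notna().to_numpy()
        any_high[present] |= col[present].astype(bool).to_numpy()
    out = pd.Series(np.where(any_high, "high", "low"), index=df.index)
    out[any_missing] = "unclassified"
    return out.iloc[0] if single else out
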