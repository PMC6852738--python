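"""Progression-free survival analysis.

Relates model-predicted apoptosis class, single-protein median splits and
clinical covariates to PFS via Kaplan-Meier estimation (Brookmeyer-Crowley
median confidence intervals through the log-log survival-curve CI),
log-rank tests, and Cox proportional-hazards regression (Efron tie
handling) with likelihood-ratio p-values.

PFS is measured in months from the analysed surgical resection (whether
newly-diagnosed or recurrent) to progression, with loss to follow-up
treated as censoring.  Models use complete-case analysis: rows missing any
covariate entering a given model are dropped from that model only, and the
per-model n is recorded on the fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import median_survival_times
from scipy import stats

__all__ = [
    "MISSING",
    "KMCurve",
    "CoxFit",
    "ConvergenceError",
    "median_split",
    "km_fit",
    "log_rank",
    "cox_univariate",
    "cox_multivariate",
    "chi_square_association",
]

#: Sentinel for unavailable categorical covariate values.
MISSING = "missing"
_MISSING_TOKENS = {MISSING, "", "na", "not available", "nan", "none"}


class ConvergenceError(RuntimeError):
    """Cox partial likelihood did not converge (e.g. complete separation)."""


def median_split(values: pd.Series) -> pd.Series:
    """Dichotomise at the cohort median; ties at the median go to ``<=median``."""
    x = values.astype(float)
    if len(x) < 2:
        raise ValueError("need at least 2 samples for a median split")
    med = float(np.median(x))
    if np.all(x == x.iloc[0]):
        raise ValueError("degenerate split: all values identical")
    return pd.Series(np.where(x <= med, "<=median", ">median"),
                     index=values.index, name=values.name)


@dataclass
class KMCurve:
    """Product-limit estimate for one group."""

    group: str
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n: int
    n_events: int
    median: float              # months; inf when not reached
    median_ci: tuple[float, float]

    @property
    def median_reached(self) -> bool:
        return np.isfinite(self.median)


def _as_event_bool(event: pd.Series) -> pd.Series:
    if event.dtype == object:
        return event.map({"progressed": True, "censored": False, "1": True, "0": False})
    return event.astype(bool)


def km_fit(records: pd.DataFrame,
           grouping: str,
           duration_col: str = "pfs_months",
           event_col: str = "event") -> dict[str, KMCurve]:
    """Kaplan-Meier curve, median PFS and 95% CI per group."""
    out: dict[str, KMCurve] = {}
    for group, sub in records.groupby(grouping, observed=True):
        t = sub[duration_col].astype(float)
        e = _as_event_bool(sub[event_col])
        kmf = KaplanMeierFitter()
        kmf.fit(t, e, label=str(group))
        med = float(kmf.median_survival_time_)
        ci_df = median_survival_times(kmf.confidence_interval_)
        lo, hi = float(ci_df.iloc[0, 0]), float(ci_df.iloc[0, 1])
        sf = kmf.survival_function_
        ev = kmf.event_table
        out[str(group)] = KMCurve(
            group=str(group),
            times=sf.index.to_numpy(float),
            survival=sf.iloc[:, 0].to_numpy(float),
            at_risk=ev["at_risk"].to_numpy(float),
            n=int(len(sub)),
            n_events=int(e.sum()),
            median=med,
            median_ci=(lo, hi),
        )
    return out


def log_rank(records: pd.DataFrame,
             grouping: str,
             duration_col: str = "pfs_months",
             event_col: str = "event") -> float:
    """Unweighted log-rank test p-value across the grouping's levels."""
    groups = records[grouping]
    if groups.nunique() < 2:
        raise ValueError("log-rank test needs at least 2 groups")
    e = _as_event_bool(records[event_col])
    if int(e.sum()) == 0:
        raise ValueError("log-rank test needs at least one event")
    res = multivariate_logrank_test(records[duration_col].astype(float), groups, e)
    return float(res.p_value)


@dataclass
class CoxFit:
    """Hazard-ratio summary for one predictor (possibly adjusted)."""

    predictor: str
    reference: str | None
    table: pd.DataFrame  # rows per non-reference level: level, n, hr, ci_low, ci_high
    lrt_p: float
    n_used: int
    n_events: int
    adjusters: tuple[str, ...] = ()

    def hazard_ratio(self, level: str | None = None) -> float:
        if level is None:
            return float(self.table["hr"].iloc[0])
        return float(self.table.set_index("level").loc[level, "hr"])


def _drop_missing(records: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    sub = records.dropna(subset=cols)
    for c in cols:
        if sub[c].dtype == object:
            sub = sub[~sub[c].astype(str).str.strip().str.lower().isin(_MISSING_TOKENS)]
    return sub


def _design(records: pd.DataFrame, col: str,
            reference: str | None) -> tuple[pd.DataFrame, list[str], str | None]:
    """Encode one covariate: passthrough if numeric, dummies otherwise."""
    s = records[col]
    if pd.api.types.is_numeric_dtype(s) and s.nunique() > 2:
        return s.to_frame(col).astype(float), [col], None
    s = s.astype(str)
    levels = sorted(s.unique())
    if len(levels) < 2:
        raise ValueError(f"{col}: needs >= 2 observed levels, got {levels}")
    ref = reference if reference is not None else s.value_counts().idxmax()
    if ref not in levels:
        raise ValueError(f"{col}: reference level {ref!r} not observed")
    cols = {}
    for lev in levels:
        if lev != ref:
            cols[f"{col}::{lev}"] = (s == lev).astype(float)
    return pd.DataFrame(cols, index=records.index), list(cols), ref


def _fit_cox(df: pd.DataFrame, duration_col: str, event_col: str) -> CoxPHFitter:
    last_exc: Exception | None = None
    # damp the Newton step on retry: small cohorts with rare covariate levels
    # can overshoot at the default step size without being truly separated
    for step_size in (None, 0.25, 0.1):
        cph = CoxPHFitter()
        opts = {"step_size": step_size} if step_size else None
        try:
            cph.fit(df, duration_col=duration_col, event_col=event_col,
                    fit_options=opts)
        except Exception as exc:
            last_exc = exc
            continue
        summ = cph.summary
        finite = np.isfinite(summ["coef"]) & np.isfinite(summ["se(coef)"])
        # |log HR| beyond ~15 or se beyond ~10 signals monotone likelihood,
        # far outside any plausible biological effect
        if finite.all() and (summ["coef"].abs() < 15).all() \
                and (summ["se(coef)"] < 10).all():
            return cph
        last_exc = RuntimeError(
            f"degenerate estimates: coef={summ['coef'].to_dict()}, "
            f"se={summ['se(coef)'].to_dict()}")
    raise ConvergenceError(
        f"Cox fit failed (possible complete separation or monotone "
        f"likelihood) for columns {list(df.columns)}: {last_exc}"
    ) from last_exc


def cox_univariate(records: pd.DataFrame,
                   predictor: str,
                   duration_col: str = "pfs_months",
                   event_col: str = "event",
                   reference: str | None = None) -> CoxFit:
    """Single-predictor Cox model; Wald 95% CIs, likelihood-ratio p vs null."""
    return cox_multivariate(records, predictor, adjusters=(),
                            duration_col=duration_col, event_col=event_col,
                            reference=reference)


def cox_multivariate(records: pd.DataFrame,
                     predictor: str,
                     adjusters: tuple[str, ...] = ("age_years", "history3", "mgmt"),
                     duration_col: str = "pfs_months",
                     event_col: str = "event",
                     reference: str | None = None) -> CoxFit:
    """Cox model for ``predictor`` adjusted for ``adjusters``.

    The p-value is a likelihood-ratio test comparing the full model against
    the model containing only the adjusters (fitted on the same
    complete-case rows), with degrees of freedom equal to the number of
    predictor terms.
    """
    used_cols = [predictor, *adjusters]
    sub = _drop_missing(records, [duration_col, event_col, *used_cols]).copy()
    if len(sub) == 0:
        raise ValueError("no complete-case rows for this model")
    sub[event_col] = _as_event_bool(sub[event_col]).astype(int)

    pred_X, pred_cols, ref = _design(sub, predictor, reference)
    adj_blocks, adj_cols = [], []
    for a in adjusters:
        X, cols, _ = _design(sub, a, None)
        adj_blocks.append(X)
        adj_cols.extend(cols)
    base = sub[[duration_col, event_col]]
    full_df = pd.concat([base, pred_X, *adj_blocks], axis=1)

    full = _fit_cox(full_df, duration_col, event_col)
    if adjusters:
        reduced_df = pd.concat([base, *adj_blocks], axis=1)
        ll0 = _fit_cox(reduced_df, duration_col, event_col).log_likelihood_
    else:
        # empty null model: lifelines computes the null partial likelihood
        ll0 = full.log_likelihood_ - full.log_likelihood_ratio_test().test_statistic / 2.0
    chi2 = 2.0 * (full.log_likelihood_ - ll0)
    lrt_p = float(stats.chi2.sf(max(chi2, 0.0), df=len(pred_cols)))

    summ = full.summary
    rows = []
    for c in pred_cols:
        level = c.split("::", 1)[1] if "::" in c else c
        n_level = int((sub[predictor].astype(str) == level).sum()) if "::" in c else len(sub)
        rows.append({
            "level": level,
            "n": n_level,
            "hr": float(np.exp(summ.loc[c, "coef"])),
            "ci_low": float(np.exp(summ.loc[c, "coef lower 95%"])),
            "ci_high": float(np.exp(summ.loc[c, "coef upper 95%"])),
        })
    return CoxFit(predictor=predictor, reference=ref, table=pd.DataFrame(rows),
                  lrt_p=lrt_p, n_used=int(len(sub)),
                  n_events=int(sub[event_col].sum()), adjusters=tuple(adjusters))


@dataclass
class ChiSquareResult:
    statistic: float
    p_value: float            # uncorrected Pearson
    p_value_yates: float      # continuity-corrected companion value
    table: pd.DataFrame


def chi_square_association(class_labels: pd.Series,
                           history: pd.Series) -> ChiSquareResult:
    """Pearson chi-square for the 2x2 apoptosis-class by history table.

    Reports the uncorrected statistic as primary with the Yates-corrected
    p alongside.
    """
    tab = pd.crosstab(class_labels, history)
    if tab.shape[0] < 2 or tab.shape[1] < 2 or tab.to_numpy().sum() == 0:
        raise ValueError("contingency table has an empty margin "
                         f"(observed shape {tab.shape})")
    stat, p, _, _ = stats.chi2_contingency(tab.to_numpy(), correction=False)
    _, p_yates, _, _ = stats.chi2_contingency(tab.to_numpy(), correction=True)
    return ChiSquareResult(statistic=float(stat), p_value=float(p),
                           p_value_yates=float(p_yates), table=tab)
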