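"""Endpoint construction and the survival statistics battery.

Endpoints (months from resection):

* TTR  -- time to recurrence: recurrence diagnosis is the event; patients
  without recurrence are censored at death or last follow-up.
* DFS  -- disease-free survival: recurrence or death from any cause.
* OS   -- overall survival: death from any cause.

Analyses: Kaplan-Meier product-limit curves with log-rank group
comparison, univariable Cox proportional-hazards fits per categorical
factor (reference = low / under-median) with per-level Wald tests and a
type-3 Wald test across all levels, multivariable Cox models per feature
with age and TNM stage forced in and backward elimination of other
terms, median follow-up by the inverse (reverse) Kaplan-Meier method,
Friedman + Bonferroni-corrected Wilcoxon region comparisons, and
Spearman correlations.  Cox fits use lifelines with the Efron tie
approximation; fits with an event-free level or non-convergence come
back flagged, never as silent numbers.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import median_survival_times
from scipy import stats

ENDPOINTS = ("TTR", "DFS", "OS")


@dataclass
class SurvivalEndpoint:
    name: str
    time: float
    event: int

    def __post_init__(self) -> None:
        if self.name not in ENDPOINTS:
            raise ValueError(f"unknown endpoint {self.name!r}")
        if self.time < 0:
            raise ValueError("endpoint time must be >= 0")
        if self.event not in (0, 1):
            raise ValueError("event indicator must be 0 or 1")


def build_endpoints(
    recurrence_months: float | None,
    death_months: float | None,
    last_followup_months: float,
) -> dict[str, SurvivalEndpoint]:
    """Construct (time, event) triples for TTR, DFS and OS.

    ``None`` or NaN marks an unobserved event.  Raises on negative times
    or event times after the last follow-up.
    """
    rec = None if recurrence_months is None or np.isnan(recurrence_months) else float(recurrence_months)
    death = None if death_months is None or np.isnan(death_months) else float(death_months)
    fu = float(last_followup_months)
    if fu < 0 or (rec is not None and rec < 0) or (death is not None and death < 0):
        raise ValueError("times must be >= 0")
    for t, label in ((rec, "recurrence"), (death, "death")):
        if t is not None and t > fu + 1e-9:
            raise ValueError(f"{label} time exceeds last follow-up")

    if rec is not None:
        ttr = SurvivalEndpoint("TTR", rec, 1)
    else:
        censor = min(death, fu) if death is not None else fu
        ttr = SurvivalEndpoint("TTR", censor, 0)

    if rec is not None or death is not None:
        dfs_time = min(t for t in (rec, death) if t is not None)
        dfs = SurvivalEndpoint("DFS", dfs_time, 1)
    else:
        dfs = SurvivalEndpoint("DFS", fu, 0)

    os_ep = SurvivalEndpoint("OS", death, 1) if death is not None else SurvivalEndpoint("OS", fu, 0)
    return {"TTR": ttr, "DFS": dfs, "OS": os_ep}


def endpoint_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Vector version of :func:`build_endpoints` over a cohort table.

    Expects columns ``recurrence_months, death_months,
    last_followup_months``; returns one row per patient with
    ``{TTR,DFS,OS}_{time,event}`` columns, indexed like the input.
    """
    rows = {}
    for idx, r in cohort.iterrows():
        eps = build_endpoints(
            r.get("recurrence_months"), r.get("death_months"), r["last_followup_months"]
        )
        rows[idx] = {
            f"{name}_{part}": getattr(ep, part)
            for name, ep in eps.items()
            for part in ("time", "event")
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    if "patient_id" in cohort.columns:
        out.insert(0, "patient_id", cohort["patient_id"])
    return out


@dataclass
class KMCurve:
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    median: float  # NaN when not reached
    median_ci: tuple[float, float] = (float("nan"), float("nan"))

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times, events) -> KMCurve:
    """Product-limit estimator (simultaneous-event tie convention)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("at least one subject required")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    table = kmf.event_table.iloc[1:] if kmf.event_table.index[0] == 0 else kmf.event_table
    grid = kmf.survival_function_.index.to_numpy()
    surv = kmf.survival_function_["KM_estimate"].to_numpy()
    keep = grid > 0
    at_risk = kmf.event_table["at_risk"].reindex(grid[keep]).to_numpy()
    ci = median_survival_times(kmf.confidence_interval_)
    lo, hi = float(ci.iloc[0, 0]), float(ci.iloc[0, 1])
    return KMCurve(
        times=grid[keep],
        survival=surv[keep],
        at_risk=at_risk,
        median=float(kmf.median_survival_time_),
        median_ci=(lo, hi),
    )


def logrank_test(groups: dict[str, tuple[np.ndarray, np.ndarray]]) -> tuple[float, float, list[str]]:
    """Log-rank test across >= 2 groups of (times, events).

    Returns (chi-square statistic, p, flags); with zero events the test
    is undefined and comes back as NaN with a flag.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    times = np.concatenate([np.asarray(t, dtype=float) for t, _ in groups.values()])
    events = np.concatenate([np.asarray(e, dtype=int) for _, e in groups.values()])
    labels = np.concatenate(
        [np.repeat(name, len(t)) for name, (t, _) in groups.items()]
    )
    if events.sum() == 0:
        return float("nan"), float("nan"), ["no events; log-rank undefined"]
    res = multivariate_logrank_test(times, labels, events)
    return float(res.test_statistic), float(res.p_value), []


@dataclass
class LevelEffect:
    level: str
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p: float


@dataclass
class CoxResult:
    term: str
    levels: list[LevelEffect]
    type3_p: float
    n: int
    n_events: int
    flags: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.flags


def _wald_type3(fitter: CoxPHFitter, names: list[str]) -> float:
    """Joint Wald test that all listed coefficients are zero."""
    beta = fitter.params_[names].to_numpy()
    cov = fitter.variance_matrix_.loc[names, names].to_numpy()
    stat = float(beta @ np.linalg.solve(cov, beta))
    return float(stats.chi2.sf(stat, df=len(names)))


def _fit_cox(df: pd.DataFrame, duration_col: str, event_col: str) -> CoxPHFitter:
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col=duration_col, event_col=event_col)
    return cph


def cox_univariable(
    time: pd.Series,
    event: pd.Series,
    factor: pd.Series,
    reference: str | None = None,
    term: str = "factor",
) -> CoxResult:
    """Univariable Cox fit of one categorical factor.

    Dummy-codes the factor against ``reference`` (default: "low",
    "under-median" or the lexicographically first level present) and
    reports per-level hazard ratios with 95% Wald intervals plus a
    type-3 Wald p across all non-reference levels.  Levels without
    events make the partial likelihood monotone; such fits come back
    flagged instead of silently wrong.
    """
    data = pd.DataFrame({"time": time, "event": event, "f": factor}).dropna()
    levels = sorted(data["f"].astype(str).unique())
    if len(levels) < 2:
        return CoxResult(term, [], float("nan"), len(data), int(data["event"].sum()),
                         ["factor has fewer than 2 observed levels"])
    if reference is None:
        for cand in ("low", "under-median"):
            if cand in levels:
                reference = cand
                break
        else:
            reference = levels[0]
    flags = []
    for lvl in levels:
        sub = data[data["f"].astype(str) == lvl]
        if sub["event"].sum() == 0:
            flags.append(f"level {lvl!r} has no events; monotone likelihood")
    if flags:
        return CoxResult(term, [], float("nan"), len(data), int(data["event"].sum()), flags)

    others = [lvl for lvl in levels if lvl != reference]
    design = pd.DataFrame({"time": data["time"], "event": data["event"]})
    for lvl in others:
        design[f"f_{lvl}"] = (data["f"].astype(str) == lvl).astype(float)
    try:
        cph = _fit_cox(design, "time", "event")
    except (ConvergenceError, np.linalg.LinAlgError) as exc:
        return CoxResult(term, [], float("nan"), len(data), int(data["event"].sum()),
                         [f"non-convergence: {exc}"])
    if float(cph.standard_errors_.max()) > 10.0:
        return CoxResult(term, [], float("nan"), len(data), int(data["event"].sum()),
                         ["unstable fit (standard error > 10); likely separation"])
    effects = []
    for lvl in others:
        name = f"f_{lvl}"
        beta = float(cph.params_[name])
        se = float(cph.standard_errors_[name])
        effects.append(
            LevelEffect(
                level=f"{lvl} vs {reference}",
                hazard_ratio=float(np.exp(beta)),
                ci_low=float(np.exp(beta - 1.959963984540054 * se)),
                ci_high=float(np.exp(beta + 1.959963984540054 * se)),
                p=float(cph.summary.loc[name, "p"]),
            )
        )
    type3 = _wald_type3(cph, [f"f_{lvl}" for lvl in others])
    return CoxResult(term, effects, type3, len(data), int(data["event"].sum()))


def cox_multivariable(
    df: pd.DataFrame,
    duration_col: str,
    event_col: str,
    feature: str,
    forced: tuple[str, ...] = ("age", "tnm_stage"),
    reference: str | None = None,
    alpha_stay: float = 0.05,
) -> CoxResult:
    """Cox model for one feature adjusted for forced covariates.

    The feature (dummy-coded when categorical) enters together with the
    forced covariates; backward elimination iteratively removes
    non-forced, non-feature terms with p >= ``alpha_stay``.  Forced
    covariates are never removed, and the focal feature is always
    reported.
    """
    cols = [duration_col, event_col, feature, *forced]
    data = df[cols].dropna()
    factor = data[feature]
    categorical = factor.dtype == object or str(factor.dtype) == "category"

    design = data[[duration_col, event_col, *forced]].astype(float)
    if categorical:
        levels = sorted(factor.astype(str).unique())
        if reference is None:
            for cand in ("low", "under-median"):
                if cand in levels:
                    reference = cand
                    break
            else:
                reference = levels[0]
        others = [lvl for lvl in levels if lvl != reference]
        flags = []
        for lvl in levels:
            if data.loc[factor.astype(str) == lvl, event_col].sum() == 0:
                flags.append(f"level {lvl!r} has no events; monotone likelihood")
        if flags:
            return CoxResult(feature, [], float("nan"), len(data),
                             int(data[event_col].sum()), flags)
        feat_cols = []
        for lvl in others:
            name = f"{feature}_{lvl}"
            design[name] = (factor.astype(str) == lvl).astype(float)
            feat_cols.append(name)
    else:
        design[feature] = factor.astype(float)
        feat_cols = [feature]
        others = [feature]
        reference = ""

    try:
        cph = _fit_cox(design, duration_col, event_col)
        # Backward elimination over removable terms (none are forced or focal).
        removable = [
            c for c in design.columns
            if c not in (duration_col, event_col, *forced, *feat_cols)
        ]
        while removable:
            pvals = cph.summary.loc[removable, "p"]
            worst = pvals.idxmax()
            if pvals.max() < alpha_stay:
                break
            design = design.drop(columns=[worst])
            removable.remove(worst)
            cph = _fit_cox(design, duration_col, event_col)
    except (ConvergenceError, np.linalg.LinAlgError) as exc:
        return CoxResult(feature, [], float("nan"), len(data),
                         int(data[event_col].sum()), [f"non-convergence: {exc}"])
    if float(cph.standard_errors_[feat_cols].max()) > 10.0:
        return CoxResult(feature, [], float("nan"), len(data), int(data[event_col].sum()),
                         ["unstable fit (standard error > 10); likely separation"])

    effects = []
    for name, lvl in zip(feat_cols, others):
        beta = float(cph.params_[name])
        se = float(cph.standard_errors_[name])
        label = f"{lvl} vs {reference}" if categorical else lvl
        effects.append(
            LevelEffect(
                level=label,
                hazard_ratio=float(np.exp(beta)),
                ci_low=float(np.exp(beta - 1.959963984540054 * se)),
                ci_high=float(np.exp(beta + 1.959963984540054 * se)),
                p=float(cph.summary.loc[name, "p"]),
            )
        )
    type3 = _wald_type3(cph, feat_cols)
    return CoxResult(feature, effects, type3, len(data), int(data[event_col].sum()))


def screen_univariable(
    df: pd.DataFrame,
    duration_col: str,
    event_col: str,
    features: list[str],
    alpha: float = 0.05,
) -> list[str]:
    """Features significant in univariable analysis (type-3 p < alpha)."""
    keep = []
    for feat in features:
        res = cox_univariable(df[duration_col], df[event_col], df[feat], term=feat)
        if res.ok and res.type3_p < alpha:
            keep.append(feat)
    return keep


def inverse_km_followup(times, events) -> tuple[float, tuple[float, float], list[str]]:
    """Median follow-up by the inverse Kaplan-Meier method.

    Censorings are treated as events (and vice versa); the median of
    that curve estimates the median observation time.  When more than
    half the cohort dies the median is never reached and is flagged.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("at least one subject required")
    curve = km_estimate(times, 1 - events)
    if np.isinf(curve.median) or np.isnan(curve.median):
        return float("nan"), (float("nan"), float("nan")), ["median follow-up not reached"]
    return curve.median, curve.median_ci, []


def region_comparison(
    qa_wide: pd.DataFrame, alpha_pairwise: float = 0.05
) -> dict:
    """Friedman test across ROIs plus Bonferroni-corrected Wilcoxon pairs.

    ``qa_wide`` is patients x ROIs; only complete rows enter.  Pairwise
    Wilcoxon signed-rank p-values are multiplied by the number of
    comparisons (capped at 1).
    """
    complete = qa_wide.dropna()
    flags = []
    if complete.shape[1] < 2:
        raise ValueError("need >= 2 ROIs with paired values")
    if len(complete) < 6:
        flags.append("fewer than 6 complete pairs; low power")
    cols = list(complete.columns)
    arrays = [complete[c].to_numpy() for c in cols]
    if all(np.array_equal(arrays[0], a) for a in arrays[1:]):
        friedman_stat, friedman_p = 0.0, 1.0
    elif len(arrays) == 2:
        # With two matched groups the Friedman statistic reduces to the
        # sign test on paired differences (ties dropped), chi-square 1 df.
        diff = arrays[0] - arrays[1]
        n_pos, n_neg = int((diff > 0).sum()), int((diff < 0).sum())
        if n_pos + n_neg == 0:
            friedman_stat, friedman_p = 0.0, 1.0
        else:
            friedman_stat = (n_pos - n_neg) ** 2 / (n_pos + n_neg)
            friedman_p = float(stats.chi2.sf(friedman_stat, df=1))
    else:
        friedman_stat, friedman_p = stats.friedmanchisquare(*arrays)
    pairs = list(itertools.combinations(cols, 2))
    n_comp = len(pairs)
    pairwise = {}
    for a, b in pairs:
        diff = complete[a] - complete[b]
        if np.allclose(diff, 0):
            raw = 1.0
        else:
            raw = float(stats.wilcoxon(complete[a], complete[b]).pvalue)
        pairwise[(a, b)] = {"p_raw": raw, "p_bonferroni": bonferroni(raw, n_comp)}
    return {
        "friedman_statistic": float(friedman_stat),
        "friedman_p": float(friedman_p),
        "pairwise": pairwise,
        "n_complete": len(complete),
        "flags": flags,
    }


def bonferroni(p_raw: float, n_comparisons: int) -> float:
    return float(min(1.0, p_raw * n_comparisons))


def correlate(a, b) -> tuple[float, float, list[str]]:
    """Spearman rank correlation over complete pairs (average ranks)."""
    pair = pd.DataFrame({"a": a, "b": b}).dropna()
    if len(pair) < 4:
        raise ValueError("need >= 4 complete pairs")
    if pair["a"].nunique() == 1 or pair["b"].nunique() == 1:
        return float("nan"), float("nan"), ["constant input; correlation undefined"]
    rho, p = stats.spearmanr(pair["a"], pair["b"])
    return float(rho), float(p), []
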