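"""Prognostic evaluation of a biomarker.

Mean-split stratification, Kaplan–Meier curves, log-rank comparison, Cox
proportional-hazards models (Newton–Raphson on the partial likelihood with
Efron or Breslow tie handling), ROC/AUC, chi-square association tables and
IPI-stratified analysis.

Conventions: survival time is in months (5-year rate = S(60)); the mean
split sends values strictly below the mean to "low" and at-or-above to
"high"; Cox inference is Wald-based; the low stratum is coded 1 so a hazard
ratio above 1 reads "low-biomarker patients at higher risk".
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

from .exceptions import ConvergenceError, DegenerateSplitError, DomainError

logger = logging.getLogger(__name__)

FIVE_YEARS_MONTHS = 60.0


# ---------------------------------------------------------------------------
# stratification
# ---------------------------------------------------------------------------


@dataclass
class SplitRule:
    """Mean-based dichotomisation of a biomarker: < mean → low, ≥ mean → high."""

    threshold: float
    labels: pd.Series  # "low" / "high" per patient

    @property
    def n_low(self) -> int:
        return int((self.labels == "low").sum())

    @property
    def n_high(self) -> int:
        return int((self.labels == "high").sum())


def mean_split(values: pd.Series, threshold: float | None = None) -> SplitRule:
    """Dichotomise at the arithmetic mean (or an externally supplied cutoff)."""
    values = pd.Series(values).astype(float)
    if len(values) < 2:
        raise DomainError("mean split needs at least 2 patients")
    if threshold is None:
        threshold = float(values.mean())
    labels = pd.Series(
        np.where(values.to_numpy() < threshold, "low", "high"), index=values.index
    )
    if labels.nunique() < 2:
        raise DegenerateSplitError(
            f"degenerate split at threshold {threshold}: one stratum is empty"
        )
    return SplitRule(threshold=threshold, labels=labels)


# ---------------------------------------------------------------------------
# Kaplan–Meier
# ---------------------------------------------------------------------------


@dataclass
class KMCurve:
    """Product-limit estimate: steps at event times, censor marks kept for export."""

    event_times: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray
    censor_times: np.ndarray
    n: int

    def survival_at(self, t: float) -> float:
        """Right-continuous step value at the largest event time ≤ t."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "at_risk": self.at_risk,
                "events": self.events,
                "survival": self.survival,
            }
        )


def km_estimate(times, events) -> KMCurve:
    """Kaplan–Meier product-limit estimator (delegates to lifelines)."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    if times.size == 0:
        raise DomainError("empty survival input")
    if (times < 0).any():
        raise DomainError("negative survival time")
    if not np.isin(events, (0, 1)).all():
        raise DomainError("event indicator outside {0,1}")
    kmf = KaplanMeierFitter().fit(times, events)
    table = kmf.event_table
    mask = table["observed"] > 0
    event_times = table.index[mask].to_numpy(float)
    surv = kmf.survival_function_["KM_estimate"].reindex(table.index[mask]).to_numpy(float)
    return KMCurve(
        event_times=event_times,
        at_risk=table.loc[mask, "at_risk"].to_numpy(int),
        events=table.loc[mask, "observed"].to_numpy(int),
        survival=surv,
        censor_times=np.sort(times[events == 0]),
        n=int(times.size),
    )


def survival_at(curve: KMCurve, t: float) -> float:
    return curve.survival_at(t)


def log_rank(times, events, group_labels) -> tuple[float, int, float]:
    """Log-rank test across ≥2 groups: (chi2, df, p)."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(group_labels)
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise DomainError("log-rank needs at least two nonempty groups")
    if (counts == 0).any():
        raise DomainError("log-rank group with zero subjects")
    res = multivariate_logrank_test(times, groups, events)
    chi2 = float(res.test_statistic)
    df = len(labels) - 1
    return chi2, df, float(stats.chi2.sf(chi2, df))


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------


@dataclass
class CoxFit:
    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    hazard_ratio: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p: np.ndarray
    log_partial_likelihood: float
    ties_method: str
    n: int
    n_events: int
    converged: bool = True
    diverged: bool = False
    iterations: int = 0

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef,
                "se": self.se,
                "hazard_ratio": self.hazard_ratio,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "p": self.p,
            },
            index=self.names,
        )


def _cox_quantities(beta, X, times, events, ties):
    """Log partial likelihood, gradient and (observed) information at beta."""
    order = np.argsort(times, kind="stable")
    t, e, Xs = times[order], events[order], X[order]
    n, p = Xs.shape
    eta = Xs @ beta
    w = np.exp(eta)
    wx = w[:, None] * Xs
    wxx = w[:, None, None] * Xs[:, :, None] * Xs[:, None, :]
    # suffix sums: risk set at time t[i] = subjects i..n-1 among sorted times
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum(wx[::-1], axis=0)[::-1]
    S2 = np.cumsum(wxx[::-1], axis=0)[::-1]
    ll = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        dead = np.arange(i, j)[e[i:j] == 1]
        d = len(dead)
        if d:
            ll += eta[dead].sum()
            grad += Xs[dead].sum(axis=0)
            s0r, s1r, s2r = S0[i], S1[i], S2[i]
            if ties == "efron":
                s0d = w[dead].sum()
                s1d = wx[dead].sum(axis=0)
                s2d = wxx[dead].sum(axis=0)
                for el in range(d):
                    frac = el / d
                    denom = s0r - frac * s0d
                    xbar = (s1r - frac * s1d) / denom
                    ll -= np.log(denom)
                    grad -= xbar
                    info += (s2r - frac * s2d) / denom - np.outer(xbar, xbar)
            elif ties == "breslow":
                xbar = s1r / s0r
                ll -= d * np.log(s0r)
                grad -= d * xbar
                info += d * (s2r / s0r - np.outer(xbar, xbar))
            else:
                raise DomainError(f"unknown ties method {ties!r}")
        i = j
    return ll, grad, info


def cox_fit(
    covariates,
    times,
    events,
    ties: str = "efron",
    max_iter: int = 100,
    tol: float = 1e-8,
    coef_cap: float = 15.0,
) -> CoxFit:
    """Fit a Cox proportional-hazards model by Newton–Raphson.

    Iterates until the gradient infinity-norm drops below ``tol`` (with step
    halving on likelihood decreases).  A coefficient escaping ``coef_cap``
    signals a monotone partial likelihood (complete separation): the fit is
    returned with ``diverged=True`` and the coefficient capped.  Constant
    covariates carry no information and get coef 0, HR 1, p 1.
    """
    if isinstance(covariates, pd.DataFrame):
        names = [str(c) for c in covariates.columns]
        X = covariates.to_numpy(float)
    else:
        X = np.atleast_2d(np.asarray(covariates, float))
        if X.shape[0] == 1 and X.size > 1 and len(np.asarray(times)) != 1:
            X = X.T
        names = [f"x{i}" for i in range(X.shape[1])]
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    if np.isnan(X).any():
        raise DomainError("missing covariate values")
    if events.sum() < 1:
        raise DomainError("Cox fit needs at least one event")

    active = np.where(X.std(axis=0) > 0)[0]
    p_all = X.shape[1]
    beta_full = np.zeros(p_all)
    se_full = np.full(p_all, np.inf)
    diverged = False
    iterations = 0

    if len(active):
        Xa = X[:, active] - X[:, active].mean(axis=0)  # centering: stability only
        beta = np.zeros(len(active))
        ll, grad, info = _cox_quantities(beta, Xa, times, events, ties)
        for iterations in range(1, max_iter + 1):
            if np.max(np.abs(grad)) < tol:
                break
            try:
                step = np.linalg.solve(info, grad)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(info, grad, rcond=None)[0]
            new_beta = beta + step
            new_ll, new_grad, new_info = _cox_quantities(new_beta, Xa, times, events, ties)
            halvings = 0
            # tolerate float-level likelihood noise near the optimum
            while new_ll < ll - 1e-12 * max(1.0, abs(ll)) and halvings < 30:
                step /= 2.0
                new_beta = beta + step
                new_ll, new_grad, new_info = _cox_quantities(new_beta, Xa, times, events, ties)
                halvings += 1
            beta, ll, grad, info = new_beta, new_ll, new_grad, new_info
            if np.max(np.abs(beta)) > coef_cap:
                diverged = True
                beta = np.clip(beta, -coef_cap, coef_cap)
                ll, grad, info = _cox_quantities(beta, Xa, times, events, ties)
                warnings.warn(
                    "monotone partial likelihood: coefficient capped", RuntimeWarning
                )
                break
        converged = bool(np.max(np.abs(grad)) < tol) or diverged
        if not converged:
            raise ConvergenceError(
                f"Cox fit did not converge in {max_iter} iterations",
                beta=beta.copy(),
                gradient_norm=float(np.max(np.abs(grad))),
                iterations=iterations,
            )
        try:
            cov = np.linalg.inv(info)
            se = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            se = np.full(len(active), np.inf)
        beta_full[active] = beta
        se_full[active] = se
    else:
        converged = True
        ll, _, _ = _cox_quantities(np.zeros(0), X[:, :0], times, events, ties)

    z = np.divide(beta_full, se_full, out=np.zeros_like(beta_full), where=se_full > 0)
    with np.errstate(invalid="ignore"):
        pvals = np.where(np.isfinite(se_full), 2.0 * stats.norm.sf(np.abs(z)), 1.0)
        pvals = np.where(se_full == np.inf, 1.0, pvals)
    crit = stats.norm.ppf(0.975)
    hr = np.exp(beta_full)
    with np.errstate(over="ignore"):
        ci_low = np.where(np.isfinite(se_full), np.exp(beta_full - crit * se_full), hr)
        ci_high = np.where(np.isfinite(se_full), np.exp(beta_full + crit * se_full), hr)
    return CoxFit(
        names=names,
        coef=beta_full,
        se=se_full,
        hazard_ratio=hr,
        ci_low=ci_low,
        ci_high=ci_high,
        p=pvals,
        log_partial_likelihood=float(ll),
        ties_method=ties,
        n=int(len(times)),
        n_events=int(events.sum()),
        converged=converged,
        diverged=diverged,
        iterations=iterations,
    )


# ---------------------------------------------------------------------------
# ROC / chi-square
# ---------------------------------------------------------------------------


@dataclass
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.thresholds, "fpr": self.fpr, "tpr": self.tpr})


def roc_auc(marker, binary_outcome) -> RocResult:
    """ROC by threshold sweep; AUC = Mann–Whitney probability (ties count 0.5)."""
    marker = np.asarray(marker, float)
    outcome = np.asarray(binary_outcome, int)
    if len(np.unique(outcome)) < 2:
        raise DomainError("ROC needs both outcome classes present")
    if np.ptp(marker) == 0:
        # constant marker: chance-level diagonal by convention
        return RocResult(
            fpr=np.array([0.0, 1.0]),
            tpr=np.array([0.0, 1.0]),
            thresholds=np.array([np.inf, marker[0]]),
            auc=0.5,
        )
    fpr, tpr, thr = roc_curve(outcome, marker, drop_intermediate=False)
    return RocResult(fpr=fpr, tpr=tpr, thresholds=thr, auc=float(roc_auc_score(outcome, marker)))


def chi_square_association(table) -> tuple[float, int, float]:
    """Pearson chi-square on a 2×K count table, no continuity correction."""
    table = np.asarray(table, float)
    if (table < 0).any() or not np.allclose(table, np.round(table)):
        raise DomainError("counts must be nonnegative integers")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise DomainError("chi-square table has a zero margin")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)


# ---------------------------------------------------------------------------
# stratified analysis and composite report
# ---------------------------------------------------------------------------


def _surv_columns(sheet: pd.DataFrame, endpoint: str | None) -> pd.DataFrame:
    rows = sheet.dropna(subset=["time", "event"])
    if endpoint is not None and "endpoint" in rows.columns:
        known = rows["endpoint"].isin(["unknown"]) | rows["endpoint"].isna()
        rows = rows[(rows["endpoint"] == endpoint) | known]
    return rows


def _group_analysis(marker: pd.Series, rows: pd.DataFrame, threshold: float | None):
    split = mean_split(marker.loc[rows.index], threshold=threshold)
    times = rows["time"].to_numpy(float)
    events = rows["event"].to_numpy(int)
    labels = split.labels.to_numpy()
    curves = {
        lab: km_estimate(times[labels == lab], events[labels == lab]) for lab in ("low", "high")
    }
    chi2, df, p = log_rank(times, events, labels)
    fit = cox_fit(
        pd.DataFrame({"low_vs_high": (labels == "low").astype(float)}, index=rows.index),
        times,
        events,
    )
    return {
        "threshold": split.threshold,
        "n_low": split.n_low,
        "n_high": split.n_high,
        "km": curves,
        "five_year": {lab: curves[lab].survival_at(FIVE_YEARS_MONTHS) for lab in curves},
        "log_rank": {"chi2": chi2, "df": df, "p": p},
        "cox": fit,
    }


def ipi_stratified_analysis(
    marker: pd.Series,
    sheet: pd.DataFrame,
    endpoint: str | None = "OS",
    per_stratum_threshold: bool = False,
) -> dict:
    """Repeat the mean-split survival comparison within IPI 0–2 and 3–5 strata.

    The split threshold is the whole-cohort mean by default (recomputed per
    stratum with ``per_stratum_threshold=True``).  Strata whose split would
    leave fewer than 2 patients in a group are skipped with a warning.
    """
    rows = _surv_columns(sheet, endpoint).dropna(subset=["ipi"])
    results: dict[str, dict] = {}
    cohort_threshold = (
        float(marker.loc[rows.index].mean()) if len(rows) else None
    )
    strata = {"ipi_low_0_2": rows[rows["ipi"] <= 2], "ipi_high_3_5": rows[rows["ipi"] >= 3]}
    for name, sub in strata.items():
        if len(sub) < 4:
            logger.warning("stratum %s skipped: too few patients (%d)", name, len(sub))
            continue
        thr = None if per_stratum_threshold else cohort_threshold
        try:
            res = _group_analysis(marker, sub, thr)
        except DegenerateSplitError:
            logger.warning("stratum %s skipped: degenerate split", name)
            continue
        if min(res["n_low"], res["n_high"]) < 2:
            logger.warning("stratum %s skipped: a split group has <2 patients", name)
            continue
        results[name] = res
    return results


_CATEGORICAL_CODING = {
    "gender": lambda s: (s == "Male").astype(float),
    "subtype": lambda s: (s == "GCB").astype(float),
    "ipi_group": lambda s: (pd.to_numeric(s, errors="coerce") >= 3).astype(float),
}


def _encode_covariate(sheet: pd.DataFrame, name: str) -> pd.Series:
    if name == "ipi_group":
        return _CATEGORICAL_CODING[name](sheet["ipi"])
    col = sheet[name]
    if name in _CATEGORICAL_CODING:
        return _CATEGORICAL_CODING[name](col)
    return pd.to_numeric(col, errors="coerce").astype(float)


def survival_report(
    sheet: pd.DataFrame,
    marker: pd.Series,
    covariates: list[str] | None = None,
    endpoint: str = "OS",
    ties: str = "efron",
) -> dict:
    """Assemble the full prognostic report for one biomarker.

    Contains group sizes, per-group KM curves and 5-year rates, the log-rank
    comparison, univariate Cox fits (dichotomised and continuous marker), an
    optional multivariate Cox fit, and chi-square association tables for
    categorical covariates.
    """
    covariates = covariates or []
    rows = _surv_columns(sheet, endpoint)
    if rows.empty:
        raise DomainError(f"no patients with {endpoint} survival data")
    marker = marker.loc[rows.index].astype(float)
    base = _group_analysis(marker, rows, threshold=None)
    times = rows["time"].to_numpy(float)
    events = rows["event"].to_numpy(int)
    low = (marker.to_numpy() < base["threshold"]).astype(float)

    cont = cox_fit(pd.DataFrame({"marker": marker.to_numpy()}, index=rows.index), times, events, ties=ties)
    report = {
        "endpoint": endpoint,
        "n": int(len(rows)),
        "threshold": base["threshold"],
        "n_low": base["n_low"],
        "n_high": base["n_high"],
        "five_year": base["five_year"],
        "log_rank": base["log_rank"],
        "univariate": {
            "low_vs_high": base["cox"],
            "marker_continuous": cont,
        },
        "km": base["km"],
    }
    if covariates:
        design = {"low_vs_high": low}
        keep = np.ones(len(rows), bool)
        for cov in covariates:
            enc = _encode_covariate(rows, cov).to_numpy(float)
            design[cov] = enc
            keep &= ~np.isnan(enc)
        X = pd.DataFrame(design, index=rows.index)[keep]
        report["multivariate"] = cox_fit(X, times[keep], events[keep], ties=ties)
        assoc = {}
        for cov in covariates:
            enc = _encode_covariate(rows, cov)
            valid = enc.notna()
            if enc[valid].nunique() < 2:
                continue
            tab = pd.crosstab(enc[valid], pd.Series(low, index=rows.index)[valid])
            try:
                chi2, df, p = chi_square_association(tab.to_numpy())
            except DomainError:
                continue
            assoc[cov] = {"chi2": chi2, "df": df, "p": p}
        report["associations"] = assoc
    return report


def write_km_curve(curve: KMCurve, path) -> None:
    frame = curve.to_frame()
    censor = pd.DataFrame(
        {
            "time": curve.censor_times,
            "at_risk": pd.NA,
            "events": 0,
            "survival": [curve.survival_at(t) for t in curve.censor_times],
        }
    )
    censor["censored"] = 1
    frame["censored"] = 0
    pd.concat([frame, censor]).sort_values("time").to_csv(path, sep="\t", index=False)
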