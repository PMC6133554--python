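"""Phenotype-stratified survival analysis.

Patients carry a bivariate immune phenotype — the pair of topography
labels for a lymphoid marker (CD8) and a myeloid marker (CD163), nine
combinations in total — plus standard confounders (UICC stage, age,
sex).  Prognosis is quantified with a multivariable Cox proportional-
hazards model (Efron tie correction, Newton-Raphson to gradient norm
below 1e-8), Kaplan-Meier curves with Greenwood variance, and the
k-sample log-rank test.

The phenotype enters the Cox model as eight indicator terms against the
reference 'CD8-cold, CD163-cold'; stage as three indicators against
stage I; age continuous per year; sex as one indicator.  Wald p-values
and confidence intervals are the default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .topography import LABELS

log = logging.getLogger(__name__)

STAGES = ("I", "II", "III", "IV")


def phenotype_name(label_a: str, label_b: str, marker_a: str = "CD8", marker_b: str = "CD163") -> str:
    return f"{marker_a}-{label_a}_{marker_b}-{label_b}"


def all_phenotypes(marker_a: str = "CD8", marker_b: str = "CD163") -> list[str]:
    return [phenotype_name(a, b, marker_a, marker_b) for a in LABELS for b in LABELS]


REFERENCE_PHENOTYPE = phenotype_name("cold", "cold")


class ConvergenceError(RuntimeError):
    """Newton iterations failed to reach the gradient tolerance."""


@dataclass
class CoxResult:
    """Fitted Cox model: per-term estimates and fit metadata."""

    table: pd.DataFrame  # index: term; columns: coef, hr, se, z, p, ci_low, ci_high
    n: int
    n_events: int
    loglik: float
    converged: bool
    n_iter: int
    grad_norm: float
    ties: str = "efron"
    non_estimable: tuple[str, ...] = ()
    information: np.ndarray | None = field(default=None, repr=False)

    def hazard_ratio(self, term: str) -> float:
        return float(self.table.loc[term, "hr"])


def _efron_loglik(beta: np.ndarray, X: np.ndarray, time: np.ndarray, event: np.ndarray,
                  want_derivs: bool = True):
    """Efron partial log-likelihood with gradient and observed information.

    Rows are processed in descending time order so the risk set at each
    event time is a prefix; tied events at one time share the Efron
    correction terms.
    """
    n, p = X.shape
    # column-centering leaves the partial likelihood, gradient and beta-hat
    # unchanged (score residuals sum to zero) but removes the cancellation
    # noise that otherwise floors the achievable gradient norm
    X = X - X.mean(axis=0)
    order = np.argsort(-time, kind="stable")
    t_s, e_s, X_s = time[order], event[order], X[order]
    eta = np.clip(X_s @ beta, -200.0, 200.0)
    w = np.exp(eta)

    cum0 = np.cumsum(w)
    cum1 = np.cumsum(w[:, None] * X_s, axis=0)
    if want_derivs:
        outer = w[:, None, None] * (X_s[:, :, None] * X_s[:, None, :])
        cum2 = np.cumsum(outer, axis=0)

    ll = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j < n and t_s[j] == t_s[i]:
            j += 1
        deaths = np.flatnonzero(e_s[i:j]) + i
        d = len(deaths)
        if d:
            last = j - 1  # full risk set = everyone with time >= t
            S0, S1 = cum0[last], cum1[last]
            Xd = X_s[deaths]
            wd = w[deaths]
            D0, D1 = wd.sum(), wd @ Xd
            ll += float(eta[deaths].sum())
            grad += Xd.sum(axis=0)
            if want_derivs:
                S2 = cum2[last]
                D2 = (wd[:, None, None] * (Xd[:, :, None] * Xd[:, None, :])).sum(axis=0)
            for l in range(d):
                frac = l / d
                phi0 = S0 - frac * D0
                phi1 = S1 - frac * D1
                mean = phi1 / phi0
                ll -= float(np.log(phi0))
                grad -= mean
                if want_derivs:
                    phi2 = S2 - frac * D2
                    info += phi2 / phi0 - np.outer(mean, mean)
        i = j
    if want_derivs:
        return ll, grad, info
    return ll, grad


def _newton_cox(X: np.ndarray, time: np.ndarray, event: np.ndarray,
                beta0: np.ndarray | None = None, tol: float = 1e-9,
                max_iter: int = 60) -> tuple[np.ndarray, float, np.ndarray, int, float]:
    p = X.shape[1]
    beta = np.zeros(p) if beta0 is None else np.asarray(beta0, float).copy()
    ll, grad, info = _efron_loglik(beta, X, time, event)
    for it in range(1, max_iter + 1):
        gnorm = float(np.linalg.norm(grad, ord=np.inf))
        if gnorm < tol:
            return beta, ll, info, it - 1, gnorm
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.solve(info + 1e-8 * np.eye(p), grad)
        # step-halving keeps the partial likelihood non-decreasing; the
        # acceptance slack scales with |ll| so fp noise near the optimum
        # cannot reject full Newton steps
        scale = 1.0
        slack = 1e-10 * max(1.0, abs(ll))
        for _ in range(40):
            cand = beta + scale * step
            ll_new, grad_new, info_new = _efron_loglik(cand, X, time, event)
            if ll_new >= ll - slack:
                break
            scale *= 0.5
        beta, ll, grad, info = cand, ll_new, grad_new, info_new
    gnorm = float(np.linalg.norm(grad, ord=np.inf))
    if gnorm >= tol:
        raise ConvergenceError(f"Cox Newton did not converge: |grad|_inf = {gnorm:.3e}")
    return beta, ll, info, max_iter, gnorm


def fit_cox(
    X: pd.DataFrame,
    time: Sequence[float],
    event: Sequence[bool],
    tol: float = 1e-9,
    max_iter: int = 60,
    alpha: float = 0.05,
) -> CoxResult:
    """Maximize the Efron partial likelihood over the columns of ``X``.

    Binary indicator columns with no events among their carriers (or no
    carriers at all) are complete-separation hazards; they are flagged
    non-estimable, excluded from the fit, and reported with NaN
    estimates.  Constant columns raise.
    """
    X = pd.DataFrame(X).astype(float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    if (time <= 0).any():
        raise ValueError("all follow-up times must be positive")
    if event.sum() < 2:
        raise ValueError(f"need at least 2 events, got {int(event.sum())}")
    constant = [c for c in X.columns if X[c].nunique() <= 1]
    if constant:
        raise ValueError(f"constant covariates cannot be estimated: {constant}")

    non_estimable = []
    for col in X.columns:
        vals = X[col].to_numpy()
        if set(np.unique(vals)) <= {0.0, 1.0}:
            carriers = vals == 1.0
            if carriers.sum() == 0 or event[carriers].sum() == 0 or event[~carriers].sum() == 0:
                non_estimable.append(col)
    if non_estimable:
        log.warning("non-estimable terms (complete separation): %s", non_estimable)
    fit_cols = [c for c in X.columns if c not in non_estimable]
    if not fit_cols:
        raise ValueError("no estimable covariates remain")

    Xf = X[fit_cols].to_numpy(float)
    beta, ll, info, n_iter, gnorm = _newton_cox(Xf, time, event, tol=tol, max_iter=max_iter)
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    zcrit = stats.norm.ppf(1.0 - alpha / 2.0)

    table = pd.DataFrame(
        index=pd.Index(X.columns, name="term"),
        columns=["coef", "hr", "se", "z", "p", "ci_low", "ci_high"],
        dtype=float,
    )
    table.loc[fit_cols, "coef"] = beta
    table.loc[fit_cols, "se"] = se
    table.loc[fit_cols, "z"] = z
    table.loc[fit_cols, "p"] = pvals
    table.loc[fit_cols, "ci_low"] = np.exp(beta - zcrit * se)
    table.loc[fit_cols, "ci_high"] = np.exp(beta + zcrit * se)
    table["hr"] = np.exp(table["coef"])

    return CoxResult(
        table=table, n=len(time), n_events=int(event.sum()), loglik=ll,
        converged=True, n_iter=n_iter, grad_norm=gnorm,
        non_estimable=tuple(non_estimable), information=info,
    )


def cox_score_test(X: pd.DataFrame | np.ndarray, time, event) -> tuple[float, int, float]:
    """Score (Rao) test of beta = 0 for the Cox model; equals the
    log-rank statistic for a single group indicator on untied data."""
    Xa = np.asarray(pd.DataFrame(X), dtype=float)
    time = np.asarray(time, float)
    event = np.asarray(event, bool)
    _, grad, info = _efron_loglik(np.zeros(Xa.shape[1]), Xa, time, event)
    chi2 = float(grad @ np.linalg.solve(info, grad))
    df = Xa.shape[1]
    return chi2, df, float(stats.chi2.sf(chi2, df))


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank


def km_estimate(time: Sequence[float], event: Sequence[bool], alpha: float = 0.05) -> pd.DataFrame:
    """Product-limit estimator with Greenwood variance and log-log CIs.

    Returns one row per event time (plus t = 0 with S = 1): time,
    n_risk, n_events, n_censored, survival, var, ci_low, ci_high.  The
    survival curve steps down at event times only; with no censoring it
    equals the empirical survival function.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    if len(time) == 0:
        raise ValueError("no records")
    order = np.argsort(time, kind="stable")
    t_s, e_s = time[order], event[order]
    n = len(t_s)

    rows = [(0.0, n, 0, 0, 1.0, 0.0, 1.0, 1.0)]
    S = 1.0
    gw = 0.0  # running sum d / (n (n - d))
    zcrit = stats.norm.ppf(1.0 - alpha / 2.0)
    i = 0
    while i < n:
        j = i
        while j < n and t_s[j] == t_s[i]:
            j += 1
        d = int(e_s[i:j].sum())
        c = (j - i) - d
        at_risk = n - i
        if d:
            S *= 1.0 - d / at_risk
            if at_risk > d:
                gw += d / (at_risk * (at_risk - d))
            var = S * S * gw
            if 0.0 < S < 1.0:
                se_ll = np.sqrt(gw) / abs(np.log(S))
                lo = S ** np.exp(zcrit * se_ll)
                hi = S ** np.exp(-zcrit * se_ll)
            else:
                lo = hi = S
            rows.append((float(t_s[i]), at_risk, d, c, S, var, lo, hi))
        i = j
    return pd.DataFrame(
        rows,
        columns=["time", "n_risk", "n_events", "n_censored", "survival", "var", "ci_low", "ci_high"],
    )


def km_by_group(df: pd.DataFrame, group_col: str = "phenotype",
                time_col: str = "time", event_col: str = "event") -> pd.DataFrame:
    """Long-format KM export: group, time, survival, ci_low, ci_high, n_risk."""
    parts = []
    for group, sub in df.groupby(group_col, sort=True):
        km = km_estimate(sub[time_col], sub[event_col])
        km.insert(0, "group", group)
        parts.append(km)
    return pd.concat(parts, ignore_index=True)[
        ["group", "time", "survival", "ci_low", "ci_high", "n_risk"]
    ]


@dataclass
class LogrankResult:
    statistic: float
    df: int
    p: float


def logrank_test(groups: Sequence[tuple[Sequence[float], Sequence[bool]]]) -> LogrankResult:
    """K-sample log-rank: observed minus expected deaths over pooled
    event times, with the hypergeometric covariance."""
    if len(groups) < 2:
        raise ValueError("log-rank requires at least two groups")
    times = [np.asarray(t, float) for t, _ in groups]
    events = [np.asarray(e, bool) for _, e in groups]
    if any(len(t) == 0 for t in times):
        raise ValueError("empty group")
    if sum(int(e.sum()) for e in events) == 0:
        raise ValueError("no events in any group")

    k = len(groups)
    all_times = np.concatenate(times)
    all_events = np.concatenate(events)
    event_times = np.unique(all_times[all_events])

    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for t in event_times:
        n_i = np.array([float((g >= t).sum()) for g in times])
        d_i = np.array([float(((g == t) & e).sum()) for g, e in zip(times, events)])
        n_tot, d_tot = n_i.sum(), d_i.sum()
        if n_tot <= 1:
            continue
        O += d_i
        E += d_tot * n_i / n_tot
        f = d_tot * (n_tot - d_tot) / (n_tot - 1.0)
        p_i = n_i / n_tot
        V += f * (np.diag(p_i) - np.outer(p_i, p_i))
    diff = (O - E)[:-1]
    Vsub = V[:-1, :-1]
    chi2 = float(diff @ np.linalg.solve(Vsub, diff))
    df = k - 1
    return LogrankResult(statistic=chi2, df=df, p=float(stats.chi2.sf(chi2, df)))


def logrank_by_group(df: pd.DataFrame, group_col: str = "phenotype",
                     time_col: str = "time", event_col: str = "event") -> LogrankResult:
    groups = [
        (sub[time_col].to_numpy(float), sub[event_col].to_numpy(bool))
        for _, sub in df.groupby(group_col, sort=True)
    ]
    return logrank_test(groups)


# ---------------------------------------------------------------------------
# Design matrices and the bivariate phenotype hazard table


def build_design(
    records: pd.DataFrame,
    reference_phenotype: str = REFERENCE_PHENOTYPE,
    phenotypes: Sequence[str] | None = None,
    covariates: Sequence[str] = ("stage", "age", "sex"),
) -> pd.DataFrame:
    """Indicator design: 8 phenotype terms vs the reference, stage II-IV
    vs stage I, age per year, sex (male = 1)."""
    if phenotypes is None:
        phenotypes = all_phenotypes()
    if reference_phenotype not in phenotypes:
        raise ValueError(f"reference phenotype {reference_phenotype!r} not among phenotypes")
    cols = {}
    present = records["phenotype"]
    for ph in phenotypes:
        if ph == reference_phenotype:
            continue
        cols[ph] = (present == ph).astype(float)
    if "stage" in covariates:
        stage = records["stage"].astype(str)
        bad = set(stage.unique()) - set(STAGES)
        if bad:
            raise ValueError(f"unknown UICC stages {sorted(bad)}")
        for s in STAGES[1:]:
            cols[f"stage_{s}"] = (stage == s).astype(float)
    if "age" in covariates:
        cols["age"] = records["age"].astype(float)
    if "sex" in covariates:
        sex = records["sex"]
        if sex.dtype == object:
            cols["sex_male"] = (sex.astype(str).str.lower().isin(["male", "m", "1"])).astype(float)
        else:
            cols["sex_male"] = sex.astype(float)
    return pd.DataFrame(cols, index=records.index)


def fit_phenotype_cox(
    records: pd.DataFrame,
    reference_phenotype: str = REFERENCE_PHENOTYPE,
    covariates: Sequence[str] = ("stage", "age", "sex"),
) -> CoxResult:
    """One multivariable fit: phenotype indicators + confounders.

    Patients with a missing phenotype (e.g. unlabelable slides) are
    dropped with a logged count before fitting.
    """
    usable = records.dropna(subset=["phenotype"])
    n_dropped = len(records) - len(usable)
    if n_dropped:
        log.warning("dropping %d patients with missing phenotype", n_dropped)
    ref_mask = usable["phenotype"] == reference_phenotype
    if ref_mask.sum() == 0 or usable.loc[ref_mask, "event"].sum() < 1:
        raise ValueError(f"reference group {reference_phenotype!r} is empty or has no events")
    X = build_design(usable, reference_phenotype, covariates=covariates)
    # phenotypes with no carriers at all cannot be estimated; drop the column
    empty = [c for c in X.columns if X[c].nunique() <= 1 and not c.startswith(("stage_", "age", "sex"))]
    X = X.drop(columns=empty)
    result = fit_cox(X, usable["time"], usable["event"])
    result.non_estimable = tuple(sorted(set(result.non_estimable) | set(empty)))
    return result


def phenotype_hazard_table(
    records: pd.DataFrame,
    reference_phenotype: str = REFERENCE_PHENOTYPE,
    marker_a: str = "CD8",
    marker_b: str = "CD163",
    covariates: Sequence[str] = ("stage", "age", "sex"),
) -> dict:
    """3x3 hazard-ratio grid for the bivariate phenotypes.

    Rows are marker A's labels, columns marker B's.  The reference cell
    carries HR = 1 by definition; cells with no patients carry no HR;
    non-estimable cells (carriers but complete separation) are flagged.
    Returns dict with 'hr', 'p', 'n' DataFrames and the CoxResult.
    """
    result = fit_phenotype_cox(records, reference_phenotype, covariates)
    idx = pd.Index(LABELS, name=marker_a)
    cols = pd.Index(LABELS, name=marker_b)
    hr = pd.DataFrame(np.nan, index=idx, columns=cols)
    p = pd.DataFrame(np.nan, index=idx, columns=cols)
    n = pd.DataFrame(0, index=idx, columns=cols, dtype=int)
    counts = records.dropna(subset=["phenotype"])["phenotype"].value_counts()
    for a in LABELS:
        for b in LABELS:
            ph = phenotype_name(a, b, marker_a, marker_b)
            n.loc[a, b] = int(counts.get(ph, 0))
            if ph == reference_phenotype:
                hr.loc[a, b] = 1.0
            elif n.loc[a, b] > 0 and ph in result.table.index:
                hr.loc[a, b] = result.table.loc[ph, "hr"]
                p.loc[a, b] = result.table.loc[ph, "p"]
    return {"hr": hr, "p": p, "n": n, "cox": result, "reference": reference_phenotype}


def density_cox(
    records: pd.DataFrame,
    density_col: str,
    covariates: Sequence[str] = ("stage", "age", "sex"),
) -> CoxResult:
    """Univariate analogue: one compartment's density as a continuous
    covariate plus the same confounders (the negative-control analysis —
    raw densities alone are typically not prognostic)."""
    usable = records.dropna(subset=[density_col])
    X = build_design(usable, phenotypes=[REFERENCE_PHENOTYPE],
                     reference_phenotype=REFERENCE_PHENOTYPE, covariates=covariates)
    X.insert(0, density_col, usable[density_col].astype(float))
    return fit_cox(X, usable["time"], usable["event"])
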