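"""Survival machinery: Aalen additive hazards, Cox PH, LRT, Kaplan-Meier.

The additive-hazard estimator is implemented directly as Aalen's
least-squares increment estimator: with an intercept-only design the
cumulative baseline reproduces the Nelson-Aalen estimator, curve
estimation freezes at the first event time where the at-risk design loses
rank, and the per-covariate test is B_j(t*)/SE(B_j(t*)) at a stable test
time (see :func:`fit_additive_hazard`).  Cox proportional hazards is a
Newton-Raphson fit of the Efron-tie partial likelihood (cross-checked
against lifelines in the test suite); Kaplan-Meier curves delegate to
``lifelines``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from lifelines import KaplanMeierFitter


class SurvivalError(ValueError):
    """Raised when a survival fit cannot be carried out."""


@dataclass
class AdditiveHazardFit:
    """Result of the Aalen least-squares additive-hazard fit.

    ``cum_coef`` holds the cumulative regression curves B_j(t) (step
    functions changing only at event times; the intercept column is the
    cumulative baseline hazard, i.e. the Nelson-Aalen estimator when it is
    the only column).  ``cum_var`` holds the matching pointwise variance
    estimates.  ``z`` and ``p`` are the per-covariate tests
    B_j(t*)/SE(B_j(t*)) evaluated at ``test_tau`` (see
    :func:`fit_additive_hazard`); ``tau`` is the last event time at which
    the at-risk design had full rank, where the curves end.
    """

    times: np.ndarray
    cum_coef: pd.DataFrame
    cum_var: pd.DataFrame
    z: pd.Series
    p: pd.Series
    tau: float
    n: int
    n_events: int
    test_tau: float = float("nan")
    sup_z: Optional[pd.Series] = None
    sup_p: Optional[pd.Series] = None

    def coefficient_slope(self, name: str) -> float:
        """Average effect per unit time, B_j(t*)/t* at the test time."""
        t = self.test_tau if np.isfinite(self.test_tau) else self.tau
        return float(self.cum_coef[name].loc[t] / t)


def _as_design(design: pd.DataFrame) -> pd.DataFrame:
    if not isinstance(design, pd.DataFrame):
        design = pd.DataFrame(np.asarray(design))
        design.columns = [f"x{j}" for j in range(design.shape[1])]
    if design.isna().any().any():
        raise SurvivalError("design matrix contains missing values")
    return design


def fit_additive_hazard(
    time: Sequence[float],
    event: Sequence[int],
    design: pd.DataFrame,
    sup_test: bool = False,
    test_time: str = "stable",
) -> AdditiveHazardFit:
    """Fit the additive (Aalen) hazard model h(t|X) = X' alpha(t).

    At each distinct event time t the increment of the cumulative
    coefficient vector is the least-squares solution
    ``(X'X)^{-1} X' dN`` over the at-risk set, with tied events processed
    jointly.  The pointwise variance uses the optional-variation estimator
    ``(X'X)^{-1} X' diag(dN) X (X'X)^{-1}`` accumulated over event times.
    Estimation stops (curves frozen) at the first event time where the
    at-risk design is rank deficient.

    Parameters
    ----------
    time, event
        Follow-up times (> 0) and 0/1 event indicators.
    design
        Numeric design matrix including an intercept column.
    sup_test
        Also compute a supremum-type test over the curve (sensitivity
        analysis).
    test_time
        Where the per-covariate z-test B_j(t)/SE(B_j(t)) is evaluated.
        ``"stable"`` (default) uses the last event time with at least
        p + 20 subjects at risk — increments estimated on at-risk sets
        close to the column count p are noise-dominated and would swamp
        the test — falling back to the last estimable time when no event
        time qualifies (small samples).  ``"endpoint"`` always uses the
        last estimable event time.
    """
    t = np.asarray(time, dtype=float)
    d = np.asarray(event, dtype=int)
    X = _as_design(design)
    Xv = X.to_numpy(dtype=float)
    n, p = Xv.shape
    if len(t) != n or len(d) != n:
        raise SurvivalError("time/event/design lengths differ")
    if d.sum() == 0:
        raise SurvivalError("no events observed; additive hazard fit undefined")

    event_times = np.unique(t[d == 1])
    # Build the at-risk Gram matrix X'X incrementally from the latest event
    # time backwards: the at-risk set {i : t_i >= s} only grows as s
    # decreases, so each event time costs one rank-k update plus one solve.
    order = np.argsort(-t)
    t_sorted = t[order]
    X_sorted = Xv[order]
    increments, var_increments, singular, risk_counts = [], [], [], []
    G = np.zeros((p, p))
    ptr = 0
    for et in event_times[::-1]:
        while ptr < n and t_sorted[ptr] >= et:
            xi = X_sorted[ptr]
            G += np.outer(xi, xi)
            ptr += 1
        risk_counts.append(ptr)
        Xe = Xv[(t == et) & (d == 1)]
        if np.linalg.matrix_rank(G, tol=1e-8 * max(1.0, np.trace(G))) < p:
            increments.append(None)
            var_increments.append(None)
            singular.append(True)
            continue
        Ginv = np.linalg.inv(G)
        dB = Ginv @ Xe.sum(axis=0)
        Ae = Xe @ Ginv  # rows: (X'X)^{-1} x_i for each tied event
        increments.append(dB)
        var_increments.append((Ae**2).sum(axis=0))
        singular.append(False)
    increments.reverse()
    var_increments.reverse()
    singular.reverse()
    risk_counts.reverse()

    if singular[0]:
        raise SurvivalError(
            "design rank-deficient at the first event time; remove collinear columns"
        )
    coefs, vars_, times_kept = [], [], []
    B = np.zeros(p)
    V = np.zeros(p)
    tau = None
    for et, dB, dV, sing in zip(event_times, increments, var_increments, singular):
        if sing:  # freeze curves at the first rank-deficient event time
            break
        B = B + dB
        V = V + dV
        coefs.append(B.copy())
        vars_.append(V.copy())
        times_kept.append(et)
        tau = et

    times_arr = np.asarray(times_kept)
    cum_coef = pd.DataFrame(coefs, index=times_arr, columns=X.columns)
    cum_var = pd.DataFrame(vars_, index=times_arr, columns=X.columns)

    if test_time == "stable":
        stable = [k for k in range(len(times_kept)) if risk_counts[k] >= p + 20]
        test_idx = stable[-1] if stable else len(times_kept) - 1
    elif test_time == "endpoint":
        test_idx = len(times_kept) - 1
    else:
        raise ValueError(f"unknown test_time policy {test_time!r}")
    se = np.sqrt(np.maximum(cum_var.iloc[test_idx].to_numpy(), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = cum_coef.iloc[test_idx].to_numpy() / se
    z = pd.Series(np.where(se > 0, z, np.nan), index=X.columns)
    pval = pd.Series(2 * stats.norm.sf(np.abs(z)), index=X.columns)

    fit = AdditiveHazardFit(
        times=times_arr,
        cum_coef=cum_coef,
        cum_var=cum_var,
        z=z,
        p=pval,
        tau=float(tau),
        n=n,
        n_events=int(d.sum()),
        test_tau=float(times_kept[test_idx]),
    )
    if sup_test:
        fit.sup_z, fit.sup_p = _supremum_test(cum_coef, cum_var)
    return fit


def _supremum_test(cum_coef: pd.DataFrame, cum_var: pd.DataFrame):
    """Supremum test: max_t |B_j(t)| / SE_j(tau), Brownian-motion reference.

    Under the null B_j, time-changed by its variance, behaves like
    standard Brownian motion on [0, 1]; the p-value is
    P(sup_{s<=1} |W(s)| >= z) computed from the classical series.
    """
    se_tau = np.sqrt(np.maximum(cum_var.iloc[-1].to_numpy(), 1e-300))
    sup = (cum_coef.abs().to_numpy() / se_tau).max(axis=0)
    sup_z = pd.Series(sup, index=cum_coef.columns)

    def tail(a: float) -> float:
        if a <= 0:
            return 1.0
        k = np.arange(50)
        terms = ((-1) ** k / (2 * k + 1)) * np.exp(-((2 * k + 1) ** 2) * np.pi**2 / (8 * a**2))
        return float(np.clip(1 - (4 / np.pi) * terms.sum(), 0.0, 1.0))

    sup_p = pd.Series([tail(a) for a in sup], index=cum_coef.columns)
    return sup_z, sup_p


@dataclass
class CoxFit:
    """Cox proportional-hazards fit (Efron tie handling, via lifelines)."""

    coef: pd.Series
    se: pd.Series
    p: pd.Series
    log_likelihood: float
    log_likelihood_null: float
    n: int
    n_events: int
    covariates: tuple

    def hazard_ratios(self) -> pd.Series:
        return np.exp(self.coef)


def _efron_ll_grad_hess(beta, t, d, X):
    """Efron-tie-corrected partial log-likelihood with gradient and Hessian.

    Risk-set sums are accumulated over subjects sorted by decreasing
    follow-up time, so the whole evaluation is O(n p^2) plus the tied
    event groups.
    """
    n, p = X.shape
    order = np.argsort(-t, kind="stable")
    ts, ds, Xs = t[order], d[order], X[order]
    eta = Xs @ beta
    eta = np.clip(eta, -500, 500)
    w = np.exp(eta)
    wX = w[:, None] * Xs
    wXX = np.einsum("i,ij,ik->ijk", w, Xs, Xs)
    S0 = np.cumsum(w)
    S1 = np.cumsum(wX, axis=0)
    S2 = np.cumsum(wXX, axis=0)

    ll = 0.0
    U = X[d == 1].sum(axis=0)  # events' own covariates enter the gradient once
    H = np.zeros((p, p))
    uniq, counts = np.unique(ts[ds == 1], return_counts=True)
    risk_idx = np.searchsorted(-ts, -uniq, side="right") - 1  # last index with t >= et

    single = counts == 1
    if single.any():  # vectorized path for untied event times
        idx = risk_idx[single]
        denom = S0[idx]
        g = S1[idx] / denom[:, None]
        ll += eta[ds == 1][np.isin(ts[ds == 1], uniq[single])].sum() - np.log(denom).sum()
        U -= g.sum(axis=0)
        H += np.einsum("i,ijk->jk", 1.0 / denom, S2[idx]) - g.T @ g

    for et, k, in_risk in zip(uniq[~single], counts[~single], risk_idx[~single]):
        tie = (ts == et) & (ds == 1)
        T0 = w[tie].sum()
        T1 = wX[tie].sum(axis=0)
        T2 = wXX[tie].sum(axis=0)
        ll += eta[tie].sum()
        for c in np.arange(k) / k:
            denom = S0[in_risk] - c * T0
            g = (S1[in_risk] - c * T1) / denom
            h = (S2[in_risk] - c * T2) / denom - np.outer(g, g)
            ll -= np.log(denom)
            U -= g
            H += h
    return ll, U, H


def fit_cox(time, event, design: pd.DataFrame, max_iter: int = 100, tol: float = 1e-8) -> CoxFit:
    """Fit Cox PH by Newton-Raphson on the Efron-tie partial likelihood.

    Iterates with step-halving (the partial likelihood increases
    monotonically across accepted steps) until the coefficient change
    falls below ``tol``.

    Raises
    ------
    SurvivalError
        On zero events, a single subject, constant covariate columns, or
        monotone likelihood (separation), naming the offending covariate.
    """
    X = _as_design(design)
    t = np.asarray(time, dtype=float)
    d = np.asarray(event, dtype=int)
    if len(t) < 2:
        raise SurvivalError("Cox fit requires at least two subjects")
    if d.sum() == 0:
        raise SurvivalError("Cox fit requires at least one event")
    sd = X.to_numpy(float).std(axis=0)
    if (sd == 0).any():
        const = list(X.columns[sd == 0])
        raise SurvivalError(f"constant covariate columns in Cox design: {const}")
    scale = sd.copy()
    Xv = X.to_numpy(float) / scale  # unit-scale columns for conditioning

    beta = np.zeros(X.shape[1])
    ll, U, H = _efron_ll_grad_hess(beta, t, d, Xv)
    ll_null = ll
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(H, U)
        except np.linalg.LinAlgError as exc:
            raise SurvivalError(f"singular information matrix: {exc}") from exc
        # step-halving keeps the likelihood non-decreasing
        factor = 1.0
        for _half in range(30):
            cand = beta + factor * step
            ll_new, U_new, H_new = _efron_ll_grad_hess(cand, t, d, Xv)
            if ll_new >= ll - 1e-12:
                break
            factor /= 2
        delta = np.max(np.abs(cand - beta))
        beta, ll, U, H = cand, ll_new, U_new, H_new
        if np.max(np.abs(beta)) > 50:
            worst = X.columns[int(np.argmax(np.abs(beta)))]
            raise SurvivalError(
                f"monotone likelihood (separation) on covariate {worst!r}"
            )
        if delta < tol:
            break
    else:
        worst = X.columns[int(np.argmax(np.abs(beta)))]
        raise SurvivalError(
            f"Cox fit did not converge; suspect separation on covariate {worst!r}"
        )
    cov = np.linalg.inv(H)
    se_scaled = np.sqrt(np.maximum(np.diag(cov), 0.0))
    coef = pd.Series(beta / scale, index=X.columns)
    se = pd.Series(se_scaled / scale, index=X.columns)
    with np.errstate(divide="ignore", invalid="ignore"):
        zstat = coef / se
    pvals = pd.Series(2 * stats.norm.sf(np.abs(zstat)), index=X.columns)
    return CoxFit(
        coef=coef,
        se=se,
        p=pvals,
        log_likelihood=float(ll),
        log_likelihood_null=float(ll_null),
        n=len(t),
        n_events=int(d.sum()),
        covariates=tuple(X.columns),
    )


def likelihood_ratio_test(full: CoxFit, reduced: CoxFit):
    """Nested-model LRT: chi2 = 2 (ll_full - ll_reduced), df = extra covariates.

    Raises :class:`SurvivalError` if the models are not nested on the same
    samples (reduced covariates must be a subset of full's, same n and
    events).
    """
    if not set(reduced.covariates) <= set(full.covariates):
        raise SurvivalError("models are not nested: reduced covariates not a subset")
    if (full.n, full.n_events) != (reduced.n, reduced.n_events):
        raise SurvivalError("LRT requires identical samples in both models")
    df = len(full.covariates) - len(reduced.covariates)
    chi2 = max(2.0 * (full.log_likelihood - reduced.log_likelihood), 0.0)
    p = 1.0 if df == 0 else float(stats.chi2.sf(chi2, df))
    return chi2, df, p


@dataclass
class KMCurves:
    """Kaplan-Meier product-limit curves and medians per group."""

    curves: Dict[str, pd.DataFrame]  # group -> columns [time, survival]
    medians: Dict[str, float]        # first t with S(t) <= 0.5; nan if never
    group_sizes: Dict[str, int]


def kaplan_meier(time, event, group) -> KMCurves:
    """Product-limit survival estimate per group.

    The median is the first time S(t) <= 0.5 and is NaN when the curve
    never reaches one half (e.g. everything censored).
    """
    t = np.asarray(time, dtype=float)
    d = np.asarray(event, dtype=int)
    g = np.asarray(group)
    curves, medians, sizes = {}, {}, {}
    for label in pd.unique(g):
        mask = g == label
        if mask.sum() == 0:
            raise SurvivalError(f"empty group {label!r}")
        km = KaplanMeierFitter()
        km.fit(t[mask], d[mask])
        sf = km.survival_function_.reset_index()
        sf.columns = ["time", "survival"]
        curves[str(label)] = sf
        med = km.median_survival_time_
        medians[str(label)] = float(med) if np.isfinite(med) else float("nan")
        sizes[str(label)] = int(mask.sum())
    return KMCurves(curves=curves, medians=medians, group_sizes=sizes)
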