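"""AICc all-subsets model selection, support rules, and model averaging.

Four response variables are analysed, each with its own global model and
error structure:

==================  =======================  ============================
response            family                   global fixed effects
==================  =======================  ============================
departure_doy       Gaussian LM              age + sex + year + age:sex
minutes_after_sunset  Gamma GLM, log link    age + sex + year
speed_kmh           Gaussian LM              age + sex + year + tailwind
km_per_day          Gaussian LMM (bird RI)   age + sex + year + midpoint_lat
                                             + distance_km + days_between
                                             + departure_doy
==================  =======================  ============================

Every subset of the global terms (respecting marginality for the
interaction) is fitted by full maximum likelihood and ranked by AICc.
Models are *supported* when their dAICc <= 2 and they beat the
intercept-only model by at least 2 AICc.  Supported models are screened
for uninformative parameters (a term whose addition costs AICc relative
to the nested model lacking it) and coefficients are model-averaged over
the supported set with full (zero-substitution) averaging and
unconditional 95% confidence intervals.

Indicator coding: age adult = 1 / juvenile = 0; sex male = 1 / female = 0;
year enters as a numeric calendar year.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special, stats

__all__ = [
    "FitResult", "RankedModelSet", "GLOBAL_TERMS",
    "build_design", "fit_linear", "fit_gamma_log", "fit_lmm", "aicc",
    "all_subsets", "rank_models", "supported_set", "flag_uninformative",
    "model_average", "group_t_test", "run_response_analysis",
]

#: global fixed-effect term lists per response
GLOBAL_TERMS: dict[str, tuple[str, ...]] = {
    "departure_doy": ("age", "sex", "year", "age:sex"),
    "minutes_after_sunset": ("age", "sex", "year"),
    "speed_kmh": ("age", "sex", "year", "tailwind"),
    "km_per_day": ("age", "sex", "year", "midpoint_lat", "distance_km",
                   "days_between", "departure_doy"),
}


@dataclass(frozen=True)
class FitResult:
    """One fitted candidate model."""

    terms: tuple[str, ...]
    estimates: dict[str, float]   # includes "intercept"
    std_errors: dict[str, float]
    loglik: float
    k: int      # every estimated parameter, incl. variance/dispersion/RI
    n: int
    family: str  # gaussian_lm | gamma_log_glm | gaussian_lmm
    singular: bool = False

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must count at least intercept + variance")
        # n > k + 1 is required only when AICc is computed; aicc() enforces it


@dataclass
class RankedModelSet:
    """Full candidate set with AICc ranking and averaged coefficients."""

    table: pd.DataFrame          # terms, loglik, n, k, aicc, delta, weight
    fits: list[FitResult]
    supported: list[FitResult]
    intercept_only_aicc: float
    averaged: pd.DataFrame | None   # coefficient, estimate, se, lo95, hi95
    uninformative: dict[str, list[str]]


def build_design(frame: pd.DataFrame, terms: Sequence[str]) -> pd.DataFrame:
    """Design matrix (with intercept) for a term list.

    Interaction terms ``a:b`` are products of their main-effect columns.
    """
    X = pd.DataFrame({"intercept": np.ones(len(frame))}, index=frame.index)
    for t in terms:
        if ":" in t:
            a, b = t.split(":")
            X[t] = frame[a].to_numpy(dtype=float) * frame[b].to_numpy(dtype=float)
        else:
            X[t] = frame[t].to_numpy(dtype=float)
    if len(frame) and np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError(f"rank-deficient design for terms {list(terms)}")
    return X


def fit_linear(frame: pd.DataFrame, response: str,
               terms: Sequence[str]) -> FitResult:
    """Ordinary least squares with Gaussian ML log-likelihood.

    k counts the coefficients plus the residual variance.
    """
    X = build_design(frame, terms)
    y = frame[response].to_numpy(dtype=float)
    res = sm.OLS(y, X).fit()
    return FitResult(
        terms=tuple(terms),
        estimates=dict(zip(X.columns, res.params)),
        std_errors=dict(zip(X.columns, res.bse)),
        loglik=float(res.llf), k=X.shape[1] + 1, n=len(y),
        family="gaussian_lm")


def _gamma_shape_mle(y: np.ndarray, mu: np.ndarray) -> float:
    """ML estimate of the Gamma shape given fitted means."""
    # profile loglik in alpha; solve d/dalpha = 0 with a bracketed root
    c = float(np.mean(np.log(y / mu) - y / mu))  # <= -1, equality iff y == mu

    def score(alpha: float) -> float:
        return math.log(alpha) + 1.0 - special.digamma(alpha) + c

    lo, hi = 1e-6, 1e8
    if score(hi) > 0:  # essentially exact fit; dispersion -> 0
        return hi
    return float(optimize.brentq(score, lo, hi, xtol=1e-10, rtol=1e-12))


def _gamma_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    return float(np.sum(stats.gamma.logpdf(y, a=alpha, scale=mu / alpha)))


def fit_gamma_log(frame: pd.DataFrame, response: str,
                  terms: Sequence[str], tol: float = 1e-8,
                  maxiter: int = 100) -> FitResult:
    """Gamma GLM with log link; dispersion by maximum likelihood.

    Coefficients come from IRLS (which does not depend on the dispersion);
    the shape parameter is then profiled out by ML and enters both the
    reported log-likelihood and k (= #coefficients + 1).
    """
    y = frame[response].to_numpy(dtype=float)
    n_bad = int(np.sum(y <= 0))
    if n_bad:
        raise ValueError(
            f"Gamma/log response must be strictly positive; {n_bad} row(s) <= 0")
    X = build_design(frame, terms)
    model = sm.GLM(y, X, family=sm.families.Gamma(sm.families.links.Log()))
    res = model.fit(maxiter=maxiter, tol=tol)
    if not res.converged:
        raise RuntimeError(
            f"Gamma GLM did not converge in {maxiter} IRLS iterations "
            f"(terms={list(terms)})")
    mu = np.asarray(res.fittedvalues)
    alpha = _gamma_shape_mle(y, mu)
    ll = _gamma_loglik(y, mu, alpha)
    phi = 1.0 / alpha  # dispersion
    # covariance of coefficients at the ML dispersion
    scale_ratio = math.sqrt(phi / res.scale) if res.scale > 0 else 1.0
    return FitResult(
        terms=tuple(terms),
        estimates=dict(zip(X.columns, res.params)),
        std_errors=dict(zip(X.columns, res.bse * scale_ratio)),
        loglik=ll, k=X.shape[1] + 1, n=len(y), family="gamma_log_glm")


def fit_lmm(frame: pd.DataFrame, response: str, terms: Sequence[str],
            group: str = "tag_id") -> FitResult:
    """Random-intercept linear mixed model, full ML (not REML).

    ML keeps log-likelihoods comparable across fixed-effect structures,
    which AICc ranking requires.  k = #fixed coefficients + 2 (random
    intercept variance + residual variance).  A boundary/singular fit sets
    ``singular=True`` instead of failing.
    """
    X = build_design(frame, terms)
    y = frame[response].to_numpy(dtype=float)
    singular = False
    res = None
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = sm.MixedLM(y, X, groups=frame[group])
        for method in ("lbfgs", "powell"):
            try:
                res = model.fit(reml=False, method=method)
                if res.converged:
                    break
            except np.linalg.LinAlgError:
                res = None
        for w in caught:
            if "singular" in str(w.message).lower() \
                    or "boundary" in str(w.message).lower():
                singular = True
    if res is not None:
        with np.errstate(invalid="ignore"):
            bse = np.asarray(res.bse_fe)
        if not np.isfinite(bse).all() or not np.isfinite(res.llf):
            res = None  # degenerate covariance at the variance boundary
    if res is None:
        # boundary case: the ML optimum has zero random-intercept
        # variance, where the LMM collapses to OLS
        ols = sm.OLS(y, X).fit()
        return FitResult(
            terms=tuple(terms),
            estimates=dict(zip(X.columns, ols.params)),
            std_errors=dict(zip(X.columns, ols.bse)),
            loglik=float(ols.llf), k=X.shape[1] + 2, n=len(y),
            family="gaussian_lmm", singular=True)
    re_var = float(np.asarray(res.cov_re).ravel()[0])
    if re_var <= 1e-8 * max(1.0, float(np.var(y))):
        singular = True
    return FitResult(
        terms=tuple(terms),
        estimates=dict(zip(X.columns, res.fe_params)),
        std_errors=dict(zip(X.columns, bse)),
        loglik=float(res.llf), k=X.shape[1] + 2, n=len(y),
        family="gaussian_lmm", singular=singular)


def aicc(fit: FitResult | tuple[float, int, int]) -> float:
    """AICc = -2 LL + 2k + 2k(k+1)/(n - k - 1)."""
    if isinstance(fit, FitResult):
        ll, k, n = fit.loglik, fit.k, fit.n
    else:
        ll, k, n = fit
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined for n={n}, k={k}")
    return -2.0 * ll + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def all_subsets(global_terms: Sequence[str],
                marginality: bool = True) -> list[tuple[str, ...]]:
    """All candidate term sets, intercept-only included.

    With ``marginality`` an interaction ``a:b`` only appears in sets that
    also contain both of its main effects.
    """
    terms = list(global_terms)
    out: list[tuple[str, ...]] = []
    for r in range(len(terms) + 1):
        for combo in combinations(terms, r):
            if marginality:
                ok = all(set(t.split(":")) <= {c for c in combo if ":" not in c}
                         for t in combo if ":" in t)
                if not ok:
                    continue
            out.append(tuple(combo))
    return out


def rank_models(fits: Sequence[FitResult]) -> pd.DataFrame:
    """AICc table with dAICc and Akaike weights over the full set."""
    if len(fits) < 2:
        raise ValueError("need >= 2 fits to rank")
    ns = {f.n for f in fits}
    if len(ns) != 1:
        raise ValueError(f"fits on differing row counts {sorted(ns)}: not comparable")
    rows = []
    for f in fits:
        rows.append({"terms": " + ".join(f.terms) if f.terms else "(intercept)",
                     "loglik": f.loglik, "n": f.n, "k": f.k, "aicc": aicc(f)})
    tab = pd.DataFrame(rows)
    tab["delta_aicc"] = tab["aicc"] - tab["aicc"].min()
    rel = np.exp(-0.5 * tab["delta_aicc"])
    tab["weight"] = rel / rel.sum()
    order = tab["aicc"].argsort(kind="mergesort")
    return tab.iloc[order].reset_index(drop=True)


def supported_set(fits: Sequence[FitResult], table: pd.DataFrame,
                  delta_max: float = 2.0,
                  intercept_margin: float = 2.0) -> list[FitResult]:
    """Models with dAICc <= delta_max that beat intercept-only by >= margin."""
    inter = [f for f in fits if not f.terms]
    if not inter:
        raise ValueError("candidate set must include the intercept-only model")
    a0 = aicc(inter[0])
    best = min(aicc(f) for f in fits)
    out = [f for f in fits
           if aicc(f) - best <= delta_max and aicc(f) <= a0 - intercept_margin]
    out.sort(key=aicc)
    return out


def flag_uninformative(fits: Sequence[FitResult],
                       supported: Sequence[FitResult]) -> dict[str, list[str]]:
    """Terms whose inclusion in a supported model costs AICc.

    A term t in supported model M is flagged when the candidate identical
    to M minus t has lower AICc — the extra parameter buys nothing.
    Returns {flagged term: [model labels where it is uninformative]}.
    """
    by_terms = {frozenset(f.terms): f for f in fits}
    flags: dict[str, list[str]] = {}
    for m in supported:
        label = " + ".join(m.terms) if m.terms else "(intercept)"
        for t in m.terms:
            reduced = frozenset(s for s in m.terms if s != t)
            # dropping a main effect under marginality may orphan an
            # interaction; such a reduced model is not in the candidate set
            nested = by_terms.get(reduced)
            if nested is not None and aicc(m) > aicc(nested):
                flags.setdefault(t, []).append(label)
    return flags


def model_average(supported: Sequence[FitResult],
                  z: float = 1.959963984540054) -> pd.DataFrame:
    """Full (zero-substitution) model averaging over the supported set.

    Weights are renormalized within the set.  The unconditional standard
    error combines within-model variance and between-model spread:
    se_j = sum_i w_i * sqrt(se_ij^2 + (b_ij - bbar_j)^2), with b_ij = 0
    (se 0) where term j is absent from model i.
    """
    if not supported:
        raise ValueError("supported set is empty; nothing to average")
    a = np.array([aicc(f) for f in supported])
    rel = np.exp(-0.5 * (a - a.min()))
    w = rel / rel.sum()
    coefs: list[str] = []
    for f in supported:
        for c in f.estimates:
            if c not in coefs:
                coefs.append(c)
    rows = []
    for c in coefs:
        b = np.array([f.estimates.get(c, 0.0) for f in supported])
        se = np.array([f.std_errors.get(c, 0.0) for f in supported])
        est = float(np.sum(w * b))
        use = float(np.sum(w * np.sqrt(se ** 2 + (b - est) ** 2)))
        rows.append({"coefficient": c, "estimate": est, "se": use,
                     "lo95": est - z * use, "hi95": est + z * use})
    return pd.DataFrame(rows)


def group_t_test(values: Sequence[float], groups: Sequence[str]
                 ) -> tuple[float, int, float]:
    """Pooled-variance two-sample t test; groups in sorted label order.

    Returns (t, df, p) with df = n1 + n2 - 2; t compares mean(first label)
    - mean(second label).
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    labels = sorted(set(g))
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {labels}")
    x1, x2 = v[g == labels[0]], v[g == labels[1]]
    if len(x1) < 2 or len(x2) < 2:
        raise ValueError("each group needs n >= 2")
    if np.var(x1, ddof=1) == 0 and len(x1) == 2:
        raise ValueError("zero-variance group with n = 2")
    if np.var(x2, ddof=1) == 0 and len(x2) == 2:
        raise ValueError("zero-variance group with n = 2")
    n1, n2 = len(x1), len(x2)
    sp2 = (((n1 - 1) * np.var(x1, ddof=1) + (n2 - 1) * np.var(x2, ddof=1))
           / (n1 + n2 - 2))
    se = math.sqrt(sp2 * (1 / n1 + 1 / n2))
    t = float((x1.mean() - x2.mean()) / se)
    df = n1 + n2 - 2
    p = float(2 * stats.t.sf(abs(t), df))
    return t, df, p


def run_response_analysis(frame: pd.DataFrame, response: str,
                          global_terms: Sequence[str] | None = None,
                          family: str | None = None,
                          group: str = "tag_id") -> RankedModelSet:
    """Fit all subsets for one response and assemble the ranked set."""
    if global_terms is None:
        global_terms = GLOBAL_TERMS[response]
    if family is None:
        family = {"departure_doy": "gaussian_lm",
                  "minutes_after_sunset": "gamma_log_glm",
                  "speed_kmh": "gaussian_lm",
                  "km_per_day": "gaussian_lmm"}[response]
    used = [c for c in dict.fromkeys(
        [response, group] + [p for t in global_terms for p in t.split(":")])
        if c in frame.columns]
    if frame[used].isna().any().any():
        raise ValueError(f"missing values in columns used for {response}")
    fitter = {"gaussian_lm": fit_linear, "gamma_log_glm": fit_gamma_log}.get(family)
    fits = []
    for terms in all_subsets(global_terms):
        if family == "gaussian_lmm":
            fits.append(fit_lmm(frame, response, terms, group=group))
        else:
            fits.append(fitter(frame, response, terms))
    table = rank_models(fits)
    supp = supported_set(fits, table)
    flags = flag_uninformative(fits, supp) if supp else {}
    averaged = model_average(supp) if supp else None
    inter_aicc = aicc(next(f for f in fits if not f.terms))
    return RankedModelSet(table=table, fits=fits, supported=supp,
                          intercept_only_aicc=inter_aicc, averaged=averaged,
                          uninformative=flags)
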