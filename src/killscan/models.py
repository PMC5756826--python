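"""Predictive layer: random-intercept logistic models over cluster features.

Clusters from the same animal are not independent — individual bears have
idiosyncratic residency behavior — so predation presence and carcass size
are modeled with a logistic GLMM carrying a per-animal random intercept:

    logit P(y_ig = 1) = x_ig' beta + b_g,    b_g ~ N(0, sigma^2).

The marginal likelihood integrates the random intercept by adaptive
Gauss–Hermite quadrature (default 15 nodes, centered and scaled at each
group's conditional mode; the 1-node case degenerates to the Laplace
approximation).  Model selection is all-subsets by AICc with Akaike
weights; among the top three, the field-relevant pick is the model with the
highest sensitivity at the 0.5 probability threshold.  ROC/AUC uses the
Mann–Whitney construction with the Hanley–McNeil nonparametric variance.

Coefficients from the original Alberta field deployment are packaged
(:mod:`killscan.published`) so new clusters can be scored without refitting.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps
from scipy.special import expit, logsumexp

from . import published

__all__ = [
    "SeparationError",
    "FittedModel",
    "ClassificationReport",
    "build_design",
    "fit_random_intercept_logit",
    "aicc",
    "all_subsets_rank",
    "classification_report",
    "score_published",
    "predict_population",
]

CONTINUOUS_TERMS = {
    "log10_n_gps_obs": lambda df: np.log10(df["n_gps_obs"].astype(float)),
    "log10_duration": lambda df: np.log10(df["duration"].astype(float)),
    "spread": lambda df: df["spread"].astype(float),
    "log10_spread": lambda df: np.log10(df["spread"].astype(float)),
    "occupation": lambda df: df["occupation"].astype(float),
    "return_events": lambda df: df["return_events"].astype(float),
}

# categorical factors with their reference level and dummy levels
FACTORS = {
    "sex": ("female", ["male"]),
    "age_class": ("adult", ["subadult"]),
    "season": ("fall", ["spring", "summer"]),
    "stod": ("day", ["night", "twilight"]),
}


class SeparationError(RuntimeError):
    """Complete (or quasi-complete) separation: a term perfectly predicts
    the outcome and its coefficient diverges."""

    def __init__(self, term: str):
        self.term = term
        super().__init__(f"complete separation detected on term {term!r}")


def _factor_columns(df: pd.DataFrame, name: str) -> tuple[np.ndarray, list[str]]:
    ref, levels = FACTORS[name]
    vals = df[name].astype(str)
    cols = [(vals == lv).to_numpy(dtype=float) for lv in levels]
    return np.column_stack(cols), [f"{name}_{lv}" for lv in levels]


def build_design(df: pd.DataFrame, terms: list[str]) -> tuple[np.ndarray, list[str]]:
    """Design matrix (with intercept) for a term list.

    Terms are continuous names (``log10_n_gps_obs`` ...), factor names
    (``sex``, ``age_class``, ``season``, ``stod``; dummy-coded against their
    reference levels) or interactions ``age_class:season`` /
    ``age_class:sex`` (products of the dummy columns).
    """
    cols: list[np.ndarray] = [np.ones(len(df))]
    names: list[str] = ["intercept"]
    for term in terms:
        if term in CONTINUOUS_TERMS:
            cols.append(np.asarray(CONTINUOUS_TERMS[term](df), dtype=float))
            names.append(term)
        elif term in FACTORS:
            block, nm = _factor_columns(df, term)
            cols.extend(block.T)
            names.extend(nm)
        elif ":" in term:
            a, b = term.split(":")
            ba, na = _factor_columns(df, a)
            bb, nb = _factor_columns(df, b)
            for i, ni in enumerate(na):
                for j, nj in enumerate(nb):
                    cols.append(ba[:, i] * bb[:, j])
                    names.append(f"{ni}:{nj}")
        else:
            raise KeyError(f"unknown model term {term!r}")
    return np.column_stack(cols), names


@dataclass
class FittedModel:
    terms: list[str]
    coef: dict[str, float]
    se: dict[str, float]
    sigma2: float
    ll: float
    k: int  # fixed coefficients (incl. intercept) + 1 for the variance
    n: int
    aicc: float
    converged: bool
    delta_aicc: float | None = None
    weight: float | None = None
    sensitivity_at_half: float | None = None
    preferred: bool = False


def aicc(ll: float, k: int, n: int) -> float:
    """Small-sample corrected Akaike criterion:
    AICc = -2 LL + 2k + 2k(k+1)/(n - k - 1)."""
    if n <= k + 1:
        raise ValueError("AICc requires n > k + 1")
    return -2.0 * ll + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


# ---------------------------------------------------------------------------
# marginal likelihood machinery

class _GroupedData:
    """Rows sorted by group with reduceat boundaries for fast per-group sums."""

    def __init__(self, X: np.ndarray, y: np.ndarray, groups: np.ndarray):
        order = np.argsort(groups, kind="stable")
        self.X = X[order]
        self.y = y[order].astype(float)
        g = np.asarray(groups)[order]
        _, starts = np.unique(g, return_index=True)
        self.starts = np.sort(starts)
        self.n_groups = len(self.starts)
        self.group_idx = np.repeat(
            np.arange(self.n_groups),
            np.diff(np.append(self.starts, len(g))),
        )

    def group_sum(self, v: np.ndarray) -> np.ndarray:
        return np.add.reduceat(v, self.starts)


def _bernoulli_ll_terms(eta: np.ndarray, y: np.ndarray) -> np.ndarray:
    # y*eta - log(1 + e^eta), numerically stable
    return y * eta - np.logaddexp(0.0, eta)


def _marginal_ll(beta: np.ndarray, sigma: float, gd: _GroupedData,
                 z: np.ndarray, w: np.ndarray) -> float:
    """Marginal log-likelihood with the random intercept integrated out by
    adaptive Gauss–Hermite quadrature (mode + curvature per group)."""
    eta0 = gd.X @ beta
    if sigma < 1e-8:
        return float(_bernoulli_ll_terms(eta0, gd.y).sum())
    s2 = sigma * sigma
    b = np.zeros(gd.n_groups)
    # Newton iterations for the conditional modes (concave in b)
    for _ in range(50):
        p = expit(eta0 + b[gd.group_idx])
        grad = gd.group_sum(gd.y - p) - b / s2
        hess = -gd.group_sum(p * (1.0 - p)) - 1.0 / s2
        step = grad / hess
        b -= step
        if np.max(np.abs(step)) < 1e-9:
            break
    p = expit(eta0 + b[gd.group_idx])
    neg_h2 = gd.group_sum(p * (1.0 - p)) + 1.0 / s2
    tau = 1.0 / np.sqrt(neg_h2)
    # h(b) = sum_i ll_i(b) - b^2/(2 s2) - 0.5 log(2 pi s2)
    # integral ~= sqrt(2) tau sum_k w_k exp(z_k^2) exp(h(b_hat + sqrt(2) tau z_k))
    log_terms = np.empty((len(z), gd.n_groups))
    for k in range(len(z)):
        bk = b + math.sqrt(2.0) * tau * z[k]
        h = (
            gd.group_sum(_bernoulli_ll_terms(eta0 + bk[gd.group_idx], gd.y))
            - bk * bk / (2.0 * s2)
        )
        log_terms[k] = h + z[k] * z[k] + math.log(w[k])
    ll_groups = (
        logsumexp(log_terms, axis=0)
        + 0.5 * math.log(2.0)
        + np.log(tau)
        - 0.5 * math.log(2.0 * math.pi * s2)
    )
    return float(ll_groups.sum())


def _plain_logit_start(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    beta = np.zeros(X.shape[1])
    for _ in range(25):
        eta = X @ beta
        p = expit(eta)
        W = p * (1.0 - p) + 1e-10
        try:
            delta = np.linalg.solve(X.T @ (W[:, None] * X), X.T @ (y - p))
        except np.linalg.LinAlgError:
            break
        beta += delta
        if np.max(np.abs(delta)) < 1e-10 or np.max(np.abs(beta)) > 50:
            break
    return beta


def fit_random_intercept_logit(
    data: pd.DataFrame,
    outcome: str,
    terms: list[str],
    group: str = "animal_id",
    n_quad: int = 15,
) -> FittedModel:
    """Maximum-likelihood fit of the random-intercept logistic model.

    *outcome* must be a binary column; *group* identifies the animal.  With
    a single group (or an estimated variance of zero) the fit degenerates to
    a plain logistic regression with sigma^2 = 0.  Complete separation
    raises :class:`SeparationError` naming the offending term.
    """
    y = np.asarray(data[outcome], dtype=float)
    uniq = np.unique(y)
    if not np.isin(uniq, [0.0, 1.0]).all():
        raise ValueError("outcome must be binary 0/1")
    if len(uniq) < 2:
        raise ValueError("outcome has no variation")
    X, names = build_design(data, terms)
    if not np.isfinite(X).all():
        raise ValueError("missing or non-finite values in model terms")
    groups = np.asarray(data[group])
    single_group = len(np.unique(groups)) < 2
    gd = _GroupedData(X, y, groups)
    z, w = np.polynomial.hermite.hermgauss(max(n_quad, 1))

    beta0 = _plain_logit_start(X, y)
    p_fixed = X.shape[1]

    if single_group:
        sigma_hat = 0.0
        res = optimize.minimize(
            lambda b: -_marginal_ll(b, 0.0, gd, z, w), beta0, method="BFGS",
            options={"maxiter": 500},
        )
        beta_hat = res.x
        ll = -res.fun
        converged = bool(res.success)
        free = beta_hat
        nll = lambda v: -_marginal_ll(v, 0.0, gd, z, w)  # noqa: E731
    else:
        def nll_full(params):
            return -_marginal_ll(params[:-1], abs(params[-1]), gd, z, w)

        x0 = np.append(beta0, 0.5)
        res = optimize.minimize(nll_full, x0, method="BFGS", options={"maxiter": 800})
        beta_hat = res.x[:-1]
        sigma_hat = abs(res.x[-1])
        ll = -res.fun
        converged = bool(res.success)
        free = res.x
        nll = nll_full

    if np.max(np.abs(beta_hat)) > 30:
        worst = names[int(np.argmax(np.abs(beta_hat)))]
        raise SeparationError(worst)

    # Wald SEs from a central-difference Hessian of the negative LL
    se = _wald_se(nll, free, p_fixed)

    k = p_fixed + 1  # + random-intercept variance
    n = len(y)
    return FittedModel(
        terms=list(terms),
        coef=dict(zip(names, map(float, beta_hat))),
        se=dict(zip(names, map(float, se))),
        sigma2=float(sigma_hat**2),
        ll=float(ll),
        k=k,
        n=n,
        aicc=aicc(float(ll), k, n),
        converged=converged,
    )


def _wald_se(nll, x: np.ndarray, p_fixed: int) -> np.ndarray:
    n_par = len(x)
    h = np.maximum(1e-4, 1e-4 * np.abs(x))
    H = np.zeros((n_par, n_par))
    f0 = nll(x)
    fp = np.empty(n_par)
    fm = np.empty(n_par)
    for i in range(n_par):
        e = np.zeros(n_par)
        e[i] = h[i]
        fp[i] = nll(x + e)
        fm[i] = nll(x - e)
        H[i, i] = (fp[i] - 2 * f0 + fm[i]) / h[i] ** 2
    for i in range(n_par):
        for j in range(i + 1, n_par):
            ei = np.zeros(n_par)
            ej = np.zeros(n_par)
            ei[i] = h[i]
            ej[j] = h[j]
            fpp = nll(x + ei + ej)
            fmm = nll(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fp[i] - fp[j] + 2 * f0 - fm[i] - fm[j] + fmm) / (
                2 * h[i] * h[j]
            )
    try:
        cov = np.linalg.inv(H)
        d = np.diag(cov)[:p_fixed]
        se = np.sqrt(np.where(d > 0, d, np.nan))
    except np.linalg.LinAlgError:
        se = np.full(p_fixed, np.nan)
    return se


def predict_population(model: FittedModel, data: pd.DataFrame) -> np.ndarray:
    """Population-level probabilities (random intercept at 0)."""
    X, names = build_design(data, model.terms)
    beta = np.array([model.coef[nm] for nm in names])
    return expit(X @ beta)


def _valid_subsets(candidates: list[str]) -> list[list[str]]:
    subsets = []
    for r in range(len(candidates) + 1):
        for combo in itertools.combinations(candidates, r):
            ok = True
            for term in combo:
                if ":" in term:
                    a, b = term.split(":")
                    if a not in combo or b not in combo:
                        ok = False
                        break
            if ok:
                subsets.append(list(combo))
    return subsets


def all_subsets_rank(
    data: pd.DataFrame,
    candidates: list[str],
    outcome: str,
    group: str = "animal_id",
    n_quad: int = 15,
    positive_label: int = 1,
) -> list[FittedModel]:
    """Fit every admissible term subset, rank by AICc, attach Akaike weights.

    Interactions enter only alongside both main effects.  Among the top
    three models, the one with the highest sensitivity at the 0.5 threshold
    is flagged ``preferred`` — the selection rule that matters in the field,
    where missing a predation site costs more than an extra visit.  Fit
    failures are recorded and skipped.
    """
    fitted: list[FittedModel] = []
    for terms in _valid_subsets(candidates):
        try:
            fitted.append(
                fit_random_intercept_logit(data, outcome, terms, group=group, n_quad=n_quad)
            )
        except (SeparationError, ValueError, np.linalg.LinAlgError):
            continue
    if not fitted:
        raise RuntimeError("no candidate model could be fitted")
    fitted.sort(key=lambda m: m.aicc)
    best = fitted[0].aicc
    rel = np.array([math.exp(-0.5 * (m.aicc - best)) for m in fitted])
    weights = rel / rel.sum()
    y = np.asarray(data[outcome], dtype=float)
    for m, wgt in zip(fitted, weights):
        m.delta_aicc = m.aicc - best
        m.weight = float(wgt)
    for m in fitted[:3]:
        scores = predict_population(m, data)
        pred = scores >= 0.5
        pos = y == positive_label
        m.sensitivity_at_half = float(np.sum(pred & pos) / max(np.sum(pos), 1))
    top3 = fitted[:3]
    preferred = max(top3, key=lambda m: (m.sensitivity_at_half, -m.aicc))
    preferred.preferred = True
    return fitted


@dataclass
class ClassificationReport:
    thresholds: list[float]
    sensitivity: list[float]
    specificity: list[float]
    accuracy: list[float]
    auc: float
    auc_se: float
    auc_ci: tuple[float, float]
    w_statistic: float
    p_value: float


def classification_report(
    scores,
    labels,
    thresholds: tuple[float, ...] = (0.5, 0.6, 0.7, 0.8, 0.9),
) -> ClassificationReport:
    """Threshold sweep plus nonparametric ROC summary.

    sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), accuracy = (TP+TN)/n
    at each threshold (predict positive when score >= threshold).  AUC is
    the Mann–Whitney statistic W/(n1*n0) with ties counted 1/2; its SE and
    normal-theory 95% CI use the Hanley–McNeil approximation, and the test
    against AUC = 0.5 is the two-sided Mann–Whitney test.
    """
    s = np.asarray(scores, dtype=float)
    yl = np.asarray(labels, dtype=float)
    if set(np.unique(yl)) - {0.0, 1.0}:
        raise ValueError("labels must be binary 0/1")
    n1 = int((yl == 1).sum())
    n0 = int((yl == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    sens, spec, acc = [], [], []
    for thr in thresholds:
        pred = s >= thr
        tp = int(np.sum(pred & (yl == 1)))
        tn = int(np.sum(~pred & (yl == 0)))
        sens.append(tp / n1)
        spec.append(tn / n0)
        acc.append((tp + tn) / (n1 + n0))
    ranks = sps.rankdata(s)
    w = float(ranks[yl == 1].sum() - n1 * (n1 + 1) / 2.0)
    auc = w / (n1 * n0)
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc * auc / (1.0 + auc)
    var = (
        auc * (1 - auc) + (n1 - 1) * (q1 - auc * auc) + (n0 - 1) * (q2 - auc * auc)
    ) / (n1 * n0)
    se = math.sqrt(max(var, 0.0))
    ci = (max(0.0, auc - 1.959964 * se), min(1.0, auc + 1.959964 * se))
    if np.ptp(s) == 0:
        p = 1.0
    else:
        p = float(sps.mannwhitneyu(s[yl == 1], s[yl == 0], alternative="two-sided").pvalue)
    return ClassificationReport(
        thresholds=list(thresholds),
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        auc=float(auc),
        auc_se=se,
        auc_ci=ci,
        w_statistic=w,
        p_value=p,
    )


_PUBLISHED = {
    "predation": published.PREDATION_MODEL,
    "carcass": published.CARCASS_MODEL,
}


def _published_lp(row, coefs: dict[str, float]) -> float:
    lp = coefs["intercept"]
    get = row.get if hasattr(row, "get") else lambda k, d=None: getattr(row, k, d)
    for name, beta in coefs.items():
        if name == "intercept":
            continue
        if name.startswith("log10_"):
            base = name[len("log10_"):]
            val = get(base)
            if val is None or (isinstance(val, float) and math.isnan(val)):
                raise KeyError(f"missing feature {base!r} for published model")
            lp += beta * math.log10(float(val))
        elif "_" in name:
            factor, level = name.split("_", 1)
            val = get(factor)
            if val is None:
                raise KeyError(f"missing feature {factor!r} for published model")
            lp += beta * float(str(val) == level)
    return lp


def score_published(features, model: str = "predation"):
    """Probability from the packaged field-study coefficients.

    *features* is a mapping / ClusterFeatures / DataFrame with the model's
    inputs (predation: n_gps_obs, duration, sex, stod; carcass: season,
    stod, n_gps_obs, spread).  The random intercept is set to zero
    (population-level prediction); the positive class of the carcass model
    is a small/medium carcass.
    """
    if model not in _PUBLISHED:
        raise ValueError(f"unknown published model {model!r}")
    coefs = _PUBLISHED[model]
    if isinstance(features, pd.DataFrame):
        return np.array(
            [expit(_published_lp(row, coefs)) for row in features.to_dict("records")]
        )
    if hasattr(features, "__dataclass_fields__"):
        features = vars(features)
    return float(expit(_published_lp(features, coefs)))
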