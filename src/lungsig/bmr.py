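"""Bayesian multivariate logistic regression with covariate selection (BMR).

The model is logistic regression on internally z-scored covariates with
independent Gaussian priors N(0, prior_sd^2) on the standardised
coefficients (a weak N(0, 10^2) prior on the intercept).  Covariates are
chosen by greedy forward search on the Laplace-approximated log marginal
likelihood (model evidence): at each step the covariate whose addition
maximises the evidence is added, and the search stops when no addition
improves the selection objective or `max_covariates` is reached.

The selection objective is the log evidence plus a subset-size prior —
independent inclusion probability kappa per covariate (default 1/p).
This is the standard Bayesian multiplicity correction: with many
candidate covariates the prior odds of including any one of them shrink
accordingly, which keeps the false-selection rate flat in p.  The
evidence itself (what the quadrature oracle checks) is untouched.

Per selected covariate the result reports Beta (posterior mode on the
standardised scale), a posterior sd from the inverse-Hessian diagonal,
a two-sided normal-tail p-value for Beta, and the raw-scale signature
weight beta/sd(x).  An elastic-net comparator with cross-validated
penalty is provided for the overfitting contrast.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, ndtr
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

INTERCEPT_PRIOR_SD = 10.0


# ---------------------------------------------------------------------------
# Laplace machinery


def _log_lik(eta: np.ndarray, y: np.ndarray) -> float:
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _map_fit(
    X1: np.ndarray, y: np.ndarray, prior_prec: np.ndarray, tol: float = 1e-9,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Posterior mode by damped Newton; returns (w, H, log_joint_at_mode).

    X1 carries the intercept column first; prior_prec is the per-
    coefficient prior precision.  H is the negative Hessian of the log
    joint at the mode.
    """
    n, d = X1.shape
    w = np.zeros(d)

    def log_joint(w):
        return _log_lik(X1 @ w, y) - 0.5 * float(w @ (prior_prec * w))

    lj = log_joint(w)
    for _ in range(max_iter):
        eta = X1 @ w
        p = expit(eta)
        g = X1.T @ (y - p) - prior_prec * w
        if np.max(np.abs(g)) < tol:
            break
        s = np.clip(p * (1 - p), 1e-12, None)
        H = (X1 * s[:, None]).T @ X1 + np.diag(prior_prec)
        step = np.linalg.solve(H, g)
        t = 1.0
        for _ls in range(30):
            lj_new = log_joint(w + t * step)
            if lj_new >= lj:
                break
            t /= 2
        w = w + t * step
        lj = lj_new
    eta = X1 @ w
    s = np.clip(expit(eta) * (1 - expit(eta)), 1e-12, None)
    H = (X1 * s[:, None]).T @ X1 + np.diag(prior_prec)
    return w, H, lj


def laplace_log_evidence(
    X: np.ndarray, y: np.ndarray, prior_sd: float = 2.0,
    intercept_prior_sd: float = INTERCEPT_PRIOR_SD,
    correction: bool = True,
) -> float:
    """Laplace approximation to log p(y | model) for a fixed design.

    X holds the (already standardised) covariate columns, without an
    intercept column; the intercept is always included.

    With ``correction`` (default) the standard fourth-order moment
    correction is added: the log-joint is expanded past second order
    around the mode, and the Gaussian expectation of the cubic and
    quartic remainder contributes ``log(1 + C)`` with

        C = 1/8 <T4, S x S> + 1/8 A + 1/12 B,

    where S is the inverse Hessian, T3/T4 are the third/fourth
    derivative tensors of the log likelihood (the Gaussian prior's
    vanish), A and B the two Isserlis contractions of T3 with itself.
    The correction is O(1/n) and matters only for small fits; above 512
    rows it is far below 0.01 nats while its pairwise computation would
    dominate the cost, so it is skipped there.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.size == 0:
        X = np.empty((len(y), 0))
    y = np.asarray(y, dtype=float)
    X1 = np.column_stack([np.ones(len(y)), X])
    sds = np.array([intercept_prior_sd] + [prior_sd] * X.shape[1])
    prec = 1.0 / sds**2
    w, H, _ = _map_fit(X1, y, prec)
    ll = _log_lik(X1 @ w, y)
    log_prior = float(
        -0.5 * np.sum(np.log(2 * np.pi * sds**2)) - 0.5 * w @ (prec * w)
    )
    sign, logdet = np.linalg.slogdet(H)
    if sign <= 0:
        raise np.linalg.LinAlgError("Hessian not positive definite")
    d = X1.shape[1]
    log_z = ll + log_prior + 0.5 * d * np.log(2 * np.pi) - 0.5 * logdet

    n = len(y)
    if correction and n <= 512:
        p = expit(X1 @ w)
        v = p * (1 - p)
        g3 = -v * (1 - 2 * p)            # third derivative of per-row log lik
        g4 = -v * (1 - 6 * p + 6 * p**2)  # fourth derivative
        S = np.linalg.inv(H)
        Q = X1 @ S @ X1.T                 # q_nm = x_n' S x_m
        dq = np.diag(Q)
        c4 = float(np.sum(g4 * dq**2)) / 8.0
        gd = g3 * dq
        a = float(gd @ Q @ gd)
        b = float(g3 @ (Q**3) @ g3)
        c = c4 + a / 8.0 + b / 12.0
        log_z += float(np.log1p(c)) if c > -0.9 else c
    return log_z


# ---------------------------------------------------------------------------
# results and signatures


@dataclass
class BMRResult:
    """Fit summary: selection order, standardised Betas, p-values, raw weights."""

    selected: list[str]
    beta: dict[str, float]
    beta_sd: dict[str, float]
    p_value: dict[str, float]
    weight: dict[str, float]
    intercept: float               # raw scale
    evidence_path: list[tuple[int, float]]
    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)


@dataclass
class Signature:
    """Linear risk model over raw covariate values: risk = b0 + sum w_j x_j."""

    covariates: list[str]
    weights: list[float]
    intercept: float
    provenance: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, default=str, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "Signature":
        return cls(**json.loads(Path(path).read_text()))


def _standardise(X: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series, pd.Series, list[str]]:
    means = X.mean()
    sds = X.std(ddof=0)
    constant = sds[sds == 0].index.tolist()
    if constant:
        logger.warning("excluding %d constant columns: %s", len(constant), constant[:5])
    keep = [c for c in X.columns if c not in constant]
    Z = (X[keep] - means[keep]) / sds[keep]
    return Z, means, sds, constant


def _posterior_summary(
    Z: pd.DataFrame, y: np.ndarray, selected: list[str], prior_sd: float
) -> tuple[np.ndarray, np.ndarray]:
    X1 = np.column_stack([np.ones(len(y)), Z[selected].to_numpy()]) if selected else \
        np.ones((len(y), 1))
    prec = np.array([1 / INTERCEPT_PRIOR_SD**2] + [1 / prior_sd**2] * len(selected))
    w, H, _ = _map_fit(X1, y, prec)
    cov = np.linalg.inv(H)
    return w, np.sqrt(np.diag(cov))


def _build_result(
    Z: pd.DataFrame, y: np.ndarray, selected: list[str], prior_sd: float,
    path: list[tuple[int, float]], means: pd.Series, sds: pd.Series, meta: dict,
) -> BMRResult:
    w, se = _posterior_summary(Z, y, selected, prior_sd)
    beta = {c: float(w[i + 1]) for i, c in enumerate(selected)}
    beta_sd = {c: float(se[i + 1]) for i, c in enumerate(selected)}
    pval = {
        c: max(float(2 * (1 - ndtr(abs(beta[c]) / beta_sd[c]))), 1e-300)
        for c in selected
    }
    weight = {c: beta[c] / float(sds[c]) for c in selected}
    intercept = float(w[0]) - sum(beta[c] * float(means[c]) / float(sds[c]) for c in selected)
    if selected and max(abs(b) for b in beta.values()) > 5 * prior_sd:
        meta = {**meta, "separation_suspected": True}
    return BMRResult(
        selected=list(selected), beta=beta, beta_sd=beta_sd, p_value=pval,
        weight=weight, intercept=intercept, evidence_path=path,
        means={c: float(means[c]) for c in selected},
        sds={c: float(sds[c]) for c in selected}, meta=meta,
    )


def fit_bmr(
    X: pd.DataFrame,
    y,
    prior_sd: float = 2.0,
    max_covariates: int = 12,
    inclusion_prior: float | None = None,
) -> BMRResult:
    """Greedy forward evidence-based selection (see module docstring).

    `inclusion_prior` is the prior probability that any given covariate
    enters the model; the default 1/p gives an expected prior model size
    of one and the standard multiplicity correction.
    """
    if len(X) < 20:
        raise ValueError(f"need >= 20 rows, got {len(X)}")
    if X.isna().any().any():
        raise ValueError("missing values in X")
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("y must be binary 0/1")

    Z, means, sds, constant = _standardise(X)
    p = Z.shape[1]
    meta: dict = {"n": len(y), "p": p, "prior_sd": prior_sd, "excluded_constant": constant}
    kappa = inclusion_prior if inclusion_prior is not None else min(1.0 / max(p, 1), 0.5)
    kappa = min(max(kappa, 1e-12), 0.5)
    log_odds_in = float(np.log(kappa) - np.log1p(-kappa))

    def score(sel_cols: list[str]) -> float:
        ev = laplace_log_evidence(Z[sel_cols].to_numpy(), y, prior_sd)
        return ev + len(sel_cols) * log_odds_in

    selected: list[str] = []
    current = score(selected)
    path = [(0, current)]
    remaining = sorted(Z.columns)
    step = 0
    while remaining and len(selected) < max_covariates:
        best_name, best_score = None, -np.inf
        for name in remaining:  # lexicographic order => deterministic tie-break
            s = score(selected + [name])
            if s > best_score + 1e-12:
                best_name, best_score = name, s
        if best_name is None or best_score <= current:
            break
        selected.append(best_name)
        remaining.remove(best_name)
        current = best_score
        step += 1
        path.append((step, current))

    return _build_result(Z, y, selected, prior_sd, path, means, sds, meta)


def fit_bayes_logistic(
    X: pd.DataFrame, y, covariates: list[str] | None = None, prior_sd: float = 2.0
) -> BMRResult:
    """Bayesian logistic fit on a fixed covariate set (no selection).

    Used to refit a stability-selected covariate list on the full cohort.
    """
    y = np.asarray(y, dtype=float)
    cols = list(covariates) if covariates is not None else list(X.columns)
    missing = [c for c in cols if c not in X.columns]
    if missing:
        raise ValueError(f"covariates not in X: {missing}")
    Z, means, sds, constant = _standardise(X[cols])
    cols = [c for c in cols if c not in constant]
    ev = laplace_log_evidence(Z[cols].to_numpy(), y, prior_sd)
    meta = {"n": len(y), "p": len(cols), "prior_sd": prior_sd,
            "excluded_constant": constant, "fixed_covariates": True}
    return _build_result(Z, y, cols, prior_sd, [(0, ev)], means, sds, meta)


def to_signature(result: BMRResult, provenance: dict | None = None) -> Signature:
    """Raw-scale linear signature from a fit result (weights = beta / sd)."""
    return Signature(
        covariates=list(result.selected),
        weights=[result.weight[c] for c in result.selected],
        intercept=result.intercept,
        provenance={**(provenance or {}), **result.meta},
    )


def predict_risk(signature: Signature, X: pd.DataFrame) -> pd.Series:
    """Linear risk score per patient row (invariant to row order)."""
    missing = [c for c in signature.covariates if c not in X.columns]
    if missing:
        raise ValueError(f"missing covariate columns: {missing}")
    score = pd.Series(signature.intercept, index=X.index, dtype=float)
    for c, w in zip(signature.covariates, signature.weights):
        score = score + w * X[c]
    score.name = "risk"
    return score


# ---------------------------------------------------------------------------
# elastic-net comparator


def fit_elastic_net(
    X: pd.DataFrame,
    y,
    l1_ratio: float = 0.5,
    cv_folds: int = 5,
    seed: int = 0,
    Cs=10,
    max_iter: int = 10000,
) -> tuple[Signature, pd.DataFrame]:
    """Penalised logistic comparator: elastic net, penalty by CV deviance.

    Covariates are z-scored as in `fit_bmr`; the returned signature is on
    the raw scale.  Also returns the cross-validation path (C vs mean
    held-out log-loss).
    """
    y = np.asarray(y, dtype=float)
    counts = np.bincount(y.astype(int), minlength=2)
    if counts.min() < cv_folds:
        raise ValueError(
            f"minority class count {counts.min()} < cv_folds {cv_folds}: "
            "folds would be single-class"
        )
    Z, means, sds, constant = _standardise(X)
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    model = LogisticRegressionCV(
        Cs=Cs, cv=cv, penalty="elasticnet", solver="saga",
        l1_ratios=[l1_ratio], scoring="neg_log_loss", max_iter=max_iter,
        random_state=seed, n_jobs=1,
    )
    model.fit(Z.to_numpy(), y)
    coef = model.coef_[0]
    nz = np.flatnonzero(np.abs(coef) > 1e-10)
    cols = [Z.columns[i] for i in nz]
    weights = [float(coef[i]) / float(sds[Z.columns[i]]) for i in nz]
    intercept = float(model.intercept_[0]) - sum(
        float(coef[i]) * float(means[Z.columns[i]]) / float(sds[Z.columns[i]]) for i in nz
    )
    sig = Signature(
        covariates=cols, weights=weights, intercept=intercept,
        provenance={"method": "elastic_net", "l1_ratio": l1_ratio,
                    "C": float(model.C_[0]), "excluded_constant": constant},
    )
    scores = model.scores_[1.0].mean(axis=0)[:, 0]  # folds x Cs x l1_ratios
    path = pd.DataFrame({"C": model.Cs_, "mean_neg_log_loss": -scores})
    return sig, path
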