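"""Discrete-time logistic hazard models with patient-clustered inference.

Each observation row contributes a Bernoulli term ("event in the next 24
hours or not") to a plain logistic likelihood — the discrete-time hazard
formulation.  Coefficients are maximum likelihood via iteratively reweighted
least squares (IRLS); no regularization is applied, so complete separation is
an error rather than a silently penalized fit.

Because one patient contributes many rows, naive variance estimates are
anti-conservative.  The covariance is the cluster-robust sandwich estimator
with patients as clusters: per-row score contributions ``x_i (y_i - p_i)``
are summed within each patient before the outer product, which keeps the
variance valid under arbitrary within-patient dependence.  Covariate
importance is ranked by the absolute Wald z-score ``|beta_j| / se_j``.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .covariates import OUTCOME_LABELS, class_covariates
from .errors import AkiPredictError, SeparationError, SingularDesignError

MAX_ITER = 100
TOL = 1e-8
#: |log-odds| beyond which a diverging coefficient is treated as separation.
SEPARATION_BOUND = 30.0

INTERCEPT = "(intercept)"


@dataclass
class ModelFit:
    """A fitted covariate-class model for one outcome."""

    model_class: str
    outcome: str
    names: list[str]  # intercept first
    beta: np.ndarray
    cov: np.ndarray  # cluster-robust
    n_rows: int
    n_patients: int
    n_events: int
    loglik: float
    n_iter: int
    converged: bool
    metadata: dict = field(default_factory=dict)

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    @property
    def z(self) -> np.ndarray:
        return self.beta / self.se

    def wald_ci(self, level: float = 0.95) -> np.ndarray:
        from scipy.stats import norm

        q = norm.ppf(0.5 + level / 2)
        se = self.se
        return np.column_stack([self.beta - q * se, self.beta + q * se])

    def to_json(self) -> str:
        return json.dumps(
            {
                "model_class": self.model_class,
                "outcome": self.outcome,
                "names": self.names,
                "beta": self.beta.tolist(),
                "cov": self.cov.tolist(),
                "n_rows": self.n_rows,
                "n_patients": self.n_patients,
                "n_events": self.n_events,
                "loglik": self.loglik,
                "n_iter": self.n_iter,
                "converged": self.converged,
                "metadata": self.metadata,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "ModelFit":
        d = json.loads(text)
        d["beta"] = np.asarray(d["beta"])
        d["cov"] = np.asarray(d["cov"])
        return cls(**d)


def _loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # numerically stable Bernoulli log-likelihood: sum y*eta - log(1+e^eta)
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _irls(X: np.ndarray, y: np.ndarray, names: list[str]) -> tuple[np.ndarray, np.ndarray, float, int, bool]:
    """IRLS for logistic regression with step-halving.

    Returns (beta, bread = (X'WX)^-1, loglik, n_iter, converged).  The
    log-likelihood is non-decreasing across accepted iterations.
    """
    n, k = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        # name the columns whose removal restores full rank
        _, r = np.linalg.qr(X)
        bad = [names[j] for j in range(k) if abs(r[j, j]) < 1e-8 * max(1.0, abs(r[0, 0]))]
        raise SingularDesignError(bad or names)
    beta = np.zeros(k)
    eta = X @ beta
    ll = _loglik(y, eta)
    converged = False
    it = 0
    for it in range(1, MAX_ITER + 1):
        p = expit(eta)
        w = p * (1.0 - p)
        w = np.maximum(w, 1e-10)
        XtW = X.T * w
        H = XtW @ X
        g = X.T @ (y - p)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            raise SingularDesignError(names, "weighted design became singular during IRLS")
        # step-halving keeps the log-likelihood monotone
        scale = 1.0
        for _ in range(30):
            beta_new = beta + scale * step
            ll_new = _loglik(y, X @ beta_new)
            if ll_new >= ll - 1e-12:
                break
            scale /= 2.0
        beta, eta = beta_new, X @ beta_new
        if np.max(np.abs(beta)) > SEPARATION_BOUND:
            j = int(np.argmax(np.abs(beta)))
            raise SeparationError([names[j]])
        rel = abs(ll_new - ll) / (abs(ll) + 1e-12)
        ll = ll_new
        if rel < TOL:
            converged = True
            break
    p = expit(eta)
    w = np.maximum(p * (1.0 - p), 1e-10)
    bread = np.linalg.inv((X.T * w) @ X)
    return beta, bread, ll, it, converged


def cluster_sandwich(
    X: np.ndarray,
    y: np.ndarray,
    beta: np.ndarray,
    bread: np.ndarray,
    clusters: np.ndarray,
    small_sample_correction: bool = True,
) -> np.ndarray:
    """Cluster-robust covariance: bread @ meat @ bread.

    Scores are summed within cluster before the outer product.  The optional
    small-sample factor G/(G-1) matches common econometric practice; with one
    row per cluster and the factor off, the estimator reduces to the ordinary
    heteroskedasticity-robust (HC0) variance.
    """
    resid = y - expit(X @ beta)
    score = X * resid[:, None]
    df = pd.DataFrame(score)
    df["_g"] = clusters
    S = df.groupby("_g", sort=False).sum().to_numpy()
    meat = S.T @ S
    G = S.shape[0]
    V = bread @ meat @ bread
    if small_sample_correction and G > 1:
        V = V * (G / (G - 1))
    return V


def fit_discrete_logit(
    rows: pd.DataFrame,
    model_class: str,
    outcome: str = "aki24",
    cluster_col: str = "patient_id",
    covariates: list[str] | None = None,
    small_sample_correction: bool = True,
) -> ModelFit:
    """Fit one covariate-class model on complete-case observation rows.

    ``outcome`` is one of ``aki24, sustained_aki24, rrt, death`` (or directly
    a label column name).  Rows must already be complete-case for the class;
    missing values raise rather than being imputed.
    """
    label_col = OUTCOME_LABELS.get(outcome, outcome)
    if label_col not in rows.columns:
        raise AkiPredictError(f"unknown outcome {outcome!r}")
    cov_names = list(covariates) if covariates is not None else list(class_covariates(model_class))
    if rows[cov_names].isna().any().any():
        missing = [c for c in cov_names if rows[c].isna().any()]
        raise AkiPredictError(
            f"rows contain missing values for {missing}; run complete_case_filter first"
        )
    y = rows[label_col].to_numpy(dtype=float)
    if y.min() == y.max():
        raise AkiPredictError("need at least one event and one non-event row")
    X = np.column_stack([np.ones(len(rows))] + [rows[c].to_numpy(dtype=float) for c in cov_names])
    names = [INTERCEPT] + cov_names
    beta, bread, ll, it, converged = _irls(X, y, names)
    clusters = rows[cluster_col].to_numpy()
    V = cluster_sandwich(X, y, beta, bread, clusters, small_sample_correction)
    return ModelFit(
        model_class=model_class,
        outcome=outcome,
        names=names,
        beta=beta,
        cov=V,
        n_rows=len(rows),
        n_patients=int(pd.unique(clusters).size),
        n_events=int(y.sum()),
        loglik=ll,
        n_iter=it,
        converged=converged,
    )


def predict_risk(fit: ModelFit, rows: pd.DataFrame | pd.Series | dict) -> np.ndarray | float:
    """Event probability per row: inverse-logit of the linear predictor.

    Raises on a missing required covariate — never silent imputation.
    """
    single = not isinstance(rows, pd.DataFrame)
    df = pd.DataFrame([rows]) if single else rows
    cov_names = fit.names[1:]
    missing_cols = [c for c in cov_names if c not in df.columns]
    if missing_cols:
        raise AkiPredictError(f"rows lack required covariate(s): {missing_cols}")
    block = df[cov_names]
    if block.isna().any().any():
        bad = [c for c in cov_names if block[c].isna().any()]
        raise AkiPredictError(f"missing values in required covariate(s): {bad}")
    eta = fit.beta[0] + block.to_numpy(dtype=float) @ fit.beta[1:]
    p = expit(eta)
    return float(p[0]) if single else p


def rank_covariates(fit: ModelFit) -> list[tuple[str, float]]:
    """Covariates ordered by |Wald z| descending; ties broken alphabetically.

    The intercept is not ranked.
    """
    z = fit.z
    pairs = [(name, abs(float(z[i]))) for i, name in enumerate(fit.names) if name != INTERCEPT]
    return sorted(pairs, key=lambda p: (-p[1], p[0]))


def export_closed_form(fit: ModelFit) -> str:
    """Human-readable linear predictor, e.g. for an EHR rule engine.

    ``logit(p) = b0 + b1*cov1 + ...`` with full-precision coefficients; the
    export round-trips through :func:`parse_closed_form`.
    """
    terms = [repr(float(fit.beta[0]))]
    for name, b in zip(fit.names[1:], fit.beta[1:]):
        b = float(b)
        terms.append(f"{'+' if b >= 0 else '-'} {abs(b)!r}*{name}")
    return "logit(p) = " + " ".join(terms)


def parse_closed_form(text: str) -> tuple[float, dict[str, float]]:
    """Parse an exported closed-form equation back into coefficients."""
    body = text.split("=", 1)[1].strip()
    tokens = re.findall(
        r"([+-]?)\s*([0-9]*\.?[0-9]+(?:[eE][+-]?[0-9]+)?)\s*(?:\*\s*([A-Za-z_]\w*))?",
        body,
    )
    intercept = None
    coefs: dict[str, float] = {}
    for sign, num, name in tokens:
        value = float(num) * (-1.0 if sign == "-" else 1.0)
        if name:
            coefs[name] = value
        elif intercept is None:
            intercept = value
    if intercept is None:
        raise AkiPredictError(f"could not parse closed form: {text!r}")
    return intercept, coefs


def score_closed_form(text: str, rows: pd.DataFrame) -> np.ndarray:
    """Score rows from a parsed closed-form export (round-trip check)."""
    intercept, coefs = parse_closed_form(text)
    eta = np.full(len(rows), intercept)
    for name, b in coefs.items():
        eta += b * rows[name].to_numpy(dtype=float)
    return expit(eta)
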