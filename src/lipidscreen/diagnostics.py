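"""Logistic diagnostic models on marker panels with LOOCV performance.

The model is y = 1 / (1 + exp(-(b0 + b . I))) over the raw-scale
intensities I of a VIP-selected marker panel (coded 0 = control,
1 = case).  Fitting is maximum likelihood by iteratively reweighted
least squares with a tiny ridge penalty that keeps estimates finite
under the quasi-separation typical of pre-selected panels.  Diagnostic
sensitivity and specificity are estimated by leave-one-out
cross-validation at a probability threshold of 0.5.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _st
from scipy.special import expit

__all__ = [
    "LogisticModel",
    "DiagnosticPerformance",
    "predict_prob",
    "fit_logistic",
    "loocv_performance",
]

logger = logging.getLogger(__name__)

MAX_ITER = 100
TOL = 1e-10


@dataclass
class LogisticModel:
    intercept: float
    coef: np.ndarray
    feature_ids: list[str] = field(default_factory=list)
    converged: bool = True
    n_iter: int = 0
    ridge_lambda: float = 1e-8
    separated: bool = False
    se: np.ndarray | None = None          # (1 + n_markers,), intercept first
    z: np.ndarray | None = None
    p: np.ndarray | None = None
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None

    def predict_prob(self, intensities) -> np.ndarray:
        return predict_prob(self, intensities)

    def table(self) -> list[dict]:
        """Coefficient report, intercept row first."""
        names = ["(intercept)"] + list(self.feature_ids)
        beta = np.concatenate([[self.intercept], self.coef])
        rows = []
        for i, name in enumerate(names):
            rows.append(
                {
                    "term": name,
                    "beta": float(beta[i]),
                    "ci_low": float(self.ci_low[i]),
                    "ci_high": float(self.ci_high[i]),
                    "z": float(self.z[i]),
                    "p": float(self.p[i]),
                }
            )
        return rows


@dataclass(frozen=True)
class DiagnosticPerformance:
    tp: int
    fp: int
    tn: int
    fn: int
    threshold: float = 0.5

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else float("nan")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def predict_prob(model: LogisticModel, intensities) -> np.ndarray:
    """P(case) for one intensity vector or a matrix of rows.

    Numerically stable for linear predictors up to |eta| ~ 700.
    """
    x = np.atleast_2d(np.asarray(intensities, dtype=float))
    if x.shape[1] != model.coef.size:
        raise ValueError(
            f"expected {model.coef.size} marker intensities, got {x.shape[1]}")
    eta = model.intercept + x @ model.coef
    out = expit(eta)
    return out[0] if np.asarray(intensities).ndim == 1 else out


def fit_logistic(
    x_markers,
    y,
    ridge_lambda: float = 1e-8,
    feature_ids: list[str] | None = None,
) -> LogisticModel:
    """Maximum-likelihood logistic fit by IRLS with a small ridge penalty.

    The penalty (on slopes and intercept alike) is a numerical
    stabilizer, not regularization; with well-conditioned data the
    estimates match the unpenalized MLE.  Complete separation is
    detected (perfect classification with diverging coefficients) and
    flagged; the fit then returns the last stable iterate.
    """
    x = np.atleast_2d(np.asarray(x_markers, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if x.shape[0] != y.size:
        raise ValueError("x and y size mismatch")
    if len(np.unique(y)) < 2:
        raise ValueError("y must contain both classes")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("y must be coded 0/1")
    n, k = x.shape
    if n <= k + 1:
        warnings.warn(
            f"n={n} samples for {k} markers: fit is weakly determined",
            stacklevel=2)

    design = np.column_stack([np.ones(n), x])
    beta = np.zeros(k + 1)
    converged = False
    it = 0
    for it in range(1, MAX_ITER + 1):
        eta = design @ beta
        mu = expit(np.clip(eta, -700, 700))
        wt = np.clip(mu * (1 - mu), 1e-12, None)
        # IRLS normal equations with ridge
        xtw = design.T * wt
        hess = xtw @ design + ridge_lambda * np.eye(k + 1)
        grad = design.T @ (y - mu) - ridge_lambda * beta
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        beta_new = beta + step
        if not np.all(np.isfinite(beta_new)):
            break
        if np.max(np.abs(step)) < TOL * (1 + np.max(np.abs(beta))):
            beta = beta_new
            converged = True
            break
        beta = beta_new

    eta = design @ beta
    mu = expit(np.clip(eta, -700, 700))
    separated = bool(np.all((mu > 0.5) == (y > 0.5)) and np.max(np.abs(eta)) > 30)
    if separated:
        logger.warning("complete or quasi-complete separation detected")
    if not converged and not separated:
        logger.warning("IRLS did not converge in %d iterations", MAX_ITER)

    wt = np.clip(mu * (1 - mu), 1e-12, None)
    hess = (design.T * wt) @ design + ridge_lambda * np.eye(k + 1)
    cov = np.linalg.inv(hess)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    p = 2 * _st.norm.sf(np.abs(z))
    zq = _st.norm.ppf(0.975)

    return LogisticModel(
        intercept=float(beta[0]),
        coef=beta[1:].copy(),
        feature_ids=list(feature_ids or [f"m{i}" for i in range(k)]),
        converged=converged,
        n_iter=it,
        ridge_lambda=ridge_lambda,
        separated=separated,
        se=se, z=z, p=p,
        ci_low=beta - zq * se, ci_high=beta + zq * se,
    )


def loocv_performance(
    x_markers,
    y,
    threshold: float = 0.5,
    ridge_lambda: float = 1e-8,
) -> DiagnosticPerformance:
    """Leave-one-out sensitivity/specificity of the logistic panel.

    Each sample is classified (P >= threshold -> case) by a model
    refitted on the remaining n-1; a fold whose training split loses a
    class is excluded from the counts with a warning.
    """
    x = np.atleast_2d(np.asarray(x_markers, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if n < 6 or (y == 0).sum() < 3 or (y == 1).sum() < 3:
        raise ValueError("LOOCV needs n >= 6 with >= 3 samples per class")
    tp = fp = tn = fn = 0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        if len(np.unique(y[mask])) < 2:
            logger.warning("fold %d excluded: training split lost a class", i)
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            prev = logger.level
            logger.setLevel(logging.ERROR)  # per-fold refits would repeat warnings
            try:
                model = fit_logistic(x[mask], y[mask], ridge_lambda=ridge_lambda)
            finally:
                logger.setLevel(prev)
        prob = float(predict_prob(model, x[i]))
        pred = prob >= threshold
        if y[i] == 1:
            tp += pred
            fn += not pred
        else:
            fp += pred
            tn += not pred
    return DiagnosticPerformance(tp=int(tp), fp=int(fp), tn=int(tn), fn=int(fn),
                                 threshold=threshold)
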