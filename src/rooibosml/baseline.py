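"""Gaussian minimum-Mahalanobis baseline classifier.

Fits a separate multivariate Gaussian to each fermentation class and assigns
a query point to the class with the smaller Mahalanobis distance — the
"smaller multivariate Z-score" rule. With equal class covariances this is
exactly the equal-prior Gaussian maximum-likelihood decision; with unequal
covariances it deliberately omits the log-determinant term (an optional
log-likelihood rule is provided for sensitivity analysis).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import FR, UFR, LABELS, FeatureSetSpec

#: Condition-number ceiling for an acceptable regularized covariance.
_COND_MAX = 1e8
#: Ridge escalation ladder (relative to the mean diagonal entry).
_RIDGE_START = 1e-8


@dataclass(frozen=True)
class GaussianClassModel:
    """Per-class Gaussian fit for one feature-set configuration."""

    feature_spec: FeatureSetSpec
    means: dict  # label -> (d,) mean vector
    covariances: dict  # label -> (d, d) regularized covariance
    counts: dict  # label -> training sample count
    ridge: float  # relative ridge actually applied (0 if none needed)

    @property
    def n_features(self) -> int:
        return self.means[FR].shape[0]


def _regularize(cov: np.ndarray, ridge: float) -> np.ndarray:
    if ridge == 0.0:
        return cov
    return cov + ridge * float(np.mean(np.diag(cov))) * np.eye(cov.shape[0])


def fit_gaussian(
    features: np.ndarray,
    labels: np.ndarray,
    spec: FeatureSetSpec,
    *,
    ridge: float | None = None,
) -> GaussianClassModel:
    """Fit per-class mean and sample covariance (divisor n−1).

    ``ridge=None`` auto-escalates a relative ridge from 1e-8 by decades until
    both class covariances have condition number below 1e8; a ridge of 0 is
    kept when the raw covariances are already well conditioned. An explicit
    ``ridge`` pins the value (0 disables regularization entirely).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("features must be n x d with one label per row")
    d = X.shape[1]
    if d != spec.n_features:
        raise ValueError(
            f"feature matrix has {d} columns but spec {spec.describe()} "
            f"declares {spec.n_features}"
        )

    means, raw_covs, counts = {}, {}, {}
    for label in LABELS:
        Xc = X[y == label]
        if Xc.shape[0] < d + 2:
            raise ValueError(
                f"class {label} has {Xc.shape[0]} samples; need at least "
                f"{d + 2} for a {d}-feature Gaussian fit"
            )
        means[label] = Xc.mean(axis=0)
        raw_covs[label] = np.cov(Xc, rowvar=False, ddof=1).reshape(d, d)
        counts[label] = Xc.shape[0]

    def _cond_ok(r: float) -> bool:
        return all(
            np.linalg.cond(_regularize(raw_covs[l], r)) < _COND_MAX for l in LABELS
        )

    if ridge is None:
        applied = 0.0
        if not _cond_ok(0.0):
            applied = _RIDGE_START
            while not _cond_ok(applied):
                applied *= 10.0
                if applied > 1.0:
                    raise np.linalg.LinAlgError(
                        "covariance irreparably ill-conditioned"
                    )
    else:
        applied = float(ridge)

    covs = {l: _regularize(raw_covs[l], applied) for l in LABELS}
    return GaussianClassModel(
        feature_spec=spec, means=means, covariances=covs, counts=counts, ridge=applied
    )


def mahalanobis_distance(model: GaussianClassModel, label: str, x: np.ndarray) -> float:
    """sqrt((x − μ_c)ᵀ Σ_c⁻¹ (x − μ_c)) for class c = ``label``."""
    if label not in LABELS:
        raise ValueError(f"unknown class {label!r}")
    x = np.asarray(x, dtype=float)
    if x.shape != (model.n_features,):
        raise ValueError(
            f"query has shape {x.shape}; model expects ({model.n_features},)"
        )
    d = x - model.means[label]
    q = float(d @ np.linalg.solve(model.covariances[label], d))
    return float(np.sqrt(max(q, 0.0)))


def _log_likelihood(model: GaussianClassModel, label: str, x: np.ndarray) -> float:
    cov = model.covariances[label]
    d = np.asarray(x, dtype=float) - model.means[label]
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0:
        raise np.linalg.LinAlgError("covariance not positive-definite")
    return -0.5 * (float(d @ np.linalg.solve(cov, d)) + logdet)


def classify(
    model: GaussianClassModel, x: np.ndarray, *, rule: str = "mahalanobis"
) -> str:
    """Assign the class with the smaller Mahalanobis distance; ties go to FR.

    ``rule='loglik'`` switches to the full Gaussian log-likelihood (adds the
    log-determinant term), which differs only when class covariances differ.
    """
    if rule == "mahalanobis":
        d_fr = mahalanobis_distance(model, FR, x)
        d_ufr = mahalanobis_distance(model, UFR, x)
        return FR if d_fr <= d_ufr else UFR
    if rule == "loglik":
        return FR if _log_likelihood(model, FR, x) >= _log_likelihood(model, UFR, x) else UFR
    raise ValueError(f"unknown rule {rule!r}; expected 'mahalanobis' or 'loglik'")


def predict(
    model: GaussianClassModel, X: np.ndarray, *, rule: str = "mahalanobis"
) -> np.ndarray:
    """Vectorized :func:`classify` over the rows of an n×d matrix."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(
            f"query matrix has shape {X.shape}; model expects (n, {model.n_features})"
        )
    if rule == "loglik":
        return np.array([classify(model, x, rule=rule) for x in X], dtype=object)
    q = {}
    for label in LABELS:
        d = X - model.means[label]
        q[label] = np.einsum(
            "ij,ij->i", d, np.linalg.solve(model.covariances[label], d.T).T
        )
    return np.where(q[FR] <= q[UFR], FR, UFR).astype(object)
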