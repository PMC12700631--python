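"""Reference source models and the generic source-model contract.

A source model is frozen before transfer: all downstream modules consume it
only through its *structural function* ``f(x)``, the deterministic
feature-to-scalar map (a linear predictor here; any fitted model's scalar
output in general).  For a binary response the structural function returns
the linear predictor; the inverse-logit is applied downstream, because the
random effect multiplies the structural value *inside* the link:
``P(y=1) = expit(beta * f(x))``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

__all__ = [
    "SourceModel",
    "fit_linear_source",
    "fit_logistic_source",
    "standardize_features",
]


@dataclass(frozen=True)
class SourceModel:
    """A frozen source prediction model.

    Attributes
    ----------
    structural_fn
        Deterministic map from a feature vector (or an (n, p) matrix) to the
        scalar structural value(s) f(x).  Pure: no state, no randomness.
    response_kind
        ``"continuous"`` or ``"binary"``.
    p
        Feature dimension the model expects.
    theta_S
        Fitted coefficient vector, exposed for the reference linear and
        logistic models and for simulation oracles; ``None`` for opaque
        user-supplied models.
    """

    structural_fn: Callable[[np.ndarray], np.ndarray] = field(repr=False)
    response_kind: str
    p: int
    theta_S: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.response_kind not in ("continuous", "binary"):
            raise ValueError(f"unknown response_kind {self.response_kind!r}")
        if self.p < 1:
            raise ValueError("feature dimension p must be positive")

    def structural_values(self, X: np.ndarray) -> np.ndarray:
        """Evaluate f at each row of X, returning a length-n vector."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.p:
            raise ValueError(f"expected {self.p} features, got {X.shape[1]}")
        return np.asarray(self.structural_fn(X), dtype=float).reshape(-1)

    def to_json(self) -> str:
        if self.theta_S is None:
            raise ValueError("only reference models with theta_S serialize to JSON")
        return json.dumps(
            {
                "response_kind": self.response_kind,
                "p": self.p,
                "theta_S": np.asarray(self.theta_S).tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "SourceModel":
        obj = json.loads(text)
        theta = np.asarray(obj["theta_S"], dtype=float)
        return _linear_predictor_model(theta, obj["response_kind"])


def _linear_predictor_model(theta: np.ndarray, response_kind: str) -> SourceModel:
    theta = np.asarray(theta, dtype=float)

    def structural_fn(X: np.ndarray) -> np.ndarray:
        return np.atleast_2d(np.asarray(X, dtype=float)) @ theta

    return SourceModel(
        structural_fn=structural_fn,
        response_kind=response_kind,
        p=theta.size,
        theta_S=theta,
    )


def fit_linear_source(X: np.ndarray, y: np.ndarray) -> SourceModel:
    """Fit the reference linear source model by ordinary least squares.

    Requires n >= p and a full-column-rank design; a rank-deficient X raises
    rather than silently falling back to a pseudo-inverse.  Callers supply
    their own intercept column; none is added implicitly.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).reshape(-1)
    n, p = X.shape
    if n < p:
        raise ValueError(f"need at least p={p} observations, got n={n}")
    if len(y) != n:
        raise ValueError("X and y have mismatched lengths")
    theta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < p:
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < p={p}); "
            "remove collinear columns before fitting"
        )
    return _linear_predictor_model(theta, "continuous")


def fit_logistic_source(
    X: np.ndarray, y: np.ndarray, ridge_on_separation: bool = False
) -> SourceModel:
    """Fit the reference logistic source model by maximum likelihood.

    The structural function returns the *linear predictor* x'theta_hat; the
    inverse-logit is applied downstream.  Perfect separation raises unless
    ``ridge_on_separation`` opts into a tiny L2 penalty (strength 1e-6),
    which keeps the MLE finite at negligible bias.
    """
    import warnings

    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).reshape(-1)
    n, p = X.shape
    if n < p:
        raise ValueError(f"need at least p={p} observations, got n={n}")
    classes = np.unique(y)
    if not np.isin(classes, [0.0, 1.0]).all():
        raise ValueError("binary labels must be coded 0/1")
    if classes.size < 2:
        raise ValueError("labels are single-class; both labels must be present")

    def _ridge_fit() -> np.ndarray:
        from sklearn.linear_model import LogisticRegression

        # C = 1/(n*lambda) so the penalty matches an L2 strength of 1e-6.
        clf = LogisticRegression(
            C=1.0 / (n * 1e-6), fit_intercept=False, max_iter=5000, tol=1e-10
        )
        clf.fit(X, y)
        return clf.coef_.reshape(-1)

    try:
        with warnings.catch_warnings():
            # quasi-separated data triggers benign Hessian warnings from the
            # optimizer; the fit itself is checked below
            warnings.simplefilter("ignore")
            res = sm.Logit(
                y, X
            ).fit(disp=0, maxiter=500, method="lbfgs", pgtol=1e-12, factr=10.0)
        theta = np.asarray(res.params, dtype=float)
        if not np.isfinite(theta).all():
            raise PerfectSeparationError("non-finite MLE")
        # perfect separation: every observation on its own side of the fitted
        # hyperplane, so the unpenalized MLE diverges
        if np.min((2.0 * y - 1.0) * (X @ theta)) > 0.0:
            raise PerfectSeparationError("data are perfectly separated")
    except (PerfectSeparationError, np.linalg.LinAlgError) as err:
        if not ridge_on_separation:
            raise ValueError(
                "logistic fit failed (perfect or quasi-perfect separation); "
                "pass ridge_on_separation=True for a tiny-L2 fallback"
            ) from err
        theta = _ridge_fit()
    return _linear_predictor_model(theta, "binary")


def standardize_features(
    X: np.ndarray, stats: Optional[tuple[np.ndarray, np.ndarray]] = None
) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Center and scale columns to mean zero, unit variance (denominator n).

    When ``stats = (mean, sd)`` is supplied (e.g. to transform held-out
    target data with the target-training statistics), it is applied affinely
    instead of being recomputed.  Returns the transformed matrix and the
    stats used.  A zero-variance column is an error naming the column.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-d matrix")
    if stats is None:
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        bad = np.flatnonzero(sd == 0.0)
        if bad.size:
            raise ValueError(f"zero-variance column(s) at index {bad.tolist()}")
    else:
        mean, sd = (np.asarray(s, dtype=float) for s in stats)
        if mean.size != X.shape[1] or sd.size != X.shape[1]:
            raise ValueError("stats dimension does not match column count")
        if np.any(sd == 0.0):
            raise ValueError("supplied sd contains zeros")
    return (X - mean) / sd, (mean, sd)
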