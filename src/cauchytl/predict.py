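"""Posterior-predictive sampling and prediction-set construction.

Continuous response: for each of ``npost`` posterior draws (delta, gamma,
sigma) sampled with replacement, draw ``nbeta`` random effects
beta ~ Cauchy(delta, gamma), and for each beta draw ``ny`` labels
y ~ N(beta * f(x_new), sigma^2) - npost*nbeta*ny predictive values in total,
from which equal-tailed empirical quantile intervals are cut.

Binary response: the same outer loops produce npost*nbeta success
probabilities expit(beta * f(x_new)); their mean is the predictive success
probability p_tilde (the innermost Bernoulli draw is marginalized
analytically, which leaves the expectation unchanged and removes its
Monte-Carlo variance; a label-sampling path is kept for fidelity checks).
The label set at level 1-alpha contains the favored label alone only when
its predictive mass reaches 1-alpha, else both labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import expit

from .mcmc import PosteriorDraws
from .source import SourceModel

__all__ = [
    "PredictiveSample",
    "PredictionSet",
    "sample_predictive_continuous",
    "sample_predictive_binary",
    "sample_predictive_binary_labels",
    "predictive_interval",
    "binary_prediction_set",
    "point_prediction",
]


@dataclass(frozen=True)
class PredictiveSample:
    """Predictive draws for one new feature vector.

    ``values`` holds continuous label draws (kind="continuous") or success
    probabilities expit(beta*f) (kind="binary").
    """

    values: np.ndarray
    x_new: np.ndarray
    sizes: tuple[int, ...]
    kind: str

    @property
    def p_tilde(self) -> float:
        """Predictive success probability (binary kind only)."""
        if self.kind != "binary":
            raise ValueError("p_tilde is defined for binary predictive samples")
        return float(np.mean(self.values))


@dataclass(frozen=True)
class PredictionSet:
    """An interval [lower, upper] or a label subset of {0, 1} at level 1-alpha."""

    kind: str
    alpha: float
    lower: Optional[float] = None
    upper: Optional[float] = None
    labels: Optional[frozenset] = None

    def __post_init__(self) -> None:
        if self.kind == "interval":
            if self.lower is None or self.upper is None or self.lower > self.upper:
                raise ValueError("interval requires lower <= upper")
        elif self.kind == "label_set":
            if not self.labels:
                raise ValueError("label set must be nonempty")
        else:
            raise ValueError(f"unknown prediction-set kind {self.kind!r}")

    def contains(self, truth: float) -> bool:
        if self.kind == "interval":
            return bool(self.lower <= truth <= self.upper)
        return int(truth) in self.labels


def _check_post(post: PosteriorDraws, kind: str) -> None:
    if len(post) == 0:
        raise ValueError("posterior draws are empty")
    if post.response_kind != kind:
        raise ValueError(f"posterior is for {post.response_kind!r}, expected {kind!r}")


def _draw_betas(
    post: PosteriorDraws, npost: int, nbeta: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Resampled posterior indices and the (npost, nbeta) random effects."""
    idx = rng.integers(len(post), size=npost)
    beta = (
        post.delta[idx, None]
        + post.gamma[idx, None] * rng.standard_cauchy((npost, nbeta))
    )
    return idx, beta


def predictive_draws_continuous(
    f_new: np.ndarray,
    post: PosteriorDraws,
    sizes: tuple[int, int, int],
    rng: np.random.Generator,
) -> np.ndarray:
    """Predictive label draws for a batch of structural values.

    Returns an (m, npost*nbeta*ny) matrix; the posterior and random-effect
    draws are shared across the m points (fresh Gaussian noise per point),
    which preserves each row's marginal predictive law.
    """
    npost, nbeta, ny = sizes
    idx, beta = _draw_betas(post, npost, nbeta, rng)
    f_new = np.asarray(f_new, dtype=float).reshape(-1)
    m = f_new.size
    mean = beta.reshape(1, -1, 1) * f_new[:, None, None]          # (m, npost*nbeta, 1)
    noise = rng.standard_normal((m, npost * nbeta, ny))
    sig = post.sigma[idx].repeat(nbeta).reshape(1, -1, 1)
    return (mean + sig * noise).reshape(m, npost * nbeta * ny)


def predictive_probs_binary(
    f_new: np.ndarray,
    post: PosteriorDraws,
    sizes: tuple[int, int],
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Success-probability draws expit(beta*f) for a batch of points.

    Returns (probs, p_tilde): probs is (m, npost*nbeta), p_tilde its row
    means.  Random-effect draws are shared across points.
    """
    npost, nbeta = sizes
    _, beta = _draw_betas(post, npost, nbeta, rng)
    f_new = np.asarray(f_new, dtype=float).reshape(-1)
    probs = expit(beta.reshape(1, -1) * f_new[:, None])
    return probs, probs.mean(axis=1)


def sample_predictive_continuous(
    x_new: np.ndarray,
    source: SourceModel,
    post: PosteriorDraws,
    sizes: tuple[int, int, int] = (1000, 10, 10),
    rng: Optional[np.random.Generator] = None,
) -> PredictiveSample:
    """Posterior-predictive label draws for one new feature vector."""
    _check_post(post, "continuous")
    rng = rng if rng is not None else np.random.default_rng()
    x_new = np.asarray(x_new, dtype=float).reshape(-1)
    f = source.structural_values(x_new)
    values = predictive_draws_continuous(f, post, sizes, rng)[0]
    return PredictiveSample(values=values, x_new=x_new, sizes=sizes, kind="continuous")


def sample_predictive_binary(
    x_new: np.ndarray,
    source: SourceModel,
    post: PosteriorDraws,
    sizes: tuple[int, int] = (1000, 10),
    rng: Optional[np.random.Generator] = None,
) -> PredictiveSample:
    """Posterior-predictive success-probability draws for one new point."""
    _check_post(post, "binary")
    rng = rng if rng is not None else np.random.default_rng()
    x_new = np.asarray(x_new, dtype=float).reshape(-1)
    f = source.structural_values(x_new)
    probs, _ = predictive_probs_binary(f, post, sizes, rng)
    return PredictiveSample(values=probs[0], x_new=x_new, sizes=sizes, kind="binary")


def sample_predictive_binary_labels(
    x_new: np.ndarray,
    source: SourceModel,
    post: PosteriorDraws,
    sizes: tuple[int, int, int] = (1000, 10, 10),
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Label-sampling fidelity path: npost*nbeta*ny Bernoulli label draws.

    The mean of the returned 0/1 draws estimates the same p_tilde that
    `sample_predictive_binary` computes by analytic marginalization, with
    extra binomial Monte-Carlo noise.
    """
    _check_post(post, "binary")
    rng = rng if rng is not None else np.random.default_rng()
    npost, nbeta, ny = sizes
    x_new = np.asarray(x_new, dtype=float).reshape(-1)
    f = source.structural_values(x_new)
    probs, _ = predictive_probs_binary(f, post, (npost, nbeta), rng)
    labels = rng.uniform(size=(npost * nbeta, ny)) < probs[0][:, None]
    return labels.astype(float).reshape(-1)


def predictive_interval(sample: PredictiveSample, alpha: float) -> PredictionSet:
    """Equal-tailed [alpha/2, 1-alpha/2] empirical-quantile interval."""
    if sample.kind != "continuous":
        raise ValueError("interval requires a continuous predictive sample")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    if sample.values.size < 100:
        raise ValueError("need at least 100 predictive values for stable quantiles")
    lo, hi = np.quantile(sample.values, [alpha / 2.0, 1.0 - alpha / 2.0])
    return PredictionSet(kind="interval", alpha=alpha, lower=float(lo), upper=float(hi))


def binary_prediction_set(p_tilde: float, alpha: float) -> PredictionSet:
    """Label set at level 1-alpha from the predictive success probability.

    {0} if p < 1-p and 1-alpha <= 1-p; {1} if 1-p <= p and 1-alpha <= p;
    otherwise {0, 1}.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    if not (0.0 <= p_tilde <= 1.0):
        raise ValueError("p_tilde must lie in [0, 1]")
    q = 1.0 - p_tilde
    if p_tilde < q and 1.0 - alpha <= q:
        labels = frozenset({0})
    elif q <= p_tilde and 1.0 - alpha <= p_tilde:
        labels = frozenset({1})
    else:
        labels = frozenset({0, 1})
    return PredictionSet(kind="label_set", alpha=alpha, labels=labels)


def point_prediction(sample: PredictiveSample, method: str = "median") -> float:
    """Point prediction from a predictive sample.

    Continuous: the predictive median by default (the Cauchy-mixture
    predictive has no finite mean, so the sample mean is unstable).
    Binary: the predictive success probability p_tilde.
    """
    if sample.values.size == 0:
        raise ValueError("empty predictive sample")
    if sample.kind == "binary":
        return sample.p_tilde
    if method == "median":
        return float(np.median(sample.values))
    raise ValueError(f"unknown point-prediction method {method!r}")
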