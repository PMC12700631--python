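"""The Cauchy similarity law linking source and target models.

For a Gaussian feature vector ``x ~ N_p(0, I)`` and two coefficient vectors
``a`` (target) and ``b`` (source), the ratio of linear predictors
``(x'a) / (x'b)`` is exactly Cauchy distributed.  The location ``delta`` and
scale ``gamma`` of that law quantify source-target similarity:
``delta = 1, gamma = 0`` means the two models are identical, while large
``gamma`` means a weak link between the domains.  This module houses the
closed form for (delta, gamma) and the Cauchy sampling/density utilities
shared by the likelihood and the posterior-predictive sampler.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class CauchyLaw:
    """A Cauchy(delta, gamma) law; gamma = 0 denotes a point mass at delta."""

    delta: float
    gamma: float

    def __post_init__(self) -> None:
        if not (self.gamma >= 0.0):
            raise ValueError(f"gamma must be nonnegative, got {self.gamma}")


def ratio_cauchy_params(a: np.ndarray, b: np.ndarray) -> CauchyLaw:
    """Exact Cauchy law of (x'a)/(x'b) for x ~ N_p(0, I).

    Parameters
    ----------
    a, b
        Real vectors of equal length p; ``b`` is the source coefficient
        vector and must be nonzero.

    Returns
    -------
    CauchyLaw
        delta = a'b / ||b||^2 and
        gamma = ||b||^{-2} * sqrt(||b||^2 ||a||^2 - (a'b)^2).

    The radicand is nonnegative by Cauchy-Schwarz; round-off can push it
    slightly negative when a and b are parallel, so it is clamped at zero
    (a == b must yield exactly gamma = 0).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be one-dimensional vectors of equal length")
    bb = float(b @ b)
    if bb == 0.0:
        raise ValueError(
            "source coefficient vector is zero: no link between the source "
            "and target domains (gamma would be infinite)"
        )
    ab = float(a @ b)
    aa = float(a @ a)
    delta = ab / bb
    radicand = bb * aa - ab * ab
    gamma = math.sqrt(max(radicand, 0.0)) / bb
    return CauchyLaw(delta=delta, gamma=gamma)


def cauchy_sample(law: CauchyLaw, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n iid values from ``law``; gamma = 0 returns the constant delta."""
    if n < 1:
        raise ValueError("n must be a positive integer")
    if law.gamma == 0.0:
        return np.full(n, law.delta, dtype=float)
    return law.delta + law.gamma * rng.standard_cauchy(n)


def cauchy_logpdf(beta, law: CauchyLaw):
    """Log density of Cauchy(delta, gamma) at beta; requires gamma > 0."""
    if law.gamma <= 0.0:
        raise ValueError("degenerate Cauchy law (gamma = 0) has no density")
    beta = np.asarray(beta, dtype=float)
    z = (beta - law.delta) / law.gamma
    out = -np.log(math.pi * law.gamma) - np.log1p(z * z)
    return float(out) if out.ndim == 0 else out
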