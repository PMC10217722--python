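"""Gaussian kernel density estimation for projected canonical scores.

The dependence measure at the heart of RPCCA is estimated from kernel
density estimates of the two univariate score distributions and of their
bivariate joint.  The marginal estimates use the classic normal-reference
bandwidth ``1.06 n^{-1/5} s`` while the joint (product-kernel) estimate
uses the faster-shrinking ``n^{-1/6} s`` per coordinate, where ``s`` is the
sample standard deviation of the corresponding score vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .errors import DegenerateSampleError, InvalidInputError

__all__ = [
    "gaussian_kernel",
    "bandwidths",
    "BandwidthSpec",
    "GaussianKde1D",
    "GaussianKdeProduct2D",
]

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)

#: query rows processed per block when evaluating a KDE on a large grid,
#: keeping the (block x n) kernel matrix at a modest memory footprint
_EVAL_BLOCK = 1024


def gaussian_kernel(x):
    """Standard normal kernel ``K(x) = (2*pi)^{-1/2} exp(-x^2/2)``.

    Accepts scalars or arrays; raises :class:`InvalidInputError` on
    non-finite input.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise InvalidInputError("kernel argument must be finite")
    out = np.exp(-0.5 * x * x - _LOG_SQRT_2PI)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class BandwidthSpec:
    """The four bandwidths driving the score-density estimates.

    ``marginal_*`` are the univariate bandwidths ``1.06 n^{-1/5} s_j`` and
    ``joint_*`` the product-kernel bandwidths ``n^{-1/6} s_j``.
    """

    marginal_u: float
    marginal_v: float
    joint_u: float
    joint_v: float
    sample_sd_u: float
    sample_sd_v: float
    n: int


def _sample_sd(x: np.ndarray) -> float:
    # n-1 denominator: the mainstream sample-sd convention
    return float(np.std(x, ddof=1))


def bandwidths(scores_u, scores_v) -> BandwidthSpec:
    """Compute the marginal and joint bandwidths from the score vectors.

    Raises :class:`DegenerateSampleError` for n < 2 or a zero sample
    standard deviation (either would give a zero bandwidth).
    """
    u = np.asarray(scores_u, dtype=float)
    v = np.asarray(scores_v, dtype=float)
    n = u.shape[0]
    if n < 2 or v.shape[0] < 2:
        raise DegenerateSampleError("need at least 2 observations for bandwidths")
    su, sv = _sample_sd(u), _sample_sd(v)
    if su <= 0.0 or sv <= 0.0:
        raise DegenerateSampleError("zero sample standard deviation: bandwidth would vanish")
    c_marginal = 1.06 * n ** (-0.2)
    c_joint = n ** (-1.0 / 6.0)
    return BandwidthSpec(
        marginal_u=c_marginal * su,
        marginal_v=c_marginal * sv,
        joint_u=c_joint * su,
        joint_v=c_joint * sv,
        sample_sd_u=su,
        sample_sd_v=sv,
        n=n,
    )


class GaussianKde1D:
    """Univariate Gaussian KDE ``(1/(n h)) sum_i K((q - x_i)/h)``."""

    arity = "univariate"

    def __init__(self, points, bandwidth: float):
        self.points = np.asarray(points, dtype=float).ravel()
        if not np.all(np.isfinite(self.points)):
            raise InvalidInputError("sample points must be finite")
        if not bandwidth > 0:
            raise InvalidInputError("bandwidth must be strictly positive")
        self.bandwidth = float(bandwidth)

    def logpdf(self, query):
        q = np.atleast_1d(np.asarray(query, dtype=float))
        if not np.all(np.isfinite(q)):
            raise InvalidInputError("query must be finite")
        n, h = self.points.shape[0], self.bandwidth
        norm = np.log(n * h) + _LOG_SQRT_2PI
        out = np.empty(q.shape[0])
        for lo in range(0, q.shape[0], _EVAL_BLOCK):
            block = q[lo : lo + _EVAL_BLOCK, None]
            z = (block - self.points[None, :]) / h
            out[lo : lo + _EVAL_BLOCK] = logsumexp(-0.5 * z * z, axis=1) - norm
        return out if np.ndim(query) else float(out[0])

    def pdf(self, query):
        return np.exp(self.logpdf(query))


class GaussianKdeProduct2D:
    """Bivariate product-Gaussian KDE.

    ``(1/(n h_u h_v)) sum_i K((q_u - u_i)/h_u) K((q_v - v_i)/h_v)`` — a
    single sum over observations with a product kernel, not the product of
    the two marginal estimates.
    """

    arity = "bivariate"

    def __init__(self, points_u, points_v, bandwidth_u: float, bandwidth_v: float):
        self.points_u = np.asarray(points_u, dtype=float).ravel()
        self.points_v = np.asarray(points_v, dtype=float).ravel()
        if self.points_u.shape != self.points_v.shape:
            raise InvalidInputError("paired samples must have equal length")
        if not (np.all(np.isfinite(self.points_u)) and np.all(np.isfinite(self.points_v))):
            raise InvalidInputError("sample points must be finite")
        if not (bandwidth_u > 0 and bandwidth_v > 0):
            raise InvalidInputError("bandwidths must be strictly positive")
        self.bandwidth_u = float(bandwidth_u)
        self.bandwidth_v = float(bandwidth_v)

    def logpdf(self, query_u, query_v):
        qu = np.atleast_1d(np.asarray(query_u, dtype=float))
        qv = np.atleast_1d(np.asarray(query_v, dtype=float))
        if qu.shape != qv.shape:
            raise InvalidInputError("query coordinates must have equal shape")
        if not (np.all(np.isfinite(qu)) and np.all(np.isfinite(qv))):
            raise InvalidInputError("query must be finite")
        n = self.points_u.shape[0]
        hu, hv = self.bandwidth_u, self.bandwidth_v
        norm = np.log(n * hu * hv) + 2.0 * _LOG_SQRT_2PI
        out = np.empty(qu.shape[0])
        for lo in range(0, qu.shape[0], _EVAL_BLOCK):
            zu = (qu[lo : lo + _EVAL_BLOCK, None] - self.points_u[None, :]) / hu
            zv = (qv[lo : lo + _EVAL_BLOCK, None] - self.points_v[None, :]) / hv
            out[lo : lo + _EVAL_BLOCK] = logsumexp(-0.5 * (zu * zu + zv * zv), axis=1) - norm
        return out if np.ndim(query_u) else float(out[0])

    def pdf(self, query_u, query_v):
        return np.exp(self.logpdf(query_u, query_v))
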