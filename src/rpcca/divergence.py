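"""Empirical Renyi pseudodistance (RP) between projected scores.

Given paired projection scores ``u_i = a'x_i`` and ``v_i = b'y_i``, the RP
of tuning parameter ``tau > 0`` between the joint score density and the
product of the marginals is estimated by plugging kernel density estimates
into the expectation form of the divergence:

    d_tau = 1/(tau(tau+1)) * ln( (1/n) sum f_uv(u_i,v_i)^tau )
          - 1/tau          * ln( (1/n) sum f_u(u_i)^tau f_v(v_i)^tau )
          + 1/(tau+1)      * ln( (1/n sum f_u(u_i)^tau)(1/n sum f_v(v_i)^tau) )

At ``tau = 0`` the family reduces to the empirical Kullback-Leibler
divergence ``(1/n) sum ln[f_uv/(f_u f_v)]`` (mutual information), which is
the objective of informational CCA.  Larger ``tau`` down-weights
low-density (outlying) observations, which is the source of the method's
robustness.

All log-density sums go through ``logsumexp`` so that large ``tau`` or
extreme scores cannot underflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from . import kde
from .errors import DomainError, InvalidInputError

__all__ = [
    "ProjectionScores",
    "RpValue",
    "rp_hat",
    "rp_kl_hat",
    "rp_value",
    "rp_normal",
    "robustness_weights",
]


@dataclass(frozen=True)
class ProjectionScores:
    """Paired canonical scores ``(u_i, v_i)`` for one candidate pair.

    Rows are paired observations: any estimator built on the scores must be
    invariant to jointly permuting ``u`` and ``v``.
    """

    u: np.ndarray
    v: np.ndarray

    def __post_init__(self):
        u = np.asarray(self.u, dtype=float).ravel()
        v = np.asarray(self.v, dtype=float).ravel()
        if u.shape != v.shape:
            raise InvalidInputError("u and v must have equal length")
        if not (np.all(np.isfinite(u)) and np.all(np.isfinite(v))):
            raise InvalidInputError("scores must be finite")
        object.__setattr__(self, "u", u)
        object.__setattr__(self, "v", v)

    @property
    def n(self) -> int:
        return self.u.shape[0]


@dataclass(frozen=True)
class RpValue:
    """An estimated RP value with its three-logarithm decomposition.

    ``value = term_marginal + term_cross + term_joint``.  The cross term is
    the weighted-KL part that down-weights outliers; storing the split
    makes that interpretation inspectable.
    """

    tau: float
    value: float
    term_marginal: float
    term_cross: float
    term_joint: float


_LOG_2PI = np.log(2.0 * np.pi)

try:  # optional compiled kernel for the optimizer's hot path
    from numba import njit as _njit

    @_njit(cache=True, fastmath=True)
    def _log_density_sums(u, v, cu, cv, cju, cjv):  # pragma: no cover - compiled
        n = u.shape[0]
        lfu = np.empty(n)
        lfv = np.empty(n)
        lfuv = np.empty(n)
        b1 = np.empty(n)
        b2 = np.empty(n)
        b3 = np.empty(n)
        for i in range(n):
            m1 = m2 = m3 = -np.inf
            for j in range(n):
                du = u[i] - u[j]
                dv = v[i] - v[j]
                su = du * du
                sv = dv * dv
                t1 = cu * su
                t2 = cv * sv
                t3 = cju * su + cjv * sv
                b1[j] = t1
                b2[j] = t2
                b3[j] = t3
                if t1 > m1:
                    m1 = t1
                if t2 > m2:
                    m2 = t2
                if t3 > m3:
                    m3 = t3
            s1 = s2 = s3 = 0.0
            for j in range(n):
                s1 += np.exp(b1[j] - m1)
                s2 += np.exp(b2[j] - m2)
                s3 += np.exp(b3[j] - m3)
            lfu[i] = m1 + np.log(s1)
            lfv[i] = m2 + np.log(s2)
            lfuv[i] = m3 + np.log(s3)
        return lfu, lfv, lfuv

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _fitted_log_densities_numpy(u, v, bw):
    """Reference vectorized path; shares the squared-difference matrices
    across the three density estimates."""
    n = u.shape[0]
    du = u[:, None] - u[None, :]
    dv = v[:, None] - v[None, :]
    su = du * du
    sv = dv * dv
    log_fu = logsumexp(su * (-0.5 / bw.marginal_u**2), axis=1)
    log_fv = logsumexp(sv * (-0.5 / bw.marginal_v**2), axis=1)
    log_fuv = logsumexp(su * (-0.5 / bw.joint_u**2) + sv * (-0.5 / bw.joint_v**2), axis=1)
    return log_fu, log_fv, log_fuv


def _fitted_log_densities(u: np.ndarray, v: np.ndarray):
    """Fit the three KDEs on the scores and evaluate them at the sample.

    Returns ``(log f_u(u_i), log f_v(v_i), log f_uv(u_i, v_i))``.  No
    leave-one-out correction: the estimator sums the fitted densities at
    the very points used to fit them.

    This is the optimizer's hot path: the three kernel sums are fused in
    one compiled pass over the pairwise differences when numba is
    available, falling back to a shared-buffer numpy computation
    otherwise; the unit suite pins both against the public
    :mod:`~rpcca.kde` estimator classes.
    """
    bw = kde.bandwidths(u, v)
    n = u.shape[0]
    u = np.ascontiguousarray(u, dtype=np.float64)
    v = np.ascontiguousarray(v, dtype=np.float64)
    if _HAVE_NUMBA:
        log_fu, log_fv, log_fuv = _log_density_sums(
            u,
            v,
            -0.5 / bw.marginal_u**2,
            -0.5 / bw.marginal_v**2,
            -0.5 / bw.joint_u**2,
            -0.5 / bw.joint_v**2,
        )
    else:
        log_fu, log_fv, log_fuv = _fitted_log_densities_numpy(u, v, bw)
    log_fu = log_fu - (np.log(n * bw.marginal_u) + 0.5 * _LOG_2PI)
    log_fv = log_fv - (np.log(n * bw.marginal_v) + 0.5 * _LOG_2PI)
    log_fuv = log_fuv - (np.log(n * bw.joint_u * bw.joint_v) + _LOG_2PI)
    return log_fu, log_fv, log_fuv


def rp_hat(scores: ProjectionScores, tau: float) -> RpValue:
    """Empirical RP of the scores for ``tau > 0``.

    For ``tau <= 0`` use :func:`rp_kl_hat` (or :func:`rp_value`, which
    dispatches); the ``tau > 0`` expression is an indeterminate 0/0 at the
    origin.
    """
    if not tau > 0:
        raise DomainError("rp_hat requires tau > 0; use rp_kl_hat at tau = 0")
    log_fu, log_fv, log_fuv = _fitted_log_densities(scores.u, scores.v)
    return _rp_from_log_densities(log_fu, log_fv, log_fuv, tau)


def _rp_from_log_densities(log_fu, log_fv, log_fuv, tau: float) -> RpValue:
    n = log_fu.shape[0]
    log_n = math.log(n)
    # ln[(1/n) sum f^tau] computed in log space
    ln_joint = logsumexp(tau * log_fuv) - log_n
    ln_cross = logsumexp(tau * (log_fu + log_fv)) - log_n
    ln_mu = logsumexp(tau * log_fu) - log_n
    ln_mv = logsumexp(tau * log_fv) - log_n
    term_joint = ln_joint / (tau * (tau + 1.0))
    term_cross = -ln_cross / tau
    term_marginal = (ln_mu + ln_mv) / (tau + 1.0)
    return RpValue(
        tau=float(tau),
        value=term_marginal + term_cross + term_joint,
        term_marginal=term_marginal,
        term_cross=term_cross,
        term_joint=term_joint,
    )


def rp_kl_hat(scores: ProjectionScores) -> RpValue:
    """Empirical Kullback-Leibler limit of the RP family at ``tau = 0``.

    ``(1/n) sum ln[f_uv(u_i,v_i) / (f_u(u_i) f_v(v_i))]`` — the informational
    CCA objective.  The decomposition mirrors the ``tau -> 0`` limits of the
    three RP terms (the marginal term vanishes).
    """
    log_fu, log_fv, log_fuv = _fitted_log_densities(scores.u, scores.v)
    term_joint = float(np.mean(log_fuv))
    term_cross = -float(np.mean(log_fu + log_fv))
    return RpValue(
        tau=0.0,
        value=term_joint + term_cross,
        term_marginal=0.0,
        term_cross=term_cross,
        term_joint=term_joint,
    )


def rp_value(scores: ProjectionScores, tau: float) -> RpValue:
    """Empirical RP at any ``tau >= 0``, dispatching ``tau = 0`` to the KL."""
    if tau < 0:
        raise DomainError("tau must be nonnegative")
    return rp_kl_hat(scores) if tau == 0 else rp_hat(scores, tau)


def rp_normal(rho: float, tau: float) -> float:
    """Closed-form RP between a bivariate normal and its marginal product.

    For correlation ``rho`` and unit-variance margins,

        d_tau = ln{ [(1+tau(1+rho))(1+tau(1-rho))]^{1/(2 tau)}
                    / [(1+tau)^{1/tau} (1-rho^2)^{1/(2(tau+1))}] }

    with the ``tau = 0`` limit ``-0.5 ln(1 - rho^2)`` (the Gaussian mutual
    information).  It is increasing in ``rho^2`` for every ``tau``, which is
    why, under joint normality, maximizing it reproduces classical CCA.
    """
    if not abs(rho) < 1:
        raise DomainError("rho must lie strictly inside (-1, 1)")
    if tau < 0:
        raise DomainError("tau must be nonnegative")
    if tau == 0:
        return -0.5 * math.log1p(-rho * rho)
    # log1p keeps the 1/(2 tau) factors accurate for tiny tau
    ln_num = (math.log1p(tau * (1.0 + rho)) + math.log1p(tau * (1.0 - rho))) / (2.0 * tau)
    ln_den = math.log1p(tau) / tau + math.log1p(-rho * rho) / (2.0 * (tau + 1.0))
    return ln_num - ln_den


def robustness_weights(scores: ProjectionScores, tau: float):
    """Per-observation down-weighting factors of the RP estimator.

    Returns the tau-powered fitted densities ``(f_uv^tau, f_u^tau, f_v^tau)``
    at each sample point.  For small ``tau`` the RP behaves like a KL
    divergence weighted by these factors, so observations in low-density
    regions (outliers) contribute less; at ``tau = 0`` every weight is 1.
    """
    if tau < 0:
        raise DomainError("tau must be nonnegative")
    log_fu, log_fv, log_fuv = _fitted_log_densities(scores.u, scores.v)
    return (
        np.exp(tau * log_fuv),
        np.exp(tau * log_fu),
        np.exp(tau * log_fv),
    )
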