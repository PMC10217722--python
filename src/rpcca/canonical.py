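"""Sequential extraction of RPCCA canonical pairs.

Each pair ``(a_i, b_i)`` maximizes the empirical Renyi pseudodistance of
the projected scores ``(a'x, b'y)`` subject to unit sample variance
(``a' S_x a = 1``) and zero sample covariance with every earlier pair on
the same side.  Both blocks are whitened first (``S^{-1/2}(x - mean)``),
which turns the constraints into plain unit-norm/orthogonality; the
divergence itself is invariant under such invertible linear maps, so the
optimum is unchanged.  When a sample covariance is numerically singular
the whitening is skipped and the original covariance-metric constraints
are used directly.

The maximization is non-concave, so each pair is fitted with a multi-start
sequential-least-squares (SQP) optimizer: one warm start at the classical
CCA solution (which is exact under joint normality) plus random draws on
the constraint manifold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .divergence import (
    RpValue,
    _fitted_log_densities,
    _rp_from_log_densities,
    rp_value,
    ProjectionScores,
)
from .errors import DegenerateSampleError, DomainError, FitError

__all__ = [
    "WhiteningTransform",
    "CanonicalPair",
    "RpccaModel",
    "whiten",
    "fit_pair",
    "fit",
    "classical_cca",
]

#: eigenvalue-ratio threshold beyond which a sample covariance is treated
#: as singular and the whitening step is skipped
CONDITION_THRESHOLD = 1e10

#: default multi-start budget per canonical pair
DEFAULT_RESTARTS = 10

_FTOL = 1e-8
_CTOL = 1e-6
_MAXITER = 500


@dataclass(frozen=True)
class WhiteningTransform:
    """Affine map taking one data block to zero mean and identity covariance.

    ``applied`` is False when the covariance was numerically singular; the
    data are then only centered and downstream constraints revert to the
    covariance metric.
    """

    mean: np.ndarray
    cov: np.ndarray
    inv_sqrt: np.ndarray
    applied: bool

    def transform(self, data: np.ndarray) -> np.ndarray:
        centered = np.asarray(data, dtype=float) - self.mean
        return centered @ self.inv_sqrt if self.applied else centered

    def back_transform_vector(self, w: np.ndarray) -> np.ndarray:
        """Map a whitened-coordinate canonical vector to original coordinates."""
        return self.inv_sqrt @ w if self.applied else np.asarray(w, dtype=float)

    def to_white_vector(self, w: np.ndarray) -> np.ndarray:
        """Map an original-coordinate canonical vector to these whitened
        coordinates (inverse of :meth:`back_transform_vector`)."""
        w = np.asarray(w, dtype=float)
        return np.linalg.solve(self.inv_sqrt, w) if self.applied else w


@dataclass(frozen=True)
class CanonicalPair:
    """One fitted canonical pair with its achieved divergence."""

    a: np.ndarray
    b: np.ndarray
    a_white: np.ndarray
    b_white: np.ndarray
    divergence: RpValue
    index: int
    pvalue: float | None = None


@dataclass
class RpccaModel:
    """An ordered set of canonical pairs plus the whitening transforms."""

    pairs: list[CanonicalPair]
    tau: float
    transform_x: WhiteningTransform
    transform_y: WhiteningTransform
    fit_log: list = field(default_factory=list)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def scores(self, X, Y, index: int = 1):
        """Projection scores ``(a_i'x, b_i'y)`` of the ``index``-th pair."""
        pair = self.pairs[index - 1]
        return np.asarray(X, float) @ pair.a, np.asarray(Y, float) @ pair.b


def _sample_cov(data: np.ndarray) -> np.ndarray:
    return np.atleast_2d(np.cov(data, rowvar=False, ddof=1))


def whiten(data):
    """Whiten a data block; fall back to centering if the covariance is singular.

    Returns ``(whitened, WhiteningTransform)``.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim == 1:
        data = data[:, None]
    mean = data.mean(axis=0)
    cov = _sample_cov(data)
    eigval, eigvec = np.linalg.eigh(cov)
    if eigval[0] <= 0 or eigval[-1] / eigval[0] > CONDITION_THRESHOLD:
        tr = WhiteningTransform(mean=mean, cov=cov, inv_sqrt=np.eye(cov.shape[0]), applied=False)
        return data - mean, tr
    inv_sqrt = (eigvec / np.sqrt(eigval)) @ eigvec.T
    tr = WhiteningTransform(mean=mean, cov=cov, inv_sqrt=inv_sqrt, applied=True)
    return (data - mean) @ inv_sqrt, tr


def classical_cca(X, Y, n_pairs: int = 1):
    """Classical (linear) CCA via SVD of the whitened cross-covariance.

    Returns ``(A, B, correlations)`` with canonical vectors as columns in
    original coordinates, normalized to unit sample variance.  Used as the
    warm start for the RP maximization and as a linear baseline.
    """
    Xw, tx = whiten(X)
    Yw, ty = whiten(Y)
    A_w, B_w, corr = _cca_whitened(Xw, Yw)
    k = min(n_pairs, A_w.shape[1])
    A = np.column_stack([tx.back_transform_vector(A_w[:, i]) for i in range(k)])
    B = np.column_stack([ty.back_transform_vector(B_w[:, i]) for i in range(k)])
    return A, B, corr[:k]


def _cca_whitened(Xw: np.ndarray, Yw: np.ndarray):
    n = Xw.shape[0]
    C = Xw.T @ Yw / (n - 1)
    U, s, Vt = np.linalg.svd(C)
    k = min(Xw.shape[1], Yw.shape[1])
    return U[:, :k], Vt[:k].T, np.clip(s[:k], 0.0, 1.0)


def _fix_sign(w: np.ndarray) -> np.ndarray:
    # sign indeterminacy: make the largest-magnitude component positive
    return -w if w[np.argmax(np.abs(w))] < 0 else w


def _project_to_manifold(z, prior_vecs, orth_metric, unit_metric):
    """Make ``z`` feasible: orthogonalize against the prior vectors in the
    orthogonality metric, then normalize in the unit metric.

    Prior vectors are mutually orthogonal in ``orth_metric`` (each was
    constrained when fitted), so sequential oblique projection along the
    priors themselves is exact.
    """

    def apply(M, w):
        return w if M is None else M @ w

    for w in prior_vecs:
        Mw = apply(orth_metric, w)
        z = z - ((Mw @ z) / (Mw @ w)) * w
    norm2 = float(z @ apply(unit_metric, z))
    if norm2 <= 1e-12:
        return None
    return z / np.sqrt(norm2)


def _neg_objective(Xw, Yw, tau):
    q = Xw.shape[1]

    def fun(theta):
        u = Xw @ theta[:q]
        v = Yw @ theta[q:]
        try:
            log_fu, log_fv, log_fuv = _fitted_log_densities(u, v)
        except DegenerateSampleError:
            return np.inf
        if tau == 0:
            val = float(np.mean(log_fuv) - np.mean(log_fu + log_fv))
        else:
            val = _rp_from_log_densities(log_fu, log_fv, log_fuv, tau).value
        return -val

    return fun


def _constraints(q, p, prior_a, prior_b, metrics):
    """SLSQP equality constraints: unit variance in the covariance metric,
    orthogonality to earlier pairs in the Euclidean (original-coordinate)
    metric.  ``metrics`` holds ``(unit_x, orth_x, unit_y, orth_y)`` matrices
    expressed in the optimization coordinates (None means identity)."""
    unit_x, orth_x, unit_y, orth_y = metrics
    Ux = np.eye(q) if unit_x is None else unit_x
    Uy = np.eye(p) if unit_y is None else unit_y
    cons = []

    def unit(M, sl):
        def f(theta):
            w = theta[sl]
            return float(w @ M @ w) - 1.0

        def jac(theta):
            g = np.zeros(q + p)
            g[sl] = 2.0 * M @ theta[sl]
            return g

        return {"type": "eq", "fun": f, "jac": jac}

    def orth(Mw, sl):
        def f(theta):
            return float(Mw @ theta[sl])

        def jac(theta):
            g = np.zeros(q + p)
            g[sl] = Mw
            return g

        return {"type": "eq", "fun": f, "jac": jac}

    a_sl, b_sl = slice(0, q), slice(q, q + p)
    cons.append(unit(Ux, a_sl))
    cons.append(unit(Uy, b_sl))
    for wa in prior_a:
        cons.append(orth(wa if orth_x is None else orth_x @ wa, a_sl))
    for wb in prior_b:
        cons.append(orth(wb if orth_y is None else orth_y @ wb, b_sl))
    return cons


def _max_violation(theta, cons):
    return max(abs(c["fun"](theta)) for c in cons)


def _metrics_for(transform: WhiteningTransform | None):
    """``(unit, orth)`` constraint metrics in the optimization coordinates.

    Whitened coordinates: the unit-variance constraint is the identity,
    and Euclidean orthogonality of the original-coordinate vectors becomes
    the S^{-1} metric.  Fallback (original, centered coordinates): unit
    variance uses the covariance; orthogonality is the identity.
    """
    if transform is None:
        return None, None
    if transform.applied:
        return None, transform.inv_sqrt @ transform.inv_sqrt
    return transform.cov, None


def fit_pair(
    Xw,
    Yw,
    tau: float,
    prior=(),
    *,
    restarts: int = DEFAULT_RESTARTS,
    rng=None,
    transform_x: WhiteningTransform | None = None,
    transform_y: WhiteningTransform | None = None,
    init=None,
    fit_log: list | None = None,
) -> CanonicalPair:
    """Fit the next canonical pair on (whitened) data by constrained SQP.

    ``prior`` holds the earlier :class:`CanonicalPair` objects whose
    whitened vectors define the orthogonality constraints; the transforms
    supply the constraint metrics and the back-transform to original
    coordinates.  ``init`` optionally supplies explicit whitened-coordinate
    ``(a0, b0)`` starting points (used ahead of the CCA warm start and
    random draws, e.g. for warm-started continuation refits).  Raises
    :class:`FitError` if no restart reaches a feasible point.
    """
    Xw = np.asarray(Xw, dtype=float)
    Yw = np.asarray(Yw, dtype=float)
    n, q = Xw.shape
    p = Yw.shape[1]
    index = len(prior) + 1
    if index > min(q, p):
        raise DomainError(f"cannot extract pair {index}: only min(q, p) = {min(q, p)} exist")
    rng = np.random.default_rng(rng)

    unit_x, orth_x = _metrics_for(transform_x)
    unit_y, orth_y = _metrics_for(transform_y)
    prior_a = [pr.a_white for pr in prior]
    prior_b = [pr.b_white for pr in prior]
    neg = _neg_objective(Xw, Yw, tau)
    cons = _constraints(q, p, prior_a, prior_b, (unit_x, orth_x, unit_y, orth_y))

    starts = []
    for a0, b0 in init or ():
        a0 = _project_to_manifold(np.asarray(a0, float), prior_a, orth_x, unit_x)
        b0 = _project_to_manifold(np.asarray(b0, float), prior_b, orth_y, unit_y)
        if a0 is not None and b0 is not None:
            starts.append(np.concatenate([a0, b0]))
    if len(starts) < restarts and unit_x is None and unit_y is None:
        # classical CCA warm start (exact under joint normality)
        A_w, B_w, _ = _cca_whitened(Xw - Xw.mean(0), Yw - Yw.mean(0))
        j = min(index, A_w.shape[1]) - 1
        a0 = _project_to_manifold(A_w[:, j], prior_a, orth_x, unit_x)
        b0 = _project_to_manifold(B_w[:, j], prior_b, orth_y, unit_y)
        if a0 is not None and b0 is not None:
            starts.append(np.concatenate([a0, b0]))
    while len(starts) < restarts:
        a0 = _project_to_manifold(rng.standard_normal(q), prior_a, orth_x, unit_x)
        b0 = _project_to_manifold(rng.standard_normal(p), prior_b, orth_y, unit_y)
        if a0 is not None and b0 is not None:
            starts.append(np.concatenate([a0, b0]))

    best = None
    log = []
    for k, x0 in enumerate(starts):
        res = minimize(
            neg,
            x0,
            method="SLSQP",
            constraints=cons,
            options={"maxiter": _MAXITER, "ftol": _FTOL},
        )
        viol = _max_violation(res.x, cons)
        feasible = np.isfinite(res.fun) and viol < _CTOL
        log.append(
            {
                "pair": index,
                "restart": k,
                "objective": -float(res.fun),
                "constraint_violation": float(viol),
                "converged": bool(res.success),
                "feasible": bool(feasible),
                "n_iter": int(res.nit),
            }
        )
        if feasible and (best is None or res.fun < best.fun):
            best = res
    if fit_log is not None:
        fit_log.extend(log)
    if best is None:
        raise FitError(f"no feasible optimum found for pair {index}", diagnostics=log)

    a_w = _fix_sign(best.x[:q])
    b_w = _fix_sign(best.x[q:])
    div = rp_value(ProjectionScores(Xw @ a_w, Yw @ b_w), tau)
    a = transform_x.back_transform_vector(a_w) if transform_x is not None else a_w.copy()
    b = transform_y.back_transform_vector(b_w) if transform_y is not None else b_w.copy()
    return CanonicalPair(a=a, b=b, a_white=a_w, b_white=b_w, divergence=div, index=index)


def fit(
    X,
    Y,
    tau: float = 0.3,
    n_pairs: int = 1,
    *,
    restarts: int = DEFAULT_RESTARTS,
    seed=None,
) -> RpccaModel:
    """Fit an RPCCA model: whiten, extract pairs sequentially, back-transform.

    ``tau`` trades efficiency (0, informational CCA) against robustness to
    contamination; moderate values around 0.3 are a good compromise.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.shape[0] != Y.shape[0]:
        raise DomainError("X and Y must have the same number of rows")
    if tau < 0:
        raise DomainError("tau must be nonnegative")
    k_max = min(X.shape[1], Y.shape[1])
    if not 1 <= n_pairs <= k_max:
        raise DomainError(f"n_pairs must lie in [1, min(q, p) = {k_max}]")

    Xw, tx = whiten(X)
    Yw, ty = whiten(Y)

    rng = np.random.default_rng(seed)
    pairs: list[CanonicalPair] = []
    fit_log: list = []
    for _ in range(n_pairs):
        pairs.append(
            fit_pair(
                Xw,
                Yw,
                tau,
                prior=pairs,
                restarts=restarts,
                rng=rng,
                transform_x=tx,
                transform_y=ty,
                fit_log=fit_log,
            )
        )
    return RpccaModel(pairs=pairs, tau=tau, transform_x=tx, transform_y=ty, fit_log=fit_log)


def refit_from(model: RpccaModel, X, Y, *, rng=None) -> RpccaModel:
    """Locally refit a fitted model on perturbed data by continuation.

    Each pair is re-optimized with a single SQP run warm-started at the
    corresponding solution of ``model`` (mapped into the new data's
    whitened coordinates), tracking the same local optimum instead of
    re-running the global multi-start search.  This isolates the
    estimator's sensitivity to the data perturbation from restart-to-
    restart basin hopping, which is what a stability comparison between
    coupled clean/contaminated datasets is meant to measure.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    Xw, tx = whiten(X)
    Yw, ty = whiten(Y)
    rng = np.random.default_rng(rng)
    pairs: list[CanonicalPair] = []
    fit_log: list = []
    for pr in model.pairs:
        init = [(tx.to_white_vector(pr.a), ty.to_white_vector(pr.b))]
        pairs.append(
            fit_pair(
                Xw,
                Yw,
                model.tau,
                prior=pairs,
                restarts=1,
                rng=rng,
                transform_x=tx,
                transform_y=ty,
                init=init,
                fit_log=fit_log,
            )
        )
    return RpccaModel(pairs=pairs, tau=model.tau, transform_x=tx, transform_y=ty, fit_log=fit_log)
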