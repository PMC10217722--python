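"""Permutation test for a null RP divergence and sequential determination
of the number of significant canonical pairs.

Permuting the rows of X while keeping Y fixed destroys any cross-block
dependence but leaves both marginal distributions (and the covariance of
each block, hence the constraint geometry) unchanged.  Refitting the
canonical pair on many permuted datasets yields the null distribution of
the maximized divergence; the p-value is the fraction of permuted maxima
strictly exceeding the observed one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .canonical import DEFAULT_RESTARTS, RpccaModel, fit, fit_pair, whiten
from .errors import DomainError, FitError

__all__ = ["PermutationResult", "permutation_test", "n_significant_pairs"]


@dataclass(frozen=True)
class PermutationResult:
    """Outcome of the permutation test for one canonical pair.

    ``pvalue`` is the exact indicator average ``(1/R) sum I(d_perm > d_obs)``
    over the ``R`` completed permutations (ties favor the null).
    """

    pair_index: int
    observed: float
    permuted: np.ndarray
    pvalue: float
    n_permutations: int
    seed: object
    n_failed: int = 0


def _whitened_blocks(model: RpccaModel, X, Y):
    Xw = model.transform_x.transform(np.asarray(X, float))
    Yw = model.transform_y.transform(np.asarray(Y, float))
    return Xw, Yw


def permutation_test(
    X,
    Y,
    tau: float,
    pair_index: int = 1,
    n_permutations: int = 100,
    seed=None,
    *,
    prior=None,
    model: RpccaModel | None = None,
    restarts: int = DEFAULT_RESTARTS,
) -> PermutationResult:
    """Test whether the ``pair_index``-th canonical divergence is zero.

    For each of ``n_permutations`` uniform row permutations of X (Y fixed),
    the pair is refitted under the same unit-variance and orthogonality
    constraints — with the same multi-start budget as the observed fit, so
    observed and permuted maxima are comparable — and its maximized
    divergence recorded.  Permutations whose refit fails are skipped and
    counted in ``n_failed``; the p-value then averages over the completed
    ones.

    A fitted ``model`` holding at least ``pair_index`` pairs may be passed
    to reuse the observed fit (``prior`` is then ignored).
    """
    if n_permutations < 1:
        raise DomainError("n_permutations must be at least 1")
    rng = np.random.default_rng(seed)
    if model is None:
        model = fit(X, Y, tau, n_pairs=pair_index, restarts=restarts, seed=rng)
    elif model.n_pairs < pair_index:
        raise DomainError("model holds fewer pairs than pair_index")

    observed = model.pairs[pair_index - 1].divergence.value
    prior_pairs = model.pairs[: pair_index - 1]
    Xw, Yw = _whitened_blocks(model, X, Y)

    n = Xw.shape[0]
    permuted = []
    n_failed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        try:
            pair = fit_pair(
                Xw[perm],
                Yw,
                tau,
                prior=prior_pairs,
                restarts=restarts,
                rng=rng,
                transform_x=model.transform_x,
                transform_y=model.transform_y,
            )
        except FitError:
            n_failed += 1
            continue
        permuted.append(pair.divergence.value)
    permuted = np.asarray(permuted)
    if permuted.size == 0:
        raise FitError("every permutation refit failed")
    pvalue = float(np.sum(permuted > observed)) / permuted.size
    return PermutationResult(
        pair_index=pair_index,
        observed=observed,
        permuted=permuted,
        pvalue=pvalue,
        n_permutations=n_permutations,
        seed=seed,
        n_failed=n_failed,
    )


def n_significant_pairs(
    X,
    Y,
    tau: float,
    alpha: float = 0.05,
    n_permutations: int = 100,
    seed=None,
    *,
    restarts: int = DEFAULT_RESTARTS,
    max_pairs: int | None = None,
):
    """Sequentially count canonical pairs with significant dependence.

    Pairs are fitted in order; after each, the permutation test is run and
    the procedure stops at the first pair whose p-value reaches ``alpha``.
    Returns ``(count, results)`` with the per-pair
    :class:`PermutationResult` list (including the first non-significant
    pair, if any).
    """
    if not 0 < alpha < 1:
        raise DomainError("alpha must lie in (0, 1)")
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    limit = min(X.shape[1] if X.ndim > 1 else 1, Y.shape[1] if Y.ndim > 1 else 1)
    if max_pairs is not None:
        limit = min(limit, max_pairs)
    rng = np.random.default_rng(seed)

    results: list[PermutationResult] = []
    count = 0
    model = None
    for i in range(1, limit + 1):
        model = fit(X, Y, tau, n_pairs=i, restarts=restarts, seed=rng)
        res = permutation_test(
            X,
            Y,
            tau,
            pair_index=i,
            n_permutations=n_permutations,
            seed=rng,
            model=model,
            restarts=restarts,
        )
        results.append(res)
        if res.pvalue >= alpha:
            break
        count += 1
    return count, results
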