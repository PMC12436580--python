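"""Marginal maximum likelihood (MML) estimation of the GRM by EM.

The marginal likelihood integrates each respondent's pattern likelihood
over the latent prior on a fixed rectangular quadrature grid.  The
E-step computes posterior node weights per respondent; the M-step
maximises the expected complete-data log-likelihood item by item
(bounded quasi-Newton on an ordered-increment parametrisation, so
intercept ordering is preserved by construction).  For multifactor
models the factor correlation matrix is updated from the posterior
second moment of theta, rescaled to unit diagonal (fixed-variance
identification), and the prior grid weights are refreshed each cycle.

Estimation is fully deterministic: slopes start at 1.0, intercepts at
the logits of the marginal cumulative category frequencies, Sigma at the
identity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logsumexp

from .grm import (
    PROB_FLOOR,
    ItemBank,
    LatentModel,
    QuadratureGrid,
    factor_assignment,
)

__all__ = [
    "FitResult",
    "fit_grm",
    "information_criteria",
    "count_free_params",
    "marginal_loglik",
]


def marginal_loglik(
    bank: ItemBank,
    latent: LatentModel,
    responses,
    *,
    points_per_dim: int = 21,
    bound: float = 6.0,
) -> float:
    """Marginal log-likelihood of complete response data under a fitted model.

    Evaluated on a caller-chosen rectangular grid, so models of
    different dimension can be compared on one common quadrature rather
    than on their estimation grids.
    """
    from .grm import category_prob_table

    X = np.asarray(responses, dtype=int)
    grid_latent = LatentModel(latent.dimension, latent.corr)
    grid = QuadratureGrid.build(grid_latent, points_per_dim=points_per_dim, bound=bound)
    logP = np.log(np.maximum(category_prob_table(bank, grid.nodes), PROB_FLOOR))
    LL = np.zeros((grid.n_nodes, X.shape[0]))
    for i in range(bank.n_items):
        LL += logP[:, i, X[:, i]]
    return float(logsumexp(LL + np.log(grid.weights)[:, None], axis=0).sum())


@dataclass
class FitResult:
    bank: ItemBank
    latent: LatentModel
    loglik: float
    n_free_params: int
    aic: float
    bic: float
    n_obs: int
    n_cycles: int
    converged: bool
    loglik_path: np.ndarray = field(default_factory=lambda: np.empty(0))

    def summary(self) -> dict:
        return {
            "dimension": self.latent.dimension,
            "loglik": self.loglik,
            "n_free_params": self.n_free_params,
            "AIC": self.aic,
            "BIC": self.bic,
            "n_obs": self.n_obs,
            "n_cycles": self.n_cycles,
            "converged": self.converged,
            "corr": self.latent.corr.tolist(),
        }


def information_criteria(loglik: float, n_free_params: int, n_obs: int) -> tuple[float, float]:
    """AIC = -2 ll + 2p; BIC = -2 ll + p log N."""
    if n_obs < 1:
        raise ValueError("n_obs must be >= 1")
    return (-2.0 * loglik + 2.0 * n_free_params, -2.0 * loglik + n_free_params * np.log(n_obs))


def count_free_params(n_items: int, n_categories: int, dimension: int) -> int:
    """Loaded slopes + intercepts + free factor correlations."""
    return n_items + n_items * (n_categories - 1) + dimension * (dimension - 1) // 2


#: Estimation grids; scoring uses the lighter grm.DEFAULT_QUAD_POINTS.
#: The D=3 grid must resolve the prior's correlation ridge: with factor
#: correlations near 0.85 the conditional SD is ~0.5, and coarser grids
#: bias the Sigma update toward a degenerate corr -> 1 solution.
_ESTIMATION_QUAD_POINTS = {1: 61, 2: 31, 3: 25}


def _item_objective(params, t_vals, R, n_cat):
    """Negative expected complete-data log-likelihood and gradient for one item.

    params = (a, d1, g2, ..., g_{K-1}); d_k = d1 - sum of gaps, enforcing
    the strict intercept ordering.  R is the (m, K) table of expected
    response counts at the m distinct loaded-factor node values t_vals.
    """
    a, d1 = params[0], params[1]
    gaps = params[2:]
    d = d1 - np.concatenate([[0.0], np.cumsum(gaps)])  # (K-1,) decreasing
    z = a * t_vals[:, None] + d  # (m, K-1)
    pstar = expit(z)
    w = pstar * (1.0 - pstar)
    padded = np.concatenate(
        [np.ones((len(t_vals), 1)), pstar, np.zeros((len(t_vals), 1))], axis=1
    )
    P = np.maximum(-np.diff(padded, axis=1), PROB_FLOOR)  # (m, K)
    f = -(R * np.log(P)).sum()

    # dP_k/dz_j is +w_j for k = j, -w_j for k = j-1 (boundary j sits
    # between categories j-1 and j); chain through a, d1 and the gaps.
    ratio = R / P  # (m, K)
    dz = w * (ratio[:, 1:] - ratio[:, :-1])  # (m, K-1): df/dz_j
    grad_a = -(dz * t_vals[:, None]).sum()
    grad_d = -dz.sum(axis=0)  # df/dd_j
    grad_d1 = grad_d.sum()
    # gap j (j >= 2) enters d_j..d_{K-1} with coefficient -1
    grad_gaps = np.array([-grad_d[j:].sum() for j in range(1, len(grad_d))])
    return f, np.concatenate([[grad_a, grad_d1], grad_gaps])


def _fit_item(R, t_vals, a0, d0, n_cat):
    gaps0 = np.maximum(-np.diff(d0), 1e-3)
    x0 = np.concatenate([[max(a0, 1e-3)], [d0[0]], gaps0])
    bounds = [(1e-4, 100.0), (-50.0, 50.0)] + [(1e-6, 50.0)] * (n_cat - 2)
    res = minimize(
        _item_objective,
        x0,
        args=(t_vals, R, n_cat),
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 200, "ftol": 1e-12, "gtol": 1e-10},
    )
    a = res.x[0]
    d = res.x[1] - np.concatenate([[0.0], np.cumsum(res.x[2:])])
    return a, d


def _initial_intercepts(responses: np.ndarray, n_cat: int) -> np.ndarray:
    """Logits of marginal cumulative frequencies P(X >= k), made strictly ordered."""
    n_items = responses.shape[1]
    d0 = np.zeros((n_items, n_cat - 1))
    for i in range(n_items):
        for k in range(1, n_cat):
            p = np.clip((responses[:, i] >= k).mean(), 1e-3, 1 - 1e-3)
            d0[i, k - 1] = np.log(p / (1 - p))
        # enforce strict ordering in degenerate samples
        for k in range(1, n_cat - 1):
            if d0[i, k] >= d0[i, k - 1]:
                d0[i, k] = d0[i, k - 1] - 0.1
    return d0


def _item_prob_table(a_i: float, d_i: np.ndarray, axis: np.ndarray) -> np.ndarray:
    """(m, K) category probabilities of one item along its factor axis."""
    pstar = expit(a_i * axis[:, None] + d_i)
    padded = np.concatenate(
        [np.ones((len(axis), 1)), pstar, np.zeros((len(axis), 1))], axis=1
    )
    return np.maximum(-np.diff(padded, axis=1), PROB_FLOOR)


def _factor_tables(X, a, d, axis, factors, dimension):
    """A[f]: (m, N) product over factor-f items of P(x_ni | axis value)."""
    m, N = len(axis), X.shape[0]
    A = [np.ones((m, N)) for _ in range(dimension)]
    for i in range(X.shape[1]):
        P = _item_prob_table(a[i], d[i], axis)
        A[factors[i]] *= P[:, X[:, i]]
    return A


def _estep(prior_nd, A, axis):
    """Factorised E-step on the tensor-product grid.

    Returns the per-respondent marginal likelihood Z, the unnormalised
    axis marginals of the posterior per factor, and (for D > 1) the
    posterior second-moment matrix averaged over respondents.
    """
    D = len(A)
    if D == 1:
        joint = prior_nd[:, None] * A[0]
        Z = joint.sum(axis=0)
        return Z, [joint], None
    if D == 2:
        T = prior_nd
        marg0 = A[0] * (T @ A[1])
        marg1 = A[1] * (T.T @ A[0])
        Z = marg0.sum(axis=0)
        w0 = axis[:, None] * A[0]
        w1 = axis[:, None] * A[1]
        s01 = (w0 * (T @ w1)).sum(axis=0)
        marg = [marg0, marg1]
    else:
        P = prior_nd
        marg0 = A[0] * np.einsum("abc,bn,cn->an", P, A[1], A[2], optimize=True)
        marg1 = A[1] * np.einsum("abc,an,cn->bn", P, A[0], A[2], optimize=True)
        marg2 = A[2] * np.einsum("abc,an,bn->cn", P, A[0], A[1], optimize=True)
        Z = marg0.sum(axis=0)
        w = [axis[:, None] * Af for Af in A]
        s01 = np.einsum("abc,an,bn,cn->n", P, w[0], w[1], A[2], optimize=True)
        s02 = np.einsum("abc,an,bn,cn->n", P, w[0], A[1], w[2], optimize=True)
        s12 = np.einsum("abc,an,bn,cn->n", P, A[0], w[1], w[2], optimize=True)
        marg = [marg0, marg1, marg2]
    # second moments: diagonal from axis marginals, off-diagonal from the
    # pair contractions, each normalised per respondent then averaged
    N = Z.shape[0]
    S = np.empty((D, D))
    for f in range(D):
        S[f, f] = ((axis**2)[:, None] * marg[f] / Z).sum() / N
    if D == 2:
        S[0, 1] = S[1, 0] = (s01 / Z).sum() / N
    else:
        S[0, 1] = S[1, 0] = (s01 / Z).sum() / N
        S[0, 2] = S[2, 0] = (s02 / Z).sum() / N
        S[1, 2] = S[2, 1] = (s12 / Z).sum() / N
    return Z, marg, S


def fit_grm(
    responses,
    dimension: int = 1,
    *,
    points_per_dim: int | None = None,
    bound: float = 6.0,
    tol: float = 1e-4,
    max_cycles: int = 500,
    min_rows: int = 200,
    n_categories: int | None = None,
    on_empty_category: str = "fail",
) -> FitResult:
    """Fit a simple-structure GRM of the given dimension by MML-EM.

    Parameters
    ----------
    responses
        (N, n_items) integer array (or DataFrame) of complete responses
        in 0..K-1.
    dimension
        1, 2 or 3; factor membership follows the conventional subscale
        assignment.
    on_empty_category
        "fail" raises when an item never shows some category; "collapse"
        merges the empty category into its lower neighbour for
        estimation and pins the re-inserted boundary just below it.
    """
    X = np.asarray(responses, dtype=int)
    if X.ndim != 2:
        raise ValueError("responses must be a 2-D table")
    N, n_items = X.shape
    if N < min_rows:
        raise ValueError(f"need at least {min_rows} rows, got {N}")
    n_cat = n_categories if n_categories is not None else int(X.max()) + 1
    if X.max() > n_cat - 1:
        raise ValueError("responses exceed the stated number of categories")
    if X.min() < 0:
        raise ValueError("negative response codes")

    # unobserved categories: either refuse, or let the bounded M-step pin
    # the empty category's probability near zero (soft collapse)
    for i in range(n_items):
        counts = np.bincount(X[:, i], minlength=n_cat)
        missing = np.where(counts == 0)[0]
        if missing.size:
            if on_empty_category == "fail":
                raise ValueError(
                    f"item {i} never shows category {missing[0]}; "
                    "set on_empty_category='collapse' to absorb it"
                )
            warnings.warn(
                f"item {i}: categories {missing.tolist()} unobserved; their "
                "fitted probabilities will be driven toward zero",
                stacklevel=2,
            )
        if np.count_nonzero(counts) < 2:
            raise ValueError(f"item {i} shows fewer than 2 observed categories")

    factors = factor_assignment(dimension, n_items)
    latent = LatentModel(dimension)
    if points_per_dim is None:
        points_per_dim = _ESTIMATION_QUAD_POINTS[dimension]
    grid = QuadratureGrid.build(latent, points_per_dim=points_per_dim, bound=bound)
    m = grid.points_per_dim
    axis = np.linspace(-bound, bound, m)

    a = np.ones(n_items)
    d = _initial_intercepts(X, n_cat)
    corr = np.eye(dimension)

    loglik_path = []
    converged = False
    cycle = 0
    onehot = [np.equal.outer(X[:, i], np.arange(n_cat)).astype(float) for i in range(n_items)]

    for cycle in range(1, max_cycles + 1):
        # E-step, factorised over the tensor-product grid
        A = _factor_tables(X, a, d, axis, factors, dimension)
        prior_nd = grid.weights.reshape((m,) * dimension)
        Z, marg, S = _estep(prior_nd, A, axis)
        loglik = float(np.log(Z).sum())
        loglik_path.append(loglik)

        # M-step: per-item ordered-logit refit on expected counts
        a_new = np.empty_like(a)
        d_new = np.empty_like(d)
        for i in range(n_items):
            R = (marg[factors[i]] / Z) @ onehot[i]  # (m, K)
            a_new[i], d_new[i] = _fit_item(R, axis, a[i], d[i], n_cat)

        # Sigma update: posterior expected second moment, unit-diagonal rescale
        if dimension > 1:
            scale = np.sqrt(np.diag(S))
            corr_new = S / np.outer(scale, scale)
            np.fill_diagonal(corr_new, 1.0)
            # near-unidimensional data can push correlations to 1;
            # keep Sigma safely positive definite
            corr_new = np.clip(corr_new, -0.995, 0.995)
            np.fill_diagonal(corr_new, 1.0)
            evals, evecs = np.linalg.eigh(corr_new)
            if evals.min() < 1e-5:
                evals = np.maximum(evals, 1e-5)
                corr_new = evecs @ np.diag(evals) @ evecs.T
                s = np.sqrt(np.diag(corr_new))
                corr_new = corr_new / np.outer(s, s)
        else:
            corr_new = corr

        delta = max(
            np.abs(a_new - a).max(),
            np.abs(d_new - d).max(),
            np.abs(corr_new - corr).max(),
        )
        a, d, corr = a_new, d_new, corr_new
        if dimension > 1:
            latent = LatentModel(dimension, corr)
            grid.reweight(latent)
        if delta < tol:
            converged = True
            break

    if not converged:
        warnings.warn(f"EM did not converge in {max_cycles} cycles", stacklevel=2)

    slopes = np.zeros((n_items, dimension))
    slopes[np.arange(n_items), factors] = a
    bank = ItemBank(slopes, d, factors)
    latent = LatentModel(dimension, corr)
    p = count_free_params(n_items, n_cat, dimension)
    # final marginal log-likelihood at the returned parameters
    grid.reweight(latent)
    A = _factor_tables(X, a, d, axis, factors, dimension)
    Z, _, _ = _estep(grid.weights.reshape((m,) * dimension), A, axis)
    loglik = float(np.log(Z).sum())
    loglik_path.append(loglik)
    aic, bic = information_criteria(loglik, p, N)
    return FitResult(
        bank=bank,
        latent=latent,
        loglik=loglik,
        n_free_params=p,
        aic=aic,
        bic=bic,
        n_obs=N,
        n_cycles=cycle,
        converged=converged,
        loglik_path=np.array(loglik_path),
    )
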