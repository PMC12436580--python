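"""Latent-trait scoring: EAP estimation, shrinkage correction, expected totals.

EAP (expected a posteriori) scores are posterior means of theta under the
multivariate-normal prior, computed by quadrature on a rectangular grid.
Because EAP estimates shrink toward the prior mean, an empirical-reliability
correction (divide each dimension by the square root of its marginal
reliability) can be applied cohort-wide to restore unit variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .grm import ItemBank, LatentModel, QuadratureGrid, category_prob_table, response_loglik

__all__ = [
    "TraitEstimate",
    "eap_score",
    "posterior_weights",
    "empirical_reliability",
    "empirical_reliability_and_correct",
    "expected_total_score",
]


@dataclass
class TraitEstimate:
    """EAP point estimate with posterior SDs and optional corrected variant."""

    theta_hat: np.ndarray
    posterior_sd: np.ndarray
    n_items_used: int
    corrected_theta: np.ndarray | None = None


def posterior_weights(bank: ItemBank, responses, grid: QuadratureGrid) -> np.ndarray:
    """Normalized posterior mass over grid nodes for one response pattern."""
    ll = response_loglik(bank, responses, grid.nodes)
    logpost = ll + np.log(grid.weights)
    logpost -= logpost.max()
    w = np.exp(logpost)
    return w / w.sum()


def eap_score(
    bank: ItemBank,
    latent: LatentModel,
    responses,
    grid: QuadratureGrid | None = None,
) -> TraitEstimate:
    """EAP trait estimate and posterior SD for one response pattern.

    An empty pattern returns the prior mean (zero) and prior SDs.  All
    posterior mass piling up at the grid boundary triggers a warning
    (extreme respondent beyond the grid's range).
    """
    if grid is None:
        grid = QuadratureGrid.build(latent)
    w = posterior_weights(bank, responses, grid)
    theta_hat = w @ grid.nodes
    second = w @ (grid.nodes**2)
    var = np.maximum(second - theta_hat**2, 0.0)
    at_edge = np.abs(grid.nodes).max(axis=1) >= grid.bound
    if w[at_edge].sum() > 0.5:
        warnings.warn("posterior mass concentrated at grid boundary", stacklevel=2)
    responses = np.asarray(responses, dtype=float)
    n_used = int(np.sum(~np.isnan(responses) & (responses >= 0)))
    return TraitEstimate(theta_hat, np.sqrt(var), n_used)


def empirical_reliability(theta_hats: np.ndarray, posterior_sds: np.ndarray) -> np.ndarray:
    """Marginal empirical reliability per dimension.

    rho_d = Var(theta_hat_d) / (Var(theta_hat_d) + mean(SE_d^2)): the share
    of total (signal + error) variance captured by the point estimates.
    """
    theta_hats = np.atleast_2d(theta_hats)
    posterior_sds = np.atleast_2d(posterior_sds)
    if theta_hats.shape[0] < 2:
        raise ValueError("reliability needs at least two respondents")
    var = theta_hats.var(axis=0)
    mse = (posterior_sds**2).mean(axis=0)
    if np.any(var + mse == 0):
        raise ValueError("zero total variance; reliability undefined")
    return var / (var + mse)


def empirical_reliability_and_correct(
    estimates: list[TraitEstimate],
) -> tuple[np.ndarray, list[TraitEstimate]]:
    """Shrinkage-correct a cohort of EAP estimates.

    Divides each dimension of every estimate by sqrt(rho_d), so the
    corrected estimates have variance Var(theta_hat)/rho ~ the prior
    variance.  Degenerate cohorts with zero estimate variance raise.
    """
    th = np.array([e.theta_hat for e in estimates])
    sd = np.array([e.posterior_sd for e in estimates])
    rho = empirical_reliability(th, sd)
    if np.any(th.var(axis=0) == 0):
        raise ValueError("zero variance in estimates; correction undefined")
    factor = np.sqrt(rho)
    corrected = [
        TraitEstimate(e.theta_hat, e.posterior_sd, e.n_items_used, e.theta_hat / factor)
        for e in estimates
    ]
    return rho, corrected


def expected_total_score(bank: ItemBank, theta) -> float | np.ndarray:
    """Model-implied expected sum score T(theta) = sum_i sum_k k P_{i,k}(theta).

    Maps a latent estimate back to the instrument's raw scale (0-30 for
    the 10-item EPDS); weakly increasing in each theta coordinate when
    slopes are nonnegative.  Vectorises over a batch of thetas.
    """
    theta = np.asarray(theta, dtype=float)
    scalar = theta.ndim <= 1
    thetas = np.atleast_2d(theta)
    probs = category_prob_table(bank, thetas)  # (N, n_items, K)
    k = np.arange(bank.n_categories)
    totals = (probs * k).sum(axis=(1, 2))
    return float(totals[0]) if scalar else totals
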