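"""Graded response model (GRM) primitives.

The GRM (Samejima) models an ordered K-category item response through
cumulative logistic curves in slope--intercept form,

    P*_k(theta) = logistic(a . theta + d_k),     k = 1..K-1,

with P*_0 = 1 and P*_K = 0; the probability of responding in category k
is the difference of adjacent cumulative curves, P_k = P*_k - P*_{k+1}.
No 1.7 scaling constant is used.  For unidimensional reporting the
threshold parametrisation is b_k = -d_k / a.

Multidimensional models here are *simple structure* (between-item
multidimensionality): each item loads on exactly one latent factor, so
its slope vector has a single nonzero entry.  The latent trait follows a
multivariate normal prior with zero mean, unit variances and a free
correlation matrix.

This module provides the item bank / latent model / quadrature-grid
containers and the three kernels everything else is built on: category
probabilities, Fisher information matrices, and response pattern
log-likelihoods.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from scipy.stats import multivariate_normal

__all__ = [
    "PROB_FLOOR",
    "ItemBank",
    "LatentModel",
    "QuadratureGrid",
    "factor_assignment",
    "item_response_probs",
    "item_information",
    "information_trace_profile",
    "response_loglik",
    "category_prob_table",
]

#: Floor applied to category probabilities when dividing or taking logs,
#: so information and log-likelihoods stay finite at extreme theta.
PROB_FLOOR = 1e-10

#: Conventional EPDS subscale memberships, 0-based item indices.
#: One factor: all items.  Two factors: anhedonia-depression (items
#: 1, 2, 6-10) and anxiety (items 3-5).  Three factors: anhedonia
#: (items 1-2), anxiety (items 3-5), depression (items 6-10).
_ASSIGNMENTS = {
    1: np.zeros(10, dtype=int),
    2: np.array([0, 0, 1, 1, 1, 0, 0, 0, 0, 0]),
    3: np.array([0, 0, 1, 1, 1, 2, 2, 2, 2, 2]),
}

FACTOR_NAMES = {
    1: ("depression-anxiety",),
    2: ("anhedonia-depression", "anxiety"),
    3: ("anhedonia", "anxiety", "depression"),
}


def factor_assignment(dimension: int, n_items: int = 10) -> np.ndarray:
    """Item -> factor map for the supported simple structures.

    The 10-item assignments follow the conventional EPDS subscales; for
    other bank sizes only the unidimensional map is defined.
    """
    if dimension == 1:
        return np.zeros(n_items, dtype=int)
    if n_items != 10 or dimension not in _ASSIGNMENTS:
        raise ValueError(
            f"no standard {dimension}-factor assignment for {n_items} items"
        )
    return _ASSIGNMENTS[dimension].copy()


@dataclass
class ItemBank:
    """Calibrated item parameters for a simple-structure GRM.

    Parameters
    ----------
    slopes
        ``(n_items, D)`` array; exactly one strictly positive entry per
        row when ``D > 1`` (zero-slope items are tolerated as degenerate
        but valid).
    intercepts
        ``(n_items, K-1)`` array ``d_{i,k}``, strictly decreasing in k
        for every item.
    factor_index
        Which factor each item loads on, length ``n_items``.
    item_labels
        Human-facing labels (EPDS item numbers 1..10 by default).
    si_item
        0-based index of the suicidal-ideation item (EPDS item 10).
    """

    slopes: np.ndarray
    intercepts: np.ndarray
    factor_index: np.ndarray
    item_labels: list[str] = field(default_factory=list)
    si_item: int = 9

    def __post_init__(self) -> None:
        self.slopes = np.atleast_2d(np.asarray(self.slopes, dtype=float))
        self.intercepts = np.atleast_2d(np.asarray(self.intercepts, dtype=float))
        self.factor_index = np.asarray(self.factor_index, dtype=int)
        if self.slopes.shape[0] != self.intercepts.shape[0]:
            raise ValueError("slopes and intercepts disagree on item count")
        if self.factor_index.shape != (self.n_items,):
            raise ValueError("factor_index length must equal item count")
        if not self.item_labels:
            self.item_labels = [str(i + 1) for i in range(self.n_items)]
        if np.any(np.diff(self.intercepts, axis=1) >= 0):
            bad = np.where(np.any(np.diff(self.intercepts, axis=1) >= 0, axis=1))[0]
            raise ValueError(
                f"intercepts must be strictly decreasing; violated by items {bad.tolist()}"
            )
        loaded = self.slopes[np.arange(self.n_items), self.factor_index]
        if np.any(loaded < 0):
            raise ValueError("slope on the loaded factor must be nonnegative")
        off = self.slopes.copy()
        off[np.arange(self.n_items), self.factor_index] = 0.0
        if np.any(off != 0):
            raise ValueError("simple structure requires one nonzero slope per item")
        if not 0 <= self.si_item < self.n_items:
            raise ValueError("si_item out of range")

    @property
    def n_items(self) -> int:
        return self.slopes.shape[0]

    @property
    def n_categories(self) -> int:
        return self.intercepts.shape[1] + 1

    @property
    def dimension(self) -> int:
        return self.slopes.shape[1]

    @property
    def loaded_slopes(self) -> np.ndarray:
        """The (single) nonzero slope of each item, length ``n_items``."""
        return self.slopes[np.arange(self.n_items), self.factor_index]

    @property
    def max_score(self) -> int:
        return self.n_items * (self.n_categories - 1)

    def thresholds(self) -> np.ndarray:
        """Difficulty parametrisation ``b_{i,k} = -d_{i,k} / a_i``.

        Only meaningful for items with a strictly positive slope.
        """
        a = self.loaded_slopes
        with np.errstate(divide="ignore", invalid="ignore"):
            return -self.intercepts / a[:, None]

    @classmethod
    def from_thresholds(
        cls,
        loaded_slopes: np.ndarray,
        thresholds: np.ndarray,
        factor_index: np.ndarray | None = None,
        dimension: int | None = None,
        si_item: int = 9,
    ) -> "ItemBank":
        """Build a bank from loaded slopes and increasing thresholds b_{i,k}."""
        a = np.asarray(loaded_slopes, dtype=float)
        b = np.atleast_2d(np.asarray(thresholds, dtype=float))
        n_items = a.shape[0]
        if factor_index is None:
            dimension = dimension or 1
            factor_index = factor_assignment(dimension, n_items)
        factor_index = np.asarray(factor_index, dtype=int)
        if dimension is None:
            dimension = int(factor_index.max()) + 1
        slopes = np.zeros((n_items, dimension))
        slopes[np.arange(n_items), factor_index] = a
        return cls(slopes, -a[:, None] * b, factor_index, si_item=si_item)

    # ---- serialization ----------------------------------------------------

    def to_frame(self):
        import pandas as pd

        cols = {
            "item": self.item_labels,
            "factor": self.factor_index,
            "slope": self.loaded_slopes,
        }
        for k in range(self.n_categories - 1):
            cols[f"d{k + 1}"] = self.intercepts[:, k]
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        # repr-precision floats so CSV -> bank -> CSV is bit-exact
        self.to_frame().to_csv(path, index=False, float_format=None)

    @classmethod
    def from_csv(cls, path) -> "ItemBank":
        import pandas as pd

        df = pd.read_csv(path, float_precision="round_trip")
        dcols = sorted(c for c in df.columns if c.startswith("d") and c[1:].isdigit())
        factor_index = df["factor"].to_numpy(dtype=int)
        dimension = int(factor_index.max()) + 1
        n_items = len(df)
        slopes = np.zeros((n_items, dimension))
        slopes[np.arange(n_items), factor_index] = df["slope"].to_numpy(dtype=float)
        bank = cls(
            slopes,
            df[dcols].to_numpy(dtype=float),
            factor_index,
            item_labels=[str(x) for x in df["item"]],
        )
        return bank

    def to_json(self, path=None) -> str:
        payload = {
            "items": [
                {
                    "item": self.item_labels[i],
                    "factor": int(self.factor_index[i]),
                    "slope": float(self.loaded_slopes[i]),
                    "intercepts": self.intercepts[i].tolist(),
                }
                for i in range(self.n_items)
            ],
            "dimension": self.dimension,
            "si_item": self.si_item,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "ItemBank":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        items = payload["items"]
        n_items = len(items)
        dimension = payload["dimension"]
        factor_index = np.array([it["factor"] for it in items])
        slopes = np.zeros((n_items, dimension))
        slopes[np.arange(n_items), factor_index] = [it["slope"] for it in items]
        return cls(
            slopes,
            np.array([it["intercepts"] for it in items]),
            factor_index,
            item_labels=[str(it["item"]) for it in items],
            si_item=payload.get("si_item", 9),
        )


@dataclass
class LatentModel:
    """Zero-mean multivariate-normal latent trait with correlation Sigma."""

    dimension: int
    corr: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.corr is None:
            self.corr = np.eye(self.dimension)
        self.corr = np.asarray(self.corr, dtype=float)
        if self.corr.shape != (self.dimension, self.dimension):
            raise ValueError("correlation matrix shape mismatch")
        if not np.allclose(self.corr, self.corr.T):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.corr), 1.0):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.any(np.linalg.eigvalsh(self.corr) <= 0):
            raise ValueError("correlation matrix must be positive definite")


#: Default points per dimension for the rectangular quadrature grid.
DEFAULT_QUAD_POINTS = {1: 61, 2: 31, 3: 15}


@dataclass
class QuadratureGrid:
    """Rectangular quadrature grid with normal-prior weights.

    ``nodes`` is ``(Q, D)``; ``weights`` is the multivariate normal prior
    density evaluated at the nodes and renormalised to sum to one, so
    posterior expectations are plain weighted sums.
    """

    nodes: np.ndarray
    weights: np.ndarray
    points_per_dim: int
    bound: float

    @classmethod
    def build(
        cls,
        latent: LatentModel,
        points_per_dim: int | None = None,
        bound: float = 6.0,
    ) -> "QuadratureGrid":
        D = latent.dimension
        if points_per_dim is None:
            points_per_dim = DEFAULT_QUAD_POINTS.get(D, 15)
        axis = np.linspace(-bound, bound, points_per_dim)
        mesh = np.meshgrid(*([axis] * D), indexing="ij")
        nodes = np.column_stack([m.ravel() for m in mesh])
        grid = cls(nodes, np.empty(nodes.shape[0]), points_per_dim, bound)
        grid.reweight(latent)
        return grid

    def reweight(self, latent: LatentModel) -> None:
        """Recompute prior weights for an updated correlation matrix."""
        dens = multivariate_normal(
            mean=np.zeros(latent.dimension), cov=latent.corr
        ).pdf(self.nodes)
        dens = np.atleast_1d(dens)
        self.weights = dens / dens.sum()

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]


# ---- kernels ---------------------------------------------------------------


def _check_theta(bank: ItemBank, theta) -> np.ndarray:
    theta = np.asarray(theta, dtype=float)
    if theta.ndim == 0:
        theta = theta[None]
    if theta.shape[-1] != bank.dimension:
        raise ValueError(
            f"theta dimension {theta.shape[-1]} does not match bank dimension {bank.dimension}"
        )
    if not np.all(np.isfinite(theta)):
        raise ValueError("theta must be finite")
    return theta


def item_response_probs(
    bank: ItemBank, item: int, theta
) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative and category probabilities of one item at ``theta``.

    Returns
    -------
    cumulative
        ``P*_k`` for k = 1..K-1 (strictly decreasing in k).
    category
        ``P_k`` for k = 0..K-1; nonnegative, sums to 1.
    """
    theta = _check_theta(bank, theta)
    z = theta @ bank.slopes[item]  # scalar (or batch) linear predictor
    cumulative = expit(z[..., None] + bank.intercepts[item])
    padded = np.concatenate(
        [
            np.ones_like(cumulative[..., :1]),
            cumulative,
            np.zeros_like(cumulative[..., :1]),
        ],
        axis=-1,
    )
    category = -np.diff(padded, axis=-1)
    return cumulative, category


def _info_scalar(cumulative: np.ndarray) -> np.ndarray:
    """Sum_k (w_k - w_{k+1})^2 / P_k with w the logistic density at each curve."""
    w = cumulative * (1.0 - cumulative)
    w = np.concatenate(
        [np.zeros_like(w[..., :1]), w, np.zeros_like(w[..., :1])], axis=-1
    )
    padded = np.concatenate(
        [
            np.ones_like(cumulative[..., :1]),
            cumulative,
            np.zeros_like(cumulative[..., :1]),
        ],
        axis=-1,
    )
    category = np.maximum(-np.diff(padded, axis=-1), PROB_FLOOR)
    return (np.diff(w, axis=-1) ** 2 / category).sum(axis=-1)


def item_information(bank: ItemBank, item: int, theta) -> np.ndarray:
    """Expected (Fisher) information matrix of one item at ``theta``.

    ``I_i(theta) = sum_k (grad P_k)(grad P_k)^T / P_k``; under simple
    structure this is rank <= 1 with its only nonzero diagonal entry on
    the loaded factor.
    """
    theta = _check_theta(bank, theta)
    cumulative, _ = item_response_probs(bank, item, theta)
    scal = _info_scalar(cumulative)
    a = bank.slopes[item]
    return np.multiply.outer(scal, np.outer(a, a)) if np.ndim(scal) else scal * np.outer(a, a)


def information_trace_profile(bank: ItemBank, thetas) -> np.ndarray:
    """trace(I_i(theta)) for every item at a batch of thetas.

    Parameters
    ----------
    thetas : (..., D) array

    Returns
    -------
    (..., n_items) array of information traces.
    """
    thetas = _check_theta(bank, thetas)
    z = thetas @ bank.slopes.T  # (..., n_items)
    cumulative = expit(z[..., None] + bank.intercepts)  # (..., n_items, K-1)
    scal = _info_scalar(cumulative)
    return scal * (bank.slopes**2).sum(axis=1)


def category_prob_table(bank: ItemBank, thetas) -> np.ndarray:
    """Category probabilities for all items at a batch of thetas.

    Returns a ``(..., n_items, K)`` array; the workhorse precompute for
    EM estimation and the adaptive-testing engine.
    """
    thetas = _check_theta(bank, thetas)
    z = thetas @ bank.slopes.T
    cumulative = expit(z[..., None] + bank.intercepts)
    padded = np.concatenate(
        [
            np.ones_like(cumulative[..., :1]),
            cumulative,
            np.zeros_like(cumulative[..., :1]),
        ],
        axis=-1,
    )
    return -np.diff(padded, axis=-1)


def response_loglik(bank: ItemBank, responses, theta) -> float | np.ndarray:
    """Log-likelihood of a (possibly partial) response pattern at ``theta``.

    ``responses`` has length ``n_items`` with entries in 0..K-1 or a
    negative value / NaN for items not answered.  Vectorises over a
    batch of thetas.
    """
    responses = np.asarray(responses, dtype=float)
    if responses.shape[-1] != bank.n_items:
        raise ValueError("response pattern length must equal bank size")
    answered = np.where(~np.isnan(responses) & (responses >= 0))[0]
    resp = responses[answered].astype(int)
    if np.any((responses[answered] % 1) != 0):
        raise ValueError("responses must be integer categories")
    if np.any(resp > bank.n_categories - 1):
        bad = answered[np.where(resp > bank.n_categories - 1)[0][0]]
        raise ValueError(f"response out of range at item index {bad}")
    theta = _check_theta(bank, theta)
    scalar = theta.ndim == 1
    thetas = theta[None, :] if scalar else theta
    if answered.size == 0:
        out = np.zeros(thetas.shape[0])
        return float(out[0]) if scalar else out
    probs = category_prob_table(bank, thetas)[:, answered, resp]
    out = np.log(np.maximum(probs, PROB_FLOOR)).sum(axis=-1)
    return float(out[0]) if scalar else out
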