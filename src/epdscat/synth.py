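"""Synthetic cohorts emulating a routine postpartum depression screen.

Generates item banks and patient-level response tables with the
statistical structure of a large hospital screening program: 10
polytomous items with 4 ordered categories, one/two/three-factor simple
structure, correlated latent traits, demographic group labels with
realistic proportions, and a marginal positive-screen rate (total >= 8
or suicidal-ideation endorsement) near 12%.

Latent severity is drawn from a multivariate normal with unit variances
(optionally shifted per demographic group; the default shifts are zero,
a "fairness null" in which every group shares one generating process).
Responses are drawn from the graded response model: P(X_i >= k) =
logistic(a_i theta + d_ik), inverted by a single uniform draw per item.

All randomness flows through one ``numpy.random.default_rng`` (PCG64)
seeded from the spec, so a fixed seed reproduces the cohort exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import truncnorm

from .grm import ItemBank, LatentModel, factor_assignment

__all__ = [
    "CohortSpec",
    "generate_item_bank",
    "generate_cohort",
    "DEFAULT_GROUP_PROPORTIONS",
    "default_corr",
]

#: Demographic mix of the emulated screening population.
DEFAULT_GROUP_PROPORTIONS = {
    "White": 0.54,
    "AAPI": 0.12,
    "Other": 0.12,
    "Hispanic White": 0.10,
    "Black": 0.07,
    "Multiracial": 0.04,
    "Unknown": 0.01,
}

#: Discrimination range for generated items.  Screening-scale items are
#: steep: each asks almost directly about the latent symptom.
DEFAULT_SLOPE_RANGE = (1.8, 3.0)
#: First threshold b1 (severity at which category >= 1 becomes even
#: odds) and spacing of the higher thresholds.  Together with the slope
#: range these put the marginal positive-screen rate (total >= 8 or SI
#: endorsed) near 11-12% and keep low-severity respondents in the flat,
#: low-information region of the curves, so the adaptive test stops
#: after about 5 items for a typical patient.
DEFAULT_FIRST_THRESHOLD_RANGE = (0.85, 1.45)
DEFAULT_GAP_RANGE = (0.6, 1.0)
#: The suicidal-ideation item (item 10) is endorsed far more rarely than
#: the other symptoms; its first threshold sits much higher, giving an
#: endorsement rate near 4%.
DEFAULT_SI_FIRST_THRESHOLD_RANGE = (2.0, 2.3)

#: Factor correlation used for multifactor cohorts: the subscales of a
#: short depression screen are strongly related.
DEFAULT_FACTOR_CORR = 0.85

AGE_MEAN, AGE_SD, AGE_RANGE = 34.26, 4.89, (18.0, 54.0)


def default_corr(dimension: int, rho: float = DEFAULT_FACTOR_CORR) -> np.ndarray:
    corr = np.full((dimension, dimension), rho)
    np.fill_diagonal(corr, 1.0)
    return corr


@dataclass
class CohortSpec:
    """Recipe for one synthetic cohort.

    ``group_trait_shifts`` maps group label -> D-vector added to the
    latent mean; absent groups shift by zero.  ``seed`` fixes every
    random draw (bank generation uses its own seed argument).
    """

    n: int
    dimension: int = 1
    seed: int = 0
    group_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_PROPORTIONS)
    )
    group_trait_shifts: dict[str, np.ndarray] = field(default_factory=dict)
    corr: np.ndarray | None = None
    slope_range: tuple[float, float] = DEFAULT_SLOPE_RANGE
    first_threshold_range: tuple[float, float] = DEFAULT_FIRST_THRESHOLD_RANGE
    gap_range: tuple[float, float] = DEFAULT_GAP_RANGE
    si_first_threshold_range: tuple[float, float] = DEFAULT_SI_FIRST_THRESHOLD_RANGE
    with_age: bool = True
    keep_theta: bool = True

    def __post_init__(self) -> None:
        total = sum(self.group_proportions.values())
        if abs(total - 1.0) > 1e-8:
            raise ValueError(f"group proportions sum to {total}, not 1")
        if self.corr is None:
            self.corr = default_corr(self.dimension)

    @property
    def latent(self) -> LatentModel:
        return LatentModel(self.dimension, self.corr)


def generate_item_bank(
    dimension: int,
    *,
    slope_range: tuple[float, float] = DEFAULT_SLOPE_RANGE,
    first_threshold_range: tuple[float, float] = DEFAULT_FIRST_THRESHOLD_RANGE,
    gap_range: tuple[float, float] = DEFAULT_GAP_RANGE,
    si_first_threshold_range: tuple[float, float] | None = DEFAULT_SI_FIRST_THRESHOLD_RANGE,
    n_items: int = 10,
    n_categories: int = 4,
    seed: int | np.random.Generator = 0,
) -> ItemBank:
    """Random simple-structure bank with ordered thresholds.

    Slopes are uniform on ``slope_range``; the first threshold b1 is
    uniform on ``first_threshold_range`` and subsequent thresholds add
    uniform gaps from ``gap_range``, so ordering holds by construction.
    Factor membership follows the conventional subscale assignment.
    """
    if dimension not in (1, 2, 3):
        raise ValueError("dimension must be 1, 2 or 3")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    a = rng.uniform(*slope_range, size=n_items)
    b1 = rng.uniform(*first_threshold_range, size=n_items)
    if si_first_threshold_range is not None and n_items == 10:
        b1[9] = rng.uniform(*si_first_threshold_range)
    gaps = rng.uniform(*gap_range, size=(n_items, n_categories - 2))
    b = np.column_stack([b1, b1[:, None] + np.cumsum(gaps, axis=1)])
    return ItemBank.from_thresholds(
        a, b, factor_index=factor_assignment(dimension, n_items), dimension=dimension
    )


def generate_cohort(spec: CohortSpec, bank: ItemBank | None = None) -> pd.DataFrame:
    """Draw a patient-level response table from the GRM.

    Returns a DataFrame with columns ``item1..item10``, ``race``,
    optionally ``age``, and (when ``spec.keep_theta``) the hidden
    generating trait columns ``true_theta1..D`` for recovery testing.
    """
    rng = np.random.default_rng(spec.seed)
    if bank is None:
        bank = generate_item_bank(
            spec.dimension,
            slope_range=spec.slope_range,
            first_threshold_range=spec.first_threshold_range,
            gap_range=spec.gap_range,
            si_first_threshold_range=spec.si_first_threshold_range,
            seed=rng,
        )
    if bank.dimension != spec.dimension:
        raise ValueError("bank dimension does not match spec")
    n = spec.n
    labels = list(spec.group_proportions)
    probs = np.array([spec.group_proportions[g] for g in labels])
    race = rng.choice(labels, size=n, p=probs)

    theta = rng.multivariate_normal(
        np.zeros(spec.dimension), spec.corr, size=n, method="cholesky"
    )
    for g, shift in spec.group_trait_shifts.items():
        theta[race == g] += np.atleast_1d(np.asarray(shift, dtype=float))

    # invert the cumulative curves with one uniform per item:
    # X = #{k : u < P(X >= k)}
    z = theta @ bank.slopes.T  # (n, items)
    pstar = expit(z[..., None] + bank.intercepts)  # (n, items, K-1)
    u = rng.uniform(size=(n, bank.n_items, 1))
    responses = (u < pstar).sum(axis=2).astype(int)

    data = {f"item{i + 1}": responses[:, i] for i in range(bank.n_items)}
    data["race"] = race
    if spec.with_age:
        lo, hi = AGE_RANGE
        aa, bb = (lo - AGE_MEAN) / AGE_SD, (hi - AGE_MEAN) / AGE_SD
        data["age"] = np.round(
            truncnorm.rvs(aa, bb, loc=AGE_MEAN, scale=AGE_SD, size=n, random_state=rng),
            1,
        )
    df = pd.DataFrame(data)
    if spec.keep_theta:
        for d in range(spec.dimension):
            df[f"true_theta{d + 1}"] = theta[:, d]
    return df
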