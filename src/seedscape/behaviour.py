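"""Per-species stochastic submodels: gut passage, perching, fruit consumption.

Gut passage time (GPT) is Gamma with a shape parameter shared across the bird
assemblage and a species-specific scale; the species scales derive from a
linear model of mean GPT on body mass, so that shape * scale equals the
predicted mean. Perch (residence) times are Gamma per species. Fruit
consumption per feeding bout is zero-inflated Poisson (ZIP), truncated at the
fruits actually available in the cell, and fruit species are assigned in
proportion to their current availability (no built-in preference): a
without-replacement, availability-weighted draw, i.e. multivariate
hypergeometric.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

__all__ = [
    "GutModel",
    "PerchModel",
    "ConsumptionModel",
    "SpeciesTraits",
    "gpt_scale_from_mass",
    "fit_gpt_regression",
    "draw_gpt",
    "draw_perch_time",
    "draw_consumption",
    "assign_fruit_species",
    "fit_gamma",
    "fit_zip",
]


@dataclass
class GutModel:
    """Gamma GPT model: common shape, species-specific scale (minutes)."""

    shape: float
    scale_by_species: dict[str, float]
    gpt_regression: tuple[float, float] | None = None  # (intercept, slope) in min, min/g

    def __post_init__(self) -> None:
        if self.shape <= 0:
            raise ValueError("Gamma shape must be positive")
        for sp, sc in self.scale_by_species.items():
            if sc <= 0:
                raise ValueError(f"Gamma scale for {sp} must be positive")

    def mean_gpt(self, species: str) -> float:
        return self.shape * self.scale_by_species[species]


@dataclass
class PerchModel:
    """Gamma residence-time model (minutes)."""

    shape: float
    scale: float

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.scale <= 0:
            raise ValueError("Gamma parameters must be positive")


@dataclass
class ConsumptionModel:
    """ZIP fruit consumption per feeding bout.

    ``pi_zero`` is the extra probability mass at zero (non-feeding bout);
    ``lam`` the Poisson rate given feeding. Marginal mean = (1 - pi_zero) * lam.
    """

    pi_zero: float
    lam: float

    def __post_init__(self) -> None:
        if not 0 <= self.pi_zero <= 1:
            raise ValueError("pi_zero must lie in [0, 1]")
        if self.lam <= 0:
            raise ValueError("lambda must be positive")

    @property
    def mean(self) -> float:
        return (1 - self.pi_zero) * self.lam


@dataclass
class SpeciesTraits:
    """Everything the simulator needs about one bird species."""

    name: str
    body_mass_g: float
    relative_abundance: float
    perch: PerchModel
    consumption: ConsumptionModel
    movement: "object"  # MovementParams; typed loosely to avoid a cycle
    gpt_shape: float
    gpt_scale: float
    seeds_per_fruit_by_plant: dict[str, int] = field(default_factory=dict)

    def seeds_per_fruit(self, plant: str) -> int:
        return int(self.seeds_per_fruit_by_plant.get(plant, 1))


def gpt_scale_from_mass(
    body_mass_g: float, intercept: float, slope: float, shape: float
) -> float:
    """Gamma scale so the mean GPT matches the body-mass regression.

    mean = intercept + slope * mass (minutes); scale = mean / shape.
    """
    mean = intercept + slope * body_mass_g
    if mean <= 0:
        raise ValueError(
            f"predicted mean GPT {mean:.3f} min is not positive "
            f"(mass {body_mass_g} g outside plausible range)"
        )
    return mean / shape


def fit_gpt_regression(masses, mean_gpts) -> tuple[float, float]:
    """Ordinary least squares of mean GPT (min) on body mass (g)."""
    import statsmodels.api as sm

    x = sm.add_constant(np.asarray(masses, dtype=float))
    res = sm.OLS(np.asarray(mean_gpts, dtype=float), x).fit()
    return float(res.params[0]), float(res.params[1])


def draw_gpt(gut: GutModel, species: str, rng: np.random.Generator, size=None):
    """Sample gut passage time(s) in minutes for one bird species."""
    if species not in gut.scale_by_species:
        raise KeyError(f"unknown species {species!r}")
    return rng.gamma(gut.shape, gut.scale_by_species[species], size=size)


def draw_perch_time(perch: PerchModel, rng: np.random.Generator) -> float:
    """Sample a residence time in minutes."""
    return float(rng.gamma(perch.shape, perch.scale))


def draw_consumption(
    cons: ConsumptionModel, available_total: int, rng: np.random.Generator
) -> int:
    """Fruits eaten in one bout: min(ZIP draw, fruits available in the cell)."""
    if available_total < 0:
        raise ValueError("available_total must be >= 0")
    if available_total == 0:
        return 0
    if rng.random() < cons.pi_zero:
        return 0
    return int(min(rng.poisson(cons.lam), available_total))


def assign_fruit_species(
    eaten: int, cell_fruits: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Split ``eaten`` fruits across species proportionally to availability.

    Equivalent to drawing fruits one at a time without replacement with
    probabilities re-weighted as counts drop; returns per-species counts.
    """
    cell_fruits = np.asarray(cell_fruits, dtype=np.int64)
    total = int(cell_fruits.sum())
    if eaten > total:
        raise ValueError(f"cannot eat {eaten} of {total} available fruits")
    if eaten == 0:
        return np.zeros_like(cell_fruits)
    return rng.multivariate_hypergeometric(cell_fruits, eaten)


# ---------------------------------------------------------------------------
# Fitting


def fit_gamma(samples) -> tuple[float, float, float]:
    """Gamma MLE (shape, scale, loglik) with location fixed at zero."""
    x = np.asarray(samples, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    if np.any(x <= 0):
        raise ValueError("Gamma samples must be positive")
    if np.allclose(x, x[0]):
        raise ValueError("degenerate sample: all values equal")
    shape, _, scale = stats.gamma.fit(x, floc=0)
    ll = float(stats.gamma.logpdf(x, shape, scale=scale).sum())
    return float(shape), float(scale), ll


def _zip_negloglik(theta: np.ndarray, counts: np.ndarray) -> float:
    logit_pi, log_lam = theta
    pi = special.expit(logit_pi)
    lam = np.exp(log_lam)
    n0 = np.count_nonzero(counts == 0)
    pos = counts[counts > 0]
    # P(0) = pi + (1-pi) e^-lam ; P(k>0) = (1-pi) Pois(k; lam)
    ll0 = n0 * np.log(pi + (1 - pi) * np.exp(-lam) + 1e-300)
    llp = pos.size * np.log1p(-pi) + float(stats.poisson.logpmf(pos, lam).sum())
    return -(ll0 + llp)


def fit_zip(counts) -> tuple[float, float, float]:
    """Constant-only ZIP maximum likelihood: (pi_zero, lambda, loglik).

    Optimized on (logit pi, log lambda) from a moment-based start; handles the
    pi -> 0 boundary (pure Poisson data) gracefully.
    """
    y = np.asarray(counts, dtype=np.int64)
    if y.size < 3:
        raise ValueError("need at least 3 counts")
    if np.any(y < 0):
        raise ValueError("counts must be non-negative")
    if np.all(y == 0):
        raise ValueError("degenerate sample: all counts zero")
    mean = y.mean()
    p0_hat = np.count_nonzero(y == 0) / y.size
    lam0 = max(mean, 0.1)
    pi0 = min(max(p0_hat - np.exp(-lam0), 1e-3), 0.98)
    best = None
    for start in ([special.logit(pi0), np.log(lam0)], [special.logit(0.5), np.log(lam0 * 2)]):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = optimize.minimize(
                _zip_negloglik,
                np.asarray(start),
                args=(y,),
                method="L-BFGS-B",
                bounds=[(-15, 15), (-10, 10)],
            )
        if best is None or res.fun < best.fun:
            best = res
    pi = float(special.expit(best.x[0]))
    lam = float(np.exp(best.x[1]))
    return pi, lam, -float(best.fun)
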