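"""Mass-driven re-weighting of the scalar objective.

Each cell re-weights its biomass vs. storage-metabolite objectives every step
from its own (non-metabolite) biomass: the cumulative probability ``z`` of a
random cell being at most this large scales the metabolite weight, the
remaining "expansion space" ``1 - z`` scales the biomass weight, and the
result is renormalized to sum to one.  Small cells therefore prioritize
growth, large cells storage-compound production.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm, truncnorm

from . import parameters
from .metabolic_core import ParetoFront

logger = logging.getLogger(__name__)

__all__ = [
    "MassDistribution",
    "ObjectiveWeights",
    "default_mean_mass",
    "cumulative_mass_probability",
    "shift_weights",
    "shift_weight_vector",
    "match_pareto_point",
]


def default_mean_mass(side_um: float = 10.0, density_kg_m3: float = 1029.0) -> float:
    """Mass in grams of a cubic cell of edge ``side_um`` at the given density.

    The packaged default (10 um cube at seawater density 1029 kg/m^3) is
    exactly 1.029e-9 g.
    """
    if side_um <= 0 or density_kg_m3 <= 0:
        raise ValueError("cell side and density must be positive")
    # kg/m^3 -> g/um^3 is a factor 1e-15
    return density_kg_m3 * side_um**3 * 1e-15


@dataclass(frozen=True)
class MassDistribution:
    """Normal cell-mass distribution N(mean, sd_fraction * mean)."""

    mean_mass: float = field(default_factory=lambda: parameters.get("cell", "mean_mass_g"))
    sd_fraction: float = field(default_factory=lambda: parameters.get("cell", "sd_fraction"))

    def __post_init__(self) -> None:
        if self.mean_mass <= 0:
            raise ValueError("mean mass must be positive")
        if not 0.0 < self.sd_fraction < 1.0:
            raise ValueError("sd_fraction must lie in (0, 1)")

    @property
    def sigma(self) -> float:
        return self.sd_fraction * self.mean_mass

    def sample_threshold(self, rng: np.random.Generator) -> float:
        """Draw a division threshold from the distribution truncated at 0.

        Negative masses are unphysical, so sampling truncates the normal at
        zero.
        """
        lo = -self.mean_mass / self.sigma
        return float(
            truncnorm.rvs(lo, np.inf, loc=self.mean_mass, scale=self.sigma,
                          random_state=rng)
        )


def cumulative_mass_probability(x: float, dist: MassDistribution) -> float:
    """Standard normal CDF of ``x`` under ``dist``: P(random cell mass <= x)."""
    return float(norm.cdf((x - dist.mean_mass) / dist.sigma))


@dataclass(frozen=True)
class ObjectiveWeights:
    """Normalized two-term objective weights (biomass, metabolite)."""

    w_b: float
    w_m: float

    def __post_init__(self) -> None:
        if self.w_b < 0 or self.w_m < 0:
            raise ValueError("objective weights must be nonnegative")
        total = self.w_b + self.w_m
        if total <= 0:
            raise ValueError("objective weights must not both be zero")
        object.__setattr__(self, "w_b", self.w_b / total)
        object.__setattr__(self, "w_m", self.w_m / total)

    def as_array(self) -> np.ndarray:
        return np.array([self.w_b, self.w_m])


def shift_weight_vector(base: np.ndarray, z: float) -> np.ndarray:
    """General k-objective shift: index 0 is biomass, the rest metabolites.

    The biomass weight is scaled by the expansion space ``1 - z``, every
    metabolite weight by ``z``, then the vector is normalized to sum to one.
    Falls back to the normalized base weights when every scaled weight is
    zero (z in {0, 1} with a zero opposing base weight).
    """
    base = np.asarray(base, dtype=float)
    if np.any(base < 0) or base.sum() <= 0:
        raise ValueError("base weights must be nonnegative and not all zero")
    scaled = base * z
    scaled[0] = base[0] * (1.0 - z)
    total = scaled.sum()
    if total <= 0:
        logger.warning(
            "degenerate weight shift (z=%s, base=%s); falling back to base weights",
            z, base,
        )
        return base / base.sum()
    return scaled / total


def shift_weights(
    base: ObjectiveWeights, x: float, dist: MassDistribution
) -> ObjectiveWeights:
    """Re-weight a cell's objective from its biomass ``x`` (grams)."""
    z = cumulative_mass_probability(x, dist)
    w = shift_weight_vector(np.array([base.w_b, base.w_m]), z)
    return ObjectiveWeights(w_b=float(w[0]), w_m=float(w[1]))


def match_pareto_point(
    front: ParetoFront, weights: ObjectiveWeights
) -> tuple[float, float, float, float]:
    """Select the front point whose weight vector is nearest the target.

    For a two-objective front the point's implied weights are ``(a, 1 - a)``,
    so minimizing Euclidean distance to ``(w_b, w_m)`` reduces to picking the
    ``a`` nearest ``w_b``; ties break toward larger ``a``.
    """
    if front.steps == 0:
        raise ValueError("cannot match against an empty Pareto front")
    d = np.abs(front.a - weights.w_b)
    # argmin on the reversed array prefers the largest a among exact ties
    i = front.steps - 1 - int(np.argmin(d[::-1]))
    return front.point(i)
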