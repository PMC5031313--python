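"""Cost parameters of the attributable-cost model.

Each disease i carries a mean annual direct medical cost C_i (USD per
patient per year) with an uncertainty specification, and the model carries
the malnutrition cost multiplier dMN: the proportional *excess* annual cost
of a malnourished patient relative to a non-malnourished patient with the
same disease (malnourished cost = (1 + dMN) x non-malnourished cost).  dMN
is a single global parameter by default, with optional per-disease
overrides.

Uncertainty specs come in two kinds, mirroring how cost parameters are
sourced from the literature:

* ``gamma`` — mean plus standard error; draws use method-of-moments gamma
  (shape = (mean/se)^2, scale = se^2/mean).
* ``uniform`` — draws on [ (1-pct) x mean, (1+pct) x mean ], default
  pct = 0.20 (bounds 20% away from the mean).

A spec with ``se = 0`` (gamma) or ``pct = 0`` (uniform) is degenerate: draws
equal the mean exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .diseases import DISEASES


@dataclass(frozen=True)
class CostDistribution:
    """Uncertainty spec for one cost parameter."""

    kind: str  # "gamma" | "uniform"
    se: float = 0.0  # gamma only, same units as the mean
    pct: float = 0.20  # uniform only, half-width as fraction of the mean

    def __post_init__(self) -> None:
        if self.kind not in ("gamma", "uniform"):
            raise ValueError(f"distribution kind must be 'gamma' or 'uniform', got {self.kind!r}")
        if self.kind == "gamma" and self.se < 0:
            raise ValueError("gamma se must be nonnegative")
        if self.kind == "uniform" and not 0 <= self.pct < 1:
            raise ValueError("uniform pct must be in [0, 1)")

    def draw(self, mean: float, rng: np.random.Generator) -> float:
        """One random draw around ``mean``; degenerate specs return the mean."""
        if self.kind == "gamma":
            if self.se == 0:
                return mean
            if self.se <= 0:
                raise ValueError("gamma draws require se > 0")
            shape = (mean / self.se) ** 2
            scale = self.se**2 / mean
            return float(rng.gamma(shape, scale))
        lo, hi = (1 - self.pct) * mean, (1 + self.pct) * mean
        if lo == hi:
            return mean
        return float(rng.uniform(lo, hi))


@dataclass(frozen=True)
class CostParameterSet:
    """Per-disease mean annual costs plus the malnutrition multiplier dMN."""

    mean_cost: Mapping[str, float]
    cost_dist: Mapping[str, CostDistribution]
    delta_mn: float
    delta_dist: CostDistribution = field(default_factory=lambda: CostDistribution("uniform"))
    #: optional per-disease dMN overrides; empty = one global value
    delta_overrides: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [d for d in DISEASES if d not in self.mean_cost]
        if missing:
            raise ValueError(f"cost config missing disease(s): {', '.join(missing)}")
        unknown = [d for d in self.mean_cost if d not in DISEASES]
        if unknown:
            raise ValueError(f"cost config has unknown disease(s): {', '.join(unknown)}")
        for d, c in self.mean_cost.items():
            if not c > 0:
                raise ValueError(f"mean_annual_cost for {d} must be > 0, got {c}")
            if d not in self.cost_dist:
                raise ValueError(f"no uncertainty spec for {d}")
        if self.delta_mn < 0:
            raise ValueError(f"delta_mn must be nonnegative, got {self.delta_mn}")
        for d, v in self.delta_overrides.items():
            if d not in DISEASES:
                raise ValueError(f"delta_mn override for unknown disease {d!r}")
            if v < 0:
                raise ValueError(f"delta_mn override for {d} must be nonnegative")

    def cost_vector(self) -> np.ndarray:
        """C_i in canonical disease order."""
        return np.array([self.mean_cost[d] for d in DISEASES])

    def delta_vector(self) -> np.ndarray:
        """Effective dMN per disease (global value unless overridden)."""
        return np.array([self.delta_overrides.get(d, self.delta_mn) for d in DISEASES])

    def with_values(
        self, mean_cost: Mapping[str, float], delta_mn: float
    ) -> "CostParameterSet":
        """Copy with realized parameter values (used by the PSA)."""
        return CostParameterSet(
            mean_cost=dict(mean_cost),
            cost_dist=self.cost_dist,
            delta_mn=delta_mn,
            delta_dist=self.delta_dist,
            delta_overrides={},
        )
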