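"""Breeding goals over environment classes.

The aggregate genotype is H = v'a = sum_i v_i * A_i, the economically
weighted sum of the breeding values expressed in each environment class.
Two goals are provided:

* ``proportional`` - economic values equal to the class frequencies, i.e. a
  linear profit equation that values performance wherever animals happen to
  produce;
* ``resilience`` - economic values from the derivative of a saturating
  (diminishing-returns) profit function ``1 - exp(-rate * P)``, which puts
  more weight on poor environments and therefore rewards a flatter reaction
  norm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .env_grid import EnvGrid

__all__ = ["BreedingGoal", "proportional_goal", "resilience_goal", "profit"]


@dataclass(frozen=True)
class BreedingGoal:
    """Economic value per environment class."""

    values: np.ndarray
    label: str = "custom"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if not np.all(np.isfinite(v)):
            raise ValueError("economic values must be finite")
        if not np.any(v != 0.0):
            raise ValueError("at least one economic value must be nonzero")

    def intercept_slope_view(self, grid: EnvGrid) -> tuple[float, float]:
        """Equivalent weights on (A_int, A_sl).

        Because A_i = A_int + x_i * A_sl, the goal collapses to
        v_int = sum v_i and v_sl = sum v_i * x_i.
        """
        return float(self.values.sum()), float(self.values @ grid.x_means)


def proportional_goal(grid: EnvGrid) -> BreedingGoal:
    """Economic values equal to the class frequencies."""
    return BreedingGoal(values=grid.proportions.copy(), label="proportional")


def profit(P: float, rate: float = 0.3) -> float:
    """Saturating profit function 1 - exp(-rate * P)."""
    return 1.0 - np.exp(-rate * P)


def resilience_goal(
    grid: EnvGrid, rate: float = 0.3, mu: float = 0.0, b_fixed: float = 1.0
) -> BreedingGoal:
    """Economic values from the derivative of the saturating profit function.

    v_i = rate * exp(-rate * (mu + b_fixed * x_i)) evaluated at the expected
    phenotype in class i; strictly decreasing in the class mean, so poor
    environments weigh more.  With the default rate the extreme classes of
    the 13-class grid differ by roughly a factor four.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    values = rate * np.exp(-rate * (mu + b_fixed * grid.x_means))
    return BreedingGoal(values=values, label="resilience")
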