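"""Discretization of a standard-normal environmental gradient.

The environmental covariate ``x`` (e.g. a contemporary-group mean expressed
as a standardized deviation) is assumed ~ N(0, 1).  For multivariate
selection-index calculations the continuous gradient is discretized into a
small number of environment classes: an equally spaced band between
``-inner_bound`` and ``+inner_bound`` plus the two open tails.  Each class
carries its probability mass and the conditional (truncated-normal) mean of
``x`` within the class, which is the value used for all downstream genetic
covariances.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["EnvGrid", "build_env_grid", "allocate_animals"]


@dataclass(frozen=True)
class EnvGrid:
    """A discretized environmental gradient.

    Attributes
    ----------
    lower_bounds, upper_bounds
        Class boundaries on the gradient; the first lower bound is ``-inf``
        and the last upper bound ``+inf``.
    proportions
        Standard-normal probability mass of each class.
    x_means
        Conditional mean of ``x`` within each class (truncated-normal mean).
    counts_reference, counts_progeny
        Real-valued numbers of reference-population animals / progeny per
        class, populated by :func:`allocate_animals`.  Kept fractional on
        purpose: they enter variance formulas, not pens of animals.
    """

    lower_bounds: np.ndarray
    upper_bounds: np.ndarray
    proportions: np.ndarray
    x_means: np.ndarray
    counts_reference: np.ndarray | None = None
    counts_progeny: np.ndarray | None = None

    @property
    def n_classes(self) -> int:
        return len(self.proportions)

    @property
    def center_index(self) -> int:
        """Index of the class whose conditional mean is closest to zero."""
        return int(np.argmin(np.abs(self.x_means)))

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: one row per environment class."""
        data = {
            "environment": np.arange(1, self.n_classes + 1),
            "x_lower": self.lower_bounds,
            "x_upper": self.upper_bounds,
            "proportion": self.proportions,
            "x_average": self.x_means,
        }
        if self.counts_reference is not None:
            data["n_reference"] = self.counts_reference
        if self.counts_progeny is not None:
            data["n_progeny"] = self.counts_progeny
        return pd.DataFrame(data)


def _interval_masses(edges: np.ndarray) -> np.ndarray:
    return np.diff(stats.norm.cdf(edges))


def _interval_means(edges: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Truncated standard-normal means per interval.

    Uses the closed form E[x | a < x < b] = (phi(a) - phi(b)) / (Phi(b) -
    Phi(a)); the tails reduce to the inverse-Mills ratio.  A zero-mass
    interval gets the mean of its finite edge (the limit as the interval
    escapes to infinity).
    """
    phi = stats.norm.pdf(edges)
    means = np.zeros(len(masses))
    for i, mass in enumerate(masses):
        if mass > 0.0:
            means[i] = (phi[i] - phi[i + 1]) / mass
        else:
            finite = [e for e in (edges[i], edges[i + 1]) if np.isfinite(e)]
            means[i] = finite[0] if finite else 0.0
    return means


def build_env_grid(inner_bound: float = 2.0, n_inner: int = 11) -> EnvGrid:
    """Discretize N(0, 1) into ``n_inner`` equal-width inner classes plus tails.

    Parameters
    ----------
    inner_bound
        Half-width of the equally divided band; the defaults give 11 classes
        on (-2, 2) plus the two tails, 13 classes in total.
    n_inner
        Number of equal-width classes between the bounds.

    Zero-mass classes (possible when ``inner_bound`` is infinite) are dropped,
    so the returned grid always has strictly positive class probabilities.
    """
    if not inner_bound > 0:
        raise ValueError(f"inner_bound must be positive, got {inner_bound}")
    if n_inner < 1:
        raise ValueError(f"n_inner must be >= 1, got {n_inner}")
    if np.isinf(inner_bound):
        if n_inner > 1:
            raise ValueError("inner_bound must be finite when n_inner > 1")
        inner = np.array([-inner_bound, inner_bound])
    else:
        inner = np.linspace(-inner_bound, inner_bound, n_inner + 1)
    edges = np.concatenate(([-np.inf], inner, [np.inf]))
    masses = _interval_masses(edges)
    means = _interval_means(edges, masses)

    keep = masses > 0.0
    edges_lo, edges_hi = edges[:-1][keep], edges[1:][keep]
    masses, means = masses[keep], means[keep]
    return EnvGrid(
        lower_bounds=edges_lo,
        upper_bounds=edges_hi,
        proportions=masses,
        x_means=means,
    )


def allocate_animals(
    grid: EnvGrid, total_reference: float, total_progeny: float
) -> EnvGrid:
    """Spread reference-population animals and progeny over the classes.

    Counts are the class probability times the total and stay real-valued;
    rounding is a presentation concern only.
    """
    if total_reference < 0 or total_progeny < 0:
        raise ValueError("animal totals must be non-negative")
    return replace(
        grid,
        counts_reference=grid.proportions * total_reference,
        counts_progeny=grid.proportions * total_progeny,
    )
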