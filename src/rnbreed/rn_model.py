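"""Linear reaction-norm genetic architecture.

The phenotype of an animal in environment ``x`` follows

    P = mu + b*x + A_int + A_sl * x + E

with breeding values for intercept (``A_int``) and slope / environmental
sensitivity (``A_sl``) that are bivariate normal with variances
``var_int``, ``var_sl`` and covariance ``cov_int_sl``; the residual variance
``var_e`` is homogeneous across environments.  The breeding value expressed
in environment ``x`` is ``A(x) = A_int + x * A_sl``, so all per-environment
and between-environment genetic (co)variances are quadratic forms in ``x``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "RNParams",
    "genetic_variance",
    "genetic_covariance",
    "genetic_correlation",
    "heritability",
    "genetic_covariance_matrix",
]


@dataclass(frozen=True)
class RNParams:
    """Parameters of the linear reaction-norm model.

    ``mu`` and ``b_fixed`` are the population mean and the fixed (average)
    slope of the reaction norm; they shift expected phenotypes but carry no
    genetic variation.
    """

    var_int: float = 0.3
    var_sl: float = 0.05
    cov_int_sl: float = 0.0
    var_e: float = 0.7
    mu: float = 0.0
    b_fixed: float = 1.0

    def __post_init__(self) -> None:
        if self.var_int < 0 or self.var_sl < 0:
            raise ValueError("genetic variances must be non-negative")
        if self.var_e <= 0:
            raise ValueError("residual variance must be positive")
        bound = math.sqrt(self.var_int * self.var_sl)
        if abs(self.cov_int_sl) > bound + 1e-12:
            raise ValueError(
                f"|cov_int_sl|={abs(self.cov_int_sl):.6g} exceeds "
                f"sqrt(var_int*var_sl)={bound:.6g}"
            )

    @classmethod
    def from_h2(
        cls,
        h2: float,
        var_sl: float | None = None,
        r_int_sl: float = 0.0,
        slope_ratio: float = 0.05 / 0.3,
        **kwargs,
    ) -> "RNParams":
        """Scenario constructor: heritability ``h2`` in the average environment.

        Sets ``var_int = h2`` and ``var_e = 1 - h2`` so the phenotypic
        variance at x = 0 is one.  Unless ``var_sl`` is given explicitly,
        the slope variance scales with the intercept variance
        (``var_sl = slope_ratio * h2``), which leaves the whole
        between-environment genetic correlation structure invariant across
        heritability scenarios - the scenarios differ in signal-to-noise,
        not in the shape of the GxE.  The intercept-slope covariance is
        parameterized through the correlation ``r_int_sl``.
        """
        if not 0 < h2 < 1:
            raise ValueError("h2 must be in (0, 1)")
        if var_sl is None:
            var_sl = slope_ratio * h2
        return cls(
            var_int=h2,
            var_sl=var_sl,
            cov_int_sl=r_int_sl * math.sqrt(h2 * var_sl),
            var_e=1.0 - h2,
            **kwargs,
        )

    @property
    def bv_covariance(self) -> np.ndarray:
        """2x2 covariance matrix of (A_int, A_sl)."""
        return np.array(
            [[self.var_int, self.cov_int_sl], [self.cov_int_sl, self.var_sl]]
        )

    def with_bv_covariance(self, C: np.ndarray) -> "RNParams":
        """Copy with a new (A_int, A_sl) covariance, e.g. after selection."""
        return replace(
            self,
            var_int=float(C[0, 0]),
            var_sl=float(C[1, 1]),
            cov_int_sl=float(C[0, 1]),
        )


def genetic_variance(params: RNParams, x: float) -> float:
    """Additive genetic variance of A(x) = A_int + x*A_sl."""
    return params.var_int + 2.0 * x * params.cov_int_sl + x * x * params.var_sl


def genetic_covariance(params: RNParams, xi: float, xj: float) -> float:
    """Genetic covariance between breeding values expressed at xi and xj."""
    return (
        params.var_int
        + (xi + xj) * params.cov_int_sl
        + xi * xj * params.var_sl
    )


def genetic_correlation(params: RNParams, xi: float, xj: float) -> float:
    """Genetic correlation between performance in environments xi and xj."""
    vi = genetic_variance(params, xi)
    vj = genetic_variance(params, xj)
    if vi <= 0.0 or vj <= 0.0:
        raise ZeroDivisionError(
            f"genetic correlation undefined: zero genetic variance at "
            f"x={xi if vi <= 0 else xj}"
        )
    return genetic_covariance(params, xi, xj) / math.sqrt(vi * vj)


def heritability(params: RNParams, x: float) -> float:
    """Heritability in environment x (residual variance is constant)."""
    va = genetic_variance(params, x)
    return va / (va + params.var_e)


def genetic_covariance_matrix(params: RNParams, x: np.ndarray) -> np.ndarray:
    """Between-environment genetic covariance matrix over gradient values x.

    Rank <= 2 by construction (two underlying breeding values).
    """
    x = np.asarray(x, dtype=float)
    design = np.column_stack([np.ones_like(x), x])
    return design @ params.bv_covariance @ design.T
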