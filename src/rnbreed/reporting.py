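"""Golden-table regeneration and tidy CSV exports.

Regenerates the reference tables (environment grid; genomic-vs-traditional
response ratios) and the data series behind the figures (profit and
economic values, genetic correlation profile, accuracy profiles, response
profiles).  ``--check`` style functions diff regenerated values against the
packaged benchmark numbers with per-cell tolerances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _reference as ref
from .breeding_goal import profit, proportional_goal, resilience_goal
from .env_grid import EnvGrid, allocate_animals, build_env_grid
from .rn_model import RNParams, genetic_correlation, genetic_variance, heritability
from .scheme_engine import SchemeConfig, compare_schemes, predict_response
from .selection_index import (
    accuracy_profile,
    conventional_gebv_accuracies,
    conventional_progeny_accuracies,
    gebv_accuracy,
    gebv_sources,
    genetic_correlation_matrix,
    gebv_P,
    gebv_G,
    progeny_G,
    progeny_P,
)

__all__ = [
    "CheckResult",
    "table1_frame",
    "check_table1",
    "goal_frame",
    "correlation_frame",
    "accuracy_frame",
    "response_frame",
    "compare_frames",
    "check_compare",
]


@dataclass
class CheckResult:
    """Outcome of a golden-table diff."""

    ok: bool
    failures: list[str]

    def __bool__(self) -> bool:
        return self.ok


def table1_frame(
    total_reference: float = 5000.0, total_progeny: float = 100.0
) -> pd.DataFrame:
    """The 13-class environment grid with animal allocations."""
    grid = allocate_animals(build_env_grid(), total_reference, total_progeny)
    return grid.to_frame()


def check_table1(frame: pd.DataFrame | None = None) -> CheckResult:
    """Diff the regenerated grid against the printed benchmark table."""
    if frame is None:
        frame = table1_frame()
    cols = [
        "x_lower",
        "x_upper",
        "proportion",
        "x_average",
        "n_reference",
        "n_progeny",
    ]
    got = frame[cols].to_numpy()
    want = ref.TABLE1[:, 1:]
    failures = []
    for i in range(want.shape[0]):
        for j, col in enumerate(cols):
            w, g = want[i, j], got[i, j]
            if np.isinf(w) and np.isinf(g) and np.sign(w) == np.sign(g):
                continue
            if abs(w - g) > ref.TOL_TABLE1_ABS:
                failures.append(
                    f"row {i + 1} {col}: got {g:.4f}, benchmark {w:.4f}"
                )
    return CheckResult(not failures, failures)


def goal_frame(
    grid: EnvGrid | None = None, rate: float = 0.3
) -> pd.DataFrame:
    """Profit and economic value along the gradient plus both goal vectors."""
    grid = grid if grid is not None else build_env_grid()
    prop = proportional_goal(grid)
    resil = resilience_goal(grid, rate=rate)
    return pd.DataFrame(
        {
            "x": grid.x_means,
            "profit": [profit(x, rate) for x in grid.x_means],
            "economic_value": resil.values,
            "v_proportional": prop.values,
            "v_resilience": resil.values,
        }
    )


def correlation_frame(
    params: RNParams, grid: EnvGrid | None = None
) -> pd.DataFrame:
    """Genetic variance, heritability and correlation with the average
    environment, per class."""
    grid = grid if grid is not None else build_env_grid()
    x0 = grid.x_means[grid.center_index]
    return pd.DataFrame(
        {
            "x": grid.x_means,
            "genetic_variance": [
                genetic_variance(params, x) for x in grid.x_means
            ],
            "heritability": [heritability(params, x) for x in grid.x_means],
            "r_g_with_average": [
                genetic_correlation(params, x, x0) for x in grid.x_means
            ],
        }
    )


def accuracy_frame(
    params: RNParams | None = None,
    grid: EnvGrid | None = None,
    ref_sizes: tuple[float, ...] = (5000.0, 1_000_000.0),
    progeny_numbers: tuple[float, ...] = (100.0,),
    Me: float = 1200.0,
) -> pd.DataFrame:
    """Per-environment accuracies of progeny and genomic EBV.

    Tidy layout: one row per (model, evaluator, size, class) with the
    reaction-norm ('RN') and GxE-ignoring ('conv') accuracy side by side.
    """
    params = params if params is not None else RNParams()
    grid = grid if grid is not None else build_env_grid()
    rows = []
    for n_total in progeny_numbers:
        n_per = grid.proportions * n_total
        P, G = progeny_P(grid, params, n_per), progeny_G(grid, params)
        rn = accuracy_profile(P, G, params, grid)
        conv = conventional_progeny_accuracies(P, G, n_per, params, grid)
        for model, acc in (("RN", rn), ("conv", conv)):
            rows += [
                {
                    "model": model,
                    "evaluator": "progeny",
                    "size": n_total,
                    "environment": i + 1,
                    "x": x,
                    "accuracy": a,
                }
                for i, (x, a) in enumerate(zip(grid.x_means, acc))
            ]
    for ref_size in ref_sizes:
        acc_i = np.array(
            [
                gebv_accuracy(p * ref_size, heritability(params, x), Me)
                for p, x in zip(grid.proportions, grid.x_means)
            ]
        )
        rg = genetic_correlation_matrix(params, grid)
        P, G = gebv_P(acc_i, rg), gebv_G(acc_i, params, grid)
        rn = accuracy_profile(P, G, params, grid)
        conv = conventional_gebv_accuracies(acc_i, params, grid)
        for model, acc in (("RN", rn), ("conv", conv)):
            rows += [
                {
                    "model": model,
                    "evaluator": "gebv",
                    "size": ref_size,
                    "environment": i + 1,
                    "x": x,
                    "accuracy": a,
                }
                for i, (x, a) in enumerate(zip(grid.x_means, acc))
            ]
    return pd.DataFrame(rows)


def response_frame(
    params: RNParams | None = None,
    grid: EnvGrid | None = None,
    goal_name: str = "resilience",
    ref_sizes: tuple[float, ...] = (5000.0, 1_000_000.0),
    nucleus_information: bool = False,
    **config_kwargs,
) -> pd.DataFrame:
    """Response to selection per environment for the three schemes.

    The default reduced indices (sib/progeny means only) correspond to the
    response-profile figures; set ``nucleus_information=True`` for the
    full pseudo-BLUP schemes.
    """
    params = params if params is not None else RNParams()
    grid = grid if grid is not None else build_env_grid()
    goal = (
        resilience_goal(grid)
        if goal_name == "resilience"
        else proportional_goal(grid)
    )
    rows = []
    runs = [("sib", None), ("progeny", None)]
    runs += [("genomic", ref) for ref in ref_sizes]
    for scheme, ref_size in runs:
        kwargs = dict(config_kwargs)
        if ref_size is not None:
            kwargs["ref_size"] = ref_size
        result = predict_response(
            SchemeConfig(
                scheme=scheme,
                goal=goal,
                nucleus_information=nucleus_information,
                **kwargs,
            ),
            params,
            grid,
        )
        label = scheme if ref_size is None else f"genomic_{int(ref_size)}"
        rows += [
            {
                "scheme": label,
                "goal": goal_name,
                "environment": i + 1,
                "x": x,
                "response": r,
            }
            for i, (x, r) in enumerate(
                zip(grid.x_means, result.response_per_env)
            )
        ]
    return pd.DataFrame(rows)


def compare_frames(
    h2_values: tuple[float, ...] = (0.1, 0.3, 0.5),
    ref_sizes: tuple[float, ...] = (5000.0, 1_000_000.0),
    **kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scheme-comparison ratio tables (per-environment and intercept/slope)."""
    return compare_schemes(
        h2_values=h2_values, ref_sizes=ref_sizes, **kwargs
    )


def check_compare(
    env_table: pd.DataFrame | None = None,
    rn_table: pd.DataFrame | None = None,
) -> CheckResult:
    """Diff regenerated comparison ratios against the benchmark tables.

    Per-environment and intercept cells at 5% relative tolerance; slope
    cells at 15% (their denominators are near zero, as the source itself
    notes).
    """
    if env_table is None or rn_table is None:
        env_table, rn_table = compare_frames()
    failures = []
    for (comp, h2, ref_size), want in ref.TABLE3.items():
        row = env_table[
            (env_table.comparison == comp)
            & (env_table.h2 == h2)
            & (env_table.ref_size == ref_size)
        ]
        if row.empty:
            failures.append(f"missing Table-3 row {comp} h2={h2} N={ref_size}")
            continue
        got = row.iloc[0]
        for col, w in zip(("low", "middle", "high"), want):
            if abs(got[col] / w - 1.0) > ref.TOL_TABLE3_REL:
                failures.append(
                    f"T3 {comp} h2={h2} N={ref_size} {col}: "
                    f"got {got[col]:.2f}, benchmark {w:.2f}"
                )
    for (comp, h2, ref_size), (w_int, w_sl) in ref.TABLE4.items():
        row = rn_table[
            (rn_table.comparison == comp)
            & (rn_table.h2 == h2)
            & (rn_table.ref_size == ref_size)
        ]
        if row.empty:
            failures.append(f"missing Table-4 row {comp} h2={h2} N={ref_size}")
            continue
        got = row.iloc[0]
        if abs(got["intercept"] / w_int - 1.0) > ref.TOL_TABLE4_INT_REL:
            failures.append(
                f"T4 {comp} h2={h2} N={ref_size} intercept: "
                f"got {got['intercept']:.2f}, benchmark {w_int:.2f}"
            )
        sl = got["slope"]
        if np.sign(sl) != np.sign(w_sl) or abs(sl / w_sl - 1.0) > (
            ref.TOL_TABLE4_SLOPE_REL
        ):
            failures.append(
                f"T4 {comp} h2={h2} N={ref_size} slope: "
                f"got {sl:.2f}, benchmark {w_sl:.2f}"
            )
    return CheckResult(not failures, failures)
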