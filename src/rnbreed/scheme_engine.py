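"""Pseudo-BLUP prediction of response to selection per environment.

Three breeding schemes are compared on a nucleus of candidates whose
information is spread over the environment classes of an :class:`EnvGrid`:

* **sib testing** - half-sib means per environment (commercial relatives),
  full-sib records in the nucleus environment, own performance for females,
  and parental EBV sources;
* **progeny testing** - as sib testing, except male candidates are
  evaluated on half-sib progeny means per environment and carry a longer
  generation interval;
* **genomic selection** - per-environment GEBV whose accuracies follow the
  reference-population-size formula.

The pseudo-BLUP construction approximates BLUP evaluation by adding the
parents' EBV as index sources; their accuracies are taken from the same
scheme one generation earlier, closed as a fixed point jointly with the
Bulmer equilibrium.  Selection erodes between-family genetic variance
first, so the equilibrium is tracked as the pair of covariance matrices of
(A_int, A_sl) among selected sires and dams; every information source
combines parental-path contributions from these matrices (see
:mod:`.selection_index`).  Selection intensities assume a finite number of
candidates (Burrows' correction) and are shrunk for correlated index
values among relatives.

Response to selection in environment class e per round is

    R_e = [ i_m cov(I_m, A_e)/sigma_I,m + i_f cov(I_f, A_e)/sigma_I,f ]
          / (L_m + L_f)

evaluated at equilibrium; the intercept response equals the response in
the average environment and the slope (environmental-sensitivity) response
follows from R_e = R_int + x_e * R_sl, which holds exactly because the
index-to-breeding-value covariances are linear in x.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .breeding_goal import BreedingGoal, proportional_goal, resilience_goal
from .env_grid import EnvGrid, build_env_grid
from .rn_model import RNParams, genetic_covariance_matrix, heritability
from .selection_index import (
    IndexSystem,
    InfoSource,
    PopulationState,
    env_accuracy,
    gebv_accuracy,
    solve_index,
    source_matrices,
)

__all__ = [
    "SchemeConfig",
    "SchemeResult",
    "selection_intensity",
    "scheme_sources",
    "build_scheme_index",
    "bulmer_equilibrium",
    "predict_response",
    "compare_schemes",
]

SCHEMES = ("sib", "progeny", "genomic")


@dataclass(frozen=True)
class SchemeConfig:
    """Structural parameters of one breeding scheme.

    ``nucleus_information`` distinguishes the full pseudo-BLUP index
    (nucleus full-sib / own-performance records plus parental EBV) from the
    reduced sib- or progeny-means-only variant used when profiling
    responses across environments.  Generation intervals are relative;
    progeny-tested sires default to 1.6.  ``gebv_h2_basis`` chooses the
    heritability entering the GEBV-accuracy formula: the base population
    (a standing commercial reference resource, the default) or the
    candidate generation at equilibrium.
    """

    scheme: str
    goal: BreedingGoal
    p_male: float = 0.05
    p_female: float = 0.20
    n_nucleus: int = 2000
    n_progeny_per_dam: int = 10
    n_commercial: float = 100.0
    ref_size: float = 5000.0
    Me: float = 1200.0
    L_male: float | None = None
    L_female: float = 1.0
    nucleus_information: bool = True
    gebv_h2_basis: str = "base"
    fullsib_records: str = "female"  # 'female': sex-limited trait, or 'all'

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        for p in (self.p_male, self.p_female):
            if not 0 < p <= 1:
                raise ValueError("selected proportions must be in (0, 1]")
        if min(self.n_nucleus, self.n_progeny_per_dam) <= 0:
            raise ValueError("population sizes must be positive")
        if self.gebv_h2_basis not in ("base", "candidate"):
            raise ValueError("gebv_h2_basis must be 'base' or 'candidate'")
        if self.L_male is None:
            object.__setattr__(
                self, "L_male", 1.6 if self.scheme == "progeny" else 1.0
            )

    @property
    def n_candidates_per_sex(self) -> float:
        return self.n_nucleus / 2.0

    @property
    def n_dam_pool(self) -> float:
        """Number of commercial dams behind the half-sib/progeny groups."""
        return self.n_commercial / self.n_progeny_per_dam


@dataclass
class SchemeResult:
    """Per-environment responses and accuracies at Bulmer equilibrium."""

    response_per_env: np.ndarray
    R_int: float
    R_sl: float
    acc_male: float
    acc_female: float
    intensity_male: float
    intensity_female: float
    equilibrium_params: RNParams
    iterations: int
    system_male: IndexSystem = field(repr=False, default=None)
    system_female: IndexSystem = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# Selection intensity
# ---------------------------------------------------------------------------

def selection_intensity(
    p: float, n_candidates: float = math.inf, rho_index: float = 0.0
) -> float:
    """Standardized selection differential for truncation selection.

    Starts from the infinite-population intensity phi(z)/p, applies
    Burrows' finite-sample correction i - (1-p)/(2 i p (n+1)), and shrinks
    by sqrt(1 - rho_index) for the average correlation between index
    values of the candidates (correlated family information leaves less
    usable variation between candidates).
    """
    if not 0 < p <= 1:
        raise ValueError("selected proportion must be in (0, 1]")
    if not 0 <= rho_index < 1:
        raise ValueError("rho_index must be in [0, 1)")
    if p == 1.0:
        return 0.0
    z = stats.norm.ppf(1.0 - p)
    i_inf = stats.norm.pdf(z) / p
    i = i_inf
    if math.isfinite(n_candidates):
        if n_candidates < 1:
            raise ValueError("need at least one candidate")
        i = i_inf - (1.0 - p) / (2.0 * i_inf * p * (n_candidates + 1.0))
    return max(i, 0.0) * math.sqrt(1.0 - rho_index)


def _variance_reduction_factor(p: float) -> float:
    """Bulmer's k = i (i - z) for truncation at selected proportion p."""
    if p >= 1.0:
        return 0.0
    z = stats.norm.ppf(1.0 - p)
    i = stats.norm.pdf(z) / p
    return i * (i - z)


# ---------------------------------------------------------------------------
# Index assembly
# ---------------------------------------------------------------------------

def _genomic_sources(
    config: SchemeConfig, state: PopulationState, grid: EnvGrid
) -> list[InfoSource]:
    N = grid.proportions * config.ref_size
    if config.gebv_h2_basis == "base":
        h2 = [heritability(state.params, float(x)) for x in grid.x_means]
    else:
        cand = state.candidate_params()
        h2 = [heritability(cand, float(x)) for x in grid.x_means]
    return [
        InfoSource(
            kind="ebv",
            group="own",
            env_x=float(x),
            relationship=1.0,
            accuracy=gebv_accuracy(float(n), h2_i, config.Me),
            scope="individual",
            label=f"gebv[{i + 1}]",
        )
        for i, (x, n, h2_i) in enumerate(zip(grid.x_means, N, h2))
    ]


def _default_parent_acc(grid: EnvGrid) -> dict:
    return {"sire": (0.5, 0.5), "dam": (0.5, 0.5), "hsdams": 0.5}


def scheme_sources(
    config: SchemeConfig,
    state: PopulationState,
    grid: EnvGrid,
    sex: str,
    parent_acc: dict | None = None,
) -> list[InfoSource]:
    """Assemble the information sources of one candidate sex.

    The trait is sex-limited (recorded on females only), so of the
    ``n_progeny_per_dam`` nucleus full sibs half are recorded; a female
    candidate is herself one of them and contributes her record as a
    separate own-performance source.  The nucleus sits in the best
    environment (the top grid class); parental EBV are carried for the
    best and worst environments, and the EBV of the (unrelated) commercial
    dams enter as one pooled source that soaks up the dam contribution to
    the half-sib means.
    """
    if sex not in ("male", "female"):
        raise ValueError("sex must be 'male' or 'female'")
    if config.scheme == "genomic":
        return _genomic_sources(config, state, grid)
    if parent_acc is None:
        parent_acc = _default_parent_acc(grid)

    x_best = float(grid.x_means[-1])
    x_worst = float(grid.x_means[0])
    x_mid = float(grid.x_means[grid.center_index])
    use_progeny = config.scheme == "progeny" and sex == "male"
    n_comm = grid.proportions * config.n_commercial

    sources: list[InfoSource] = [
        InfoSource(
            kind="mean",
            group="prog" if use_progeny else "hs",
            env_x=float(x),
            relationship=0.5 if use_progeny else 0.25,
            n_records=float(n),
            a_within=0.25,
            scope="individual" if use_progeny else "sire",
            label=f"{'progeny' if use_progeny else 'halfsib'}_mean[{i + 1}]",
        )
        for i, (x, n) in enumerate(zip(grid.x_means, n_comm))
    ]
    if not config.nucleus_information:
        return sources

    n_sibs = (
        config.n_progeny_per_dam / 2.0
        if config.fullsib_records == "female"
        else float(config.n_progeny_per_dam)
    )
    n_fs = n_sibs - (1.0 if sex == "female" else 0.0)
    if n_fs >= 1.0:
        sources.append(
            InfoSource(
                kind="mean",
                group="fs",
                env_x=x_best,
                relationship=0.5,
                n_records=n_fs,
                a_within=0.5,
                scope="dam",
                label="fullsib_mean",
            )
        )
    if sex == "female":
        sources.append(
            InfoSource(
                kind="own",
                group="own",
                env_x=x_best,
                relationship=1.0,
                scope="individual",
                label="own_performance",
            )
        )
    for parent, scope in (("sire", "sire"), ("dam", "dam")):
        acc_best, acc_worst = parent_acc[parent]
        for env, acc, tag in (
            (x_best, acc_best, "best"),
            (x_worst, acc_worst, "worst"),
        ):
            sources.append(
                InfoSource(
                    kind="ebv",
                    group=parent,
                    env_x=env,
                    relationship=0.5,
                    accuracy=float(np.clip(acc, 0.0, 1.0)),
                    scope=scope,
                    label=f"{parent}_ebv_{tag}",
                )
            )
    sources.append(
        InfoSource(
            kind="pooled_ebv",
            group="hsdams",
            env_x=x_mid,
            relationship=0.0,
            accuracy=float(np.clip(parent_acc["hsdams"], 0.0, 1.0)),
            n_pool=config.n_dam_pool,
            scope="individual" if use_progeny else "sire",
            label="commercial_dam_ebv",
        )
    )
    return sources


def _solve_for_goal(
    sources: list[InfoSource],
    state: PopulationState,
    grid: EnvGrid,
    goal: BreedingGoal,
) -> IndexSystem:
    targets = list(grid.x_means) + ["int", "sl"]
    P, G_full = source_matrices(sources, targets=targets, state=state)
    G = G_full[:, : grid.n_classes]
    goal_cov = genetic_covariance_matrix(
        state.candidate_params(), grid.x_means
    )
    return solve_index(
        P,
        G,
        goal.values,
        goal_cov=goal_cov,
        sources=sources,
        state=state,
        g_int=G_full[:, -2],
        g_sl=G_full[:, -1],
    )


def build_scheme_index(
    config: SchemeConfig,
    params: RNParams,
    grid: EnvGrid,
    sex: str,
    parent_acc: dict | None = None,
    state: PopulationState | None = None,
) -> IndexSystem:
    """Assemble and solve the selection index of one candidate sex."""
    if state is None:
        state = PopulationState.unselected(params)
    sources = scheme_sources(config, state, grid, sex, parent_acc)
    return _solve_for_goal(sources, state, grid, config.goal)


# ---------------------------------------------------------------------------
# Correlation between index values of related candidates
# ---------------------------------------------------------------------------

_A_PAIR = {"FS": 0.5, "HS": 0.25}

# member-to-member relationships between the *unshared* source groups of
# two candidates; callables receive the candidate-candidate relationship
_CROSS_REL = {
    frozenset(("own",)): lambda a: a,
    frozenset(("prog",)): lambda a: 0.25 * a,
    frozenset(("own", "fs")): lambda a: 0.25,
    frozenset(("prog", "fs")): lambda a: 0.125,
    frozenset(("fs",)): lambda a: 0.25,
}


def _cross_candidate_cov(
    s: InfoSource,
    t: InfoSource,
    pair: str,
    P_st: float,
    state: PopulationState,
) -> float:
    """cov(source s of candidate 1, source t of candidate 2).

    Family-level sources shared by the pair (sire-scope always; dam-scope
    for full sibs) are literally the same quantity for both candidates, so
    any pairing that touches a shared source keeps the within-candidate
    covariance.  The remaining pairings are genuine cross-family
    covariances through the additive relationship of the pair
    (approximated with the candidate-generation covariance matrix; the
    result only nudges the finite-population intensity correction).
    """
    shared = {"sire"} if pair == "HS" else {"sire", "dam"}
    if s.scope in shared or t.scope in shared:
        return P_st
    a_pair = _A_PAIR[pair]
    if s.kind == "ebv" and t.kind == "ebv":
        # candidates' own GEBV
        corr = state.cov("cand", s.env_x, t.env_x) / math.sqrt(
            state.var("cand", s.env_x) * state.var("cand", t.env_x)
        )
        return a_pair * s.accuracy * t.accuracy * corr
    if s.is_phenotypic and t.is_phenotypic:
        rel_fn = _CROSS_REL.get(frozenset((s.group, t.group)))
        if rel_fn is None:
            return 0.0
        return rel_fn(a_pair) * state.cov("cand", s.env_x, t.env_x)
    return 0.0  # unshared EBV sources of different animals (dams, mates)


def _pair_index_correlation(
    system: IndexSystem, pair: str, state: PopulationState
) -> float:
    b = system.weights
    srcs = system.sources
    cov = 0.0
    for i, s in enumerate(srcs):
        if b[i] == 0.0:
            continue
        for j, t in enumerate(srcs):
            if b[j] == 0.0:
                continue
            cov += b[i] * b[j] * _cross_candidate_cov(
                s, t, pair, system.P[i, j], state
            )
    return float(np.clip(cov / system.sigma_I**2, 0.0, 1.0))


def mean_candidate_index_correlation(
    system: IndexSystem, config: SchemeConfig, state: PopulationState
) -> float:
    """Average index correlation over all candidate pairs of one sex.

    The nucleus contains full-sib groups of ``n_progeny_per_dam / 2`` per
    sex nested in paternal half-sib groups; all other pairs are treated as
    uncorrelated.
    """
    n_cand = config.n_candidates_per_sex
    fs_size = config.n_progeny_per_dam / 2.0
    n_sires = max(config.p_male * n_cand, 1.0)
    n_dams = max(config.p_female * n_cand, 1.0)
    dams_per_sire = n_dams / n_sires
    n_fs = max(fs_size - 1.0, 0.0)
    n_hs = max((dams_per_sire - 1.0) * fs_size, 0.0)
    rho_fs = _pair_index_correlation(system, "FS", state)
    rho_hs = _pair_index_correlation(system, "HS", state)
    return (n_fs * rho_fs + n_hs * rho_hs) / max(n_cand - 1.0, 1.0)


# ---------------------------------------------------------------------------
# Bulmer equilibrium and response
# ---------------------------------------------------------------------------

def _equilibrium_state(
    config: SchemeConfig,
    params: RNParams,
    grid: EnvGrid,
    max_iter: int = 200,
    tol_C: float = 1e-8,
    tol_acc: float = 1e-6,
):
    """Joint fixed point of Bulmer variance reduction and parental accuracy.

    Each round the indices of both sexes are rebuilt under the current
    population state; truncation selection on each parent index leaves the
    selected group with

        C_sel = C_cand - k * c c' / sigma_I^2,   c = cov((A_int, A_sl), I),

    and the next candidate generation has C_cand = 0.5 C_base +
    0.25 (C_sel,m + C_sel,f).  Parental EBV accuracies are refreshed from
    the per-environment accuracies of the current indices (sire from the
    male index, dam and commercial dams from the female index).
    """
    C_base = params.bv_covariance
    C_sel_m = C_base.copy()
    C_sel_f = C_base.copy()
    parent_acc = _default_parent_acc(grid)
    k_m = _variance_reduction_factor(config.p_male)
    k_f = _variance_reduction_factor(config.p_female)
    best, worst, mid = grid.n_classes - 1, 0, grid.center_index

    d_C = d_acc = math.inf
    prev_step = None
    for iteration in range(1, max_iter + 1):
        state = PopulationState(
            params=params, C_sel_m=C_sel_m, C_sel_f=C_sel_f
        )
        sys_m = build_scheme_index(
            config, params, grid, "male", parent_acc, state
        )
        sys_f = build_scheme_index(
            config, params, grid, "female", parent_acc, state
        )

        new_acc = {
            "sire": (
                env_accuracy(sys_m, params, grid, best),
                env_accuracy(sys_m, params, grid, worst),
            ),
            "dam": (
                env_accuracy(sys_f, params, grid, best),
                env_accuracy(sys_f, params, grid, worst),
            ),
            "hsdams": env_accuracy(sys_f, params, grid, mid),
        }

        C_cand = state.C_cand
        new_sel = []
        for system, k in ((sys_m, k_m), (sys_f, k_f)):
            c_vec = np.array(
                [
                    float(system.weights @ system.g_int),
                    float(system.weights @ system.g_sl),
                ]
            )
            new_sel.append(
                C_cand - k * np.outer(c_vec, c_vec) / system.sigma_I**2
            )

        d_C = max(
            float(np.max(np.abs(new_sel[0] - C_sel_m))),
            float(np.max(np.abs(new_sel[1] - C_sel_f))),
        )
        d_acc = max(
            abs(a - b)
            for key in parent_acc
            for a, b in zip(
                np.atleast_1d(new_acc[key]), np.atleast_1d(parent_acc[key])
            )
        )
        # Aitken-style acceleration of the (near-linear) contraction: once
        # the step direction has stabilized, extrapolate along it; reject
        # any extrapolation that leaves the PSD cone of covariance matrices
        x_prev = np.concatenate([C_sel_m.ravel(), C_sel_f.ravel()])
        x_new = np.concatenate([new_sel[0].ravel(), new_sel[1].ravel()])
        if prev_step is not None and iteration > 2:
            step = x_new - x_prev
            denom = float(prev_step @ prev_step)
            if denom > 0.0:
                ratio = float(step @ prev_step) / denom
                if 0.0 < ratio < 0.9:
                    x_ext = x_new + step * ratio / (1.0 - ratio)
                    cm = x_ext[:4].reshape(2, 2)
                    cf = x_ext[4:].reshape(2, 2)
                    if (
                        np.linalg.eigvalsh(cm).min() > -1e-12
                        and np.linalg.eigvalsh(cf).min() > -1e-12
                    ):
                        new_sel = [cm, cf]
        prev_step = x_new - x_prev
        C_sel_m, C_sel_f = new_sel
        parent_acc = new_acc
        if d_C < tol_C and d_acc < tol_acc:
            break
    else:
        raise RuntimeError(
            f"Bulmer/parental-accuracy fixed point did not converge in "
            f"{max_iter} iterations (|dC|={d_C:.2e}, |dacc|={d_acc:.2e})"
        )

    state = PopulationState(params=params, C_sel_m=C_sel_m, C_sel_f=C_sel_f)
    sys_m = build_scheme_index(config, params, grid, "male", parent_acc, state)
    sys_f = build_scheme_index(
        config, params, grid, "female", parent_acc, state
    )
    return state, sys_m, sys_f, iteration


def bulmer_equilibrium(
    config: SchemeConfig, params: RNParams, grid: EnvGrid
) -> tuple[RNParams, IndexSystem, IndexSystem]:
    """Equilibrium candidate-generation parameters and the two sex indices."""
    state, sys_m, sys_f, _ = _equilibrium_state(config, params, grid)
    return state.candidate_params(), sys_m, sys_f


def predict_response(
    config: SchemeConfig, params: RNParams, grid: EnvGrid
) -> SchemeResult:
    """Response to selection per environment class at Bulmer equilibrium."""
    state, sys_m, sys_f, iters = _equilibrium_state(config, params, grid)

    intensities = {}
    for sex, system, p in (
        ("male", sys_m, config.p_male),
        ("female", sys_f, config.p_female),
    ):
        rho = mean_candidate_index_correlation(system, config, state)
        intensities[sex] = selection_intensity(
            p, config.n_candidates_per_sex, rho
        )
    i_m, i_f = intensities["male"], intensities["female"]
    L_total = config.L_male + config.L_female

    def _path(system: IndexSystem, i: float, g: np.ndarray) -> float:
        return i * float(system.weights @ g) / system.sigma_I

    response = np.array(
        [
            (
                _path(sys_m, i_m, sys_m.G[:, e])
                + _path(sys_f, i_f, sys_f.G[:, e])
            )
            / L_total
            for e in range(grid.n_classes)
        ]
    )
    R_int = (
        _path(sys_m, i_m, sys_m.g_int) + _path(sys_f, i_f, sys_f.g_int)
    ) / L_total
    R_sl = (
        _path(sys_m, i_m, sys_m.g_sl) + _path(sys_f, i_f, sys_f.g_sl)
    ) / L_total

    return SchemeResult(
        response_per_env=response,
        R_int=R_int,
        R_sl=R_sl,
        acc_male=sys_m.r_IH,
        acc_female=sys_f.r_IH,
        intensity_male=i_m,
        intensity_female=i_f,
        equilibrium_params=state.candidate_params(),
        iterations=iters,
        system_male=sys_m,
        system_female=sys_f,
    )


# ---------------------------------------------------------------------------
# Scheme comparison tables
# ---------------------------------------------------------------------------

def _safe_ratio(num: float, den: float) -> float:
    if abs(den) < 1e-12:
        return math.nan
    return num / den


def compare_schemes(
    grid: EnvGrid | None = None,
    h2_values: tuple[float, ...] = (0.1, 0.3, 0.5),
    ref_sizes: tuple[float, ...] = (5000.0, 1_000_000.0),
    goal_name: str = "resilience",
    var_sl: float | None = None,
    r_int_sl: float = 0.0,
    **config_kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Genomic-selection response relative to sib / progeny testing.

    Returns two tidy tables: per-environment response ratios in the
    lowest, middle and highest class, and ratios of the intercept and
    slope responses.
    """
    if grid is None:
        grid = build_env_grid()
    if goal_name == "resilience":
        goal = resilience_goal(grid)
    elif goal_name == "proportional":
        goal = proportional_goal(grid)
    else:
        raise ValueError(f"unknown goal {goal_name!r}")

    env_rows, rn_rows = [], []
    low, mid, high = 0, grid.center_index, grid.n_classes - 1
    for h2 in h2_values:
        params = RNParams.from_h2(h2, var_sl=var_sl, r_int_sl=r_int_sl)
        trad = {
            scheme: predict_response(
                SchemeConfig(scheme=scheme, goal=goal, **config_kwargs),
                params,
                grid,
            )
            for scheme in ("sib", "progeny")
        }
        for ref in ref_sizes:
            gs = predict_response(
                SchemeConfig(
                    scheme="genomic", goal=goal, ref_size=ref, **config_kwargs
                ),
                params,
                grid,
            )
            for scheme, res in trad.items():
                env_rows.append(
                    {
                        "comparison": f"GS/{scheme}",
                        "h2": h2,
                        "ref_size": ref,
                        "low": _safe_ratio(
                            gs.response_per_env[low],
                            res.response_per_env[low],
                        ),
                        "middle": _safe_ratio(
                            gs.response_per_env[mid],
                            res.response_per_env[mid],
                        ),
                        "high": _safe_ratio(
                            gs.response_per_env[high],
                            res.response_per_env[high],
                        ),
                    }
                )
                rn_rows.append(
                    {
                        "comparison": f"GS/{scheme}",
                        "h2": h2,
                        "ref_size": ref,
                        "intercept": _safe_ratio(gs.R_int, res.R_int),
                        "slope": _safe_ratio(gs.R_sl, res.R_sl),
                    }
                )
    return pd.DataFrame(env_rows), pd.DataFrame(rn_rows)
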