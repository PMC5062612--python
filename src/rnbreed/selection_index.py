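"""Selection-index algebra for reaction-norm breeding value prediction.

An index I = b'x combines information sources x (progeny / sib means, own
performance, parental EBV, per-environment GEBV).  The optimal weights are
b = P^-1 G v, where P is the (co)variance matrix of the sources, G the
covariance matrix between sources and the breeding values per environment
class, and v the vector of economic values.  The accuracy of the index for
the breeding value expressed in class i is

    r_i = b'g_i / (sigma_I * sigma_A(x_i)),      sigma_I = sqrt(b'Pb).

Covariances follow standard quantitative-genetic rules.  In an unselected
population a mean of n records of relatives (additive relationship ``a`` to
the candidate, ``a_within`` among group members) recorded in environment
x_i has

    var  = (sigma2_A(x_i) + sigma2_e + (n-1) a_within sigma2_A(x_i)) / n
    cov with the candidate's breeding value at x_j = a * cov_A(x_i, x_j).

Under recurrent truncation selection these rules are refined: the part of a
relative's breeding value transmitted by a *selected* parent carries the
(smaller) covariance matrix of the selected group, not the population
covariance, because gametic-phase disequilibrium erodes between-family
variance first.  :class:`PopulationState` tracks the base, selected-sire,
selected-dam and candidate covariance matrices of (A_int, A_sl); every
source covariance is a fixed combination of parental-path contributions
drawn from those matrices.  With no selection all four matrices coincide
and the classic formulas above re-emerge.

A (G)EBV source is scaled to unit variance; an EBV with accuracy r for
environment x_i behaves as a predictor with

    cov(EBV_i, A_j of a relative) = a * r * cov_A(x_i, x_j) / sigma_A(x_i)
    cov(EBV_i, EBV_j, same animal) = r_i r_j r_g(x_i, x_j),

which reproduces the genomic-index matrices exactly and reduces to the true
standardized breeding value at r = 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .env_grid import EnvGrid
from .rn_model import RNParams, genetic_variance

__all__ = [
    "InfoSource",
    "IndexSystem",
    "PopulationState",
    "DegenerateIndexError",
    "progeny_sources",
    "progeny_P",
    "progeny_G",
    "gebv_accuracy",
    "gebv_sources",
    "gebv_P",
    "gebv_G",
    "genetic_correlation_matrix",
    "source_matrices",
    "solve_index",
    "env_accuracy",
    "accuracy_profile",
    "conventional_collapse_progeny",
    "conventional_progeny_accuracies",
    "conventional_collapse_gebv",
    "conventional_gebv_accuracies",
]

# Near-unit correlation between two sources above which the later source is
# redundant and pruned before inverting P.
_PRUNE_CORR = 1.0 - 1e-8


class DegenerateIndexError(ValueError):
    """P matrix singular beyond what duplicate-source pruning can repair."""


# ---------------------------------------------------------------------------
# Population state: (A_int, A_sl) covariance matrices by parental path
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PopulationState:
    """Genetic covariance structure of the population under selection.

    ``C_sel_m`` / ``C_sel_f`` are the covariance matrices of (A_int, A_sl)
    among the selected sires and dams; the candidate generation has

        C_cand = 0.5 * C_base + 0.25 * C_sel_m + 0.25 * C_sel_f

    (Mendelian-sampling variance is half the base covariance and untouched
    by selection).  ``unselected`` gives the degenerate state in which all
    matrices equal the base one.
    """

    params: RNParams
    C_sel_m: np.ndarray
    C_sel_f: np.ndarray

    @classmethod
    def unselected(cls, params: RNParams) -> "PopulationState":
        C = params.bv_covariance
        return cls(params=params, C_sel_m=C.copy(), C_sel_f=C.copy())

    @property
    def C_base(self) -> np.ndarray:
        return self.params.bv_covariance

    @property
    def C_cand(self) -> np.ndarray:
        return 0.5 * self.C_base + 0.25 * (self.C_sel_m + self.C_sel_f)

    @property
    def var_e(self) -> float:
        return self.params.var_e

    def candidate_params(self) -> RNParams:
        """Base parameters with the candidate-generation covariance."""
        return self.params.with_bv_covariance(self.C_cand)

    def _matrix(self, key: str) -> np.ndarray:
        return {
            "base": self.C_base,
            "sel_m": self.C_sel_m,
            "sel_f": self.C_sel_f,
            "cand": self.C_cand,
        }[key]

    def cov(self, key: str, e: float, target) -> float:
        """cov(A(e), A(target)) under matrix ``key``.

        ``target`` is a gradient value or one of the symbols ``'int'`` /
        ``'sl'`` for the intercept and slope breeding values.
        """
        M = self._matrix(key)
        if isinstance(target, str):
            if target == "int":
                return M[0, 0] + e * M[0, 1]
            if target == "sl":
                return M[0, 1] + e * M[1, 1]
            raise ValueError(f"unknown target {target!r}")
        t = float(target)
        return M[0, 0] + (e + t) * M[0, 1] + e * t * M[1, 1]

    def var(self, key: str, e: float) -> float:
        return self.cov(key, e, e)

    def combo(self, terms, e: float, target) -> float:
        """Weighted combination sum(coef * cov(key, e, target))."""
        return sum(coef * self.cov(key, e, target) for coef, key in terms)


@dataclass(frozen=True)
class InfoSource:
    """One information source of a selection index.

    ``kind`` is one of ``mean`` (average phenotype of a group of relatives),
    ``own`` (own performance), ``ebv`` (unit-variance predictor such as a
    parental EBV or a per-environment GEBV) or ``pooled_ebv`` (average of
    ``n_pool`` EBVs of mutually unrelated animals, e.g. the dams of the
    commercial half-sibs; relevant only through its covariance with the sib
    means, so its relationship to the candidate is zero).

    ``group`` identifies the family unit the source is measured on
    (``hs`` commercial half-sibs, ``fs`` nucleus full sibs, ``own`` the
    candidate itself - also carrying its GEBV -, ``prog`` its progeny,
    ``sire`` / ``dam`` its parents, ``hsdams`` the unrelated commercial
    dams).  ``relationship`` is the additive relationship between the
    source animals and the candidate; ``scope`` marks which candidates of
    the same family share the source verbatim (``sire``-scope: all paternal
    half sibs; ``dam``-scope: full sibs; ``individual``: nobody).
    """

    kind: str
    group: str
    env_x: float
    relationship: float
    n_records: float = 1.0
    a_within: float = 0.0
    accuracy: float = 1.0
    n_pool: float = 1.0
    scope: str = "individual"
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind in ("mean", "own") and self.n_records <= 0:
            # group sizes are real-valued (probability-mass allocations)
            raise ValueError(f"{self.kind} source needs n_records > 0")
        if self.kind in ("ebv", "pooled_ebv") and not 0 <= self.accuracy <= 1:
            raise ValueError("EBV accuracy must lie in [0, 1]")

    @property
    def is_phenotypic(self) -> bool:
        return self.kind in ("mean", "own")


# Parental-path decomposition of the genetic (co)variances of each
# phenotypic source group.  A group member's breeding value splits into a
# sire half, a dam half and a Mendelian-sampling deviation; each term
# carries the covariance matrix of the population it is drawn from.
#   - commercial half sibs: selected sire x unselected commercial dams
#   - nucleus full sibs:    selected sire x selected dam
#   - own performance:      a candidate
#   - progeny:              the (not yet selected) candidate x commercial mates
_MEMBER_VAR = {
    "hs": ((0.25, "sel_m"), (0.75, "base")),
    "fs": ((0.25, "sel_m"), (0.25, "sel_f"), (0.5, "base")),
    "own": ((1.0, "cand"),),
    "prog": ((0.25, "cand"), (0.75, "base")),
}

# covariance between two members of the same group (different dams / mates
# where applicable) - the between-family component
_WITHIN_COV = {
    "hs": ((0.25, "sel_m"),),
    "fs": ((0.25, "sel_m"), (0.25, "sel_f")),
    "own": ((1.0, "cand"),),
    "prog": ((0.25, "cand"),),
}

# covariance between members of two different phenotypic groups of the same
# candidate, through their shared ancestor paths
_PAIR_COV = {
    frozenset(("hs", "fs")): ((0.25, "sel_m"),),
    frozenset(("hs", "own")): ((0.25, "sel_m"),),
    frozenset(("fs", "own")): ((0.25, "sel_m"), (0.25, "sel_f")),
    frozenset(("prog", "fs")): ((0.125, "sel_m"), (0.125, "sel_f")),
    frozenset(("prog", "own")): ((0.5, "cand"),),
}

# covariance between a group member and the candidate's own breeding value
_CAND_COV = {
    "hs": ((0.25, "sel_m"),),
    "fs": ((0.25, "sel_m"), (0.25, "sel_f")),
    "own": ((1.0, "cand"),),
    "prog": ((0.5, "cand"),),
}

# which population an EBV source predicts: parental EBVs predict the
# selected parent, the candidate's own GEBV predicts the candidate
_EBV_POP = {"sire": "sel_m", "dam": "sel_f", "hsdams": "base", "own": "cand"}

# additive relationship between the animal behind an EBV source and the
# members of a phenotypic group, through that animal's transmitted half
_EBV_REL = {
    ("sire", "hs"): 0.5,
    ("sire", "fs"): 0.5,
    ("sire", "own"): 0.5,
    ("sire", "prog"): 0.25,
    ("dam", "fs"): 0.5,
    ("dam", "own"): 0.5,
    ("dam", "prog"): 0.25,
    ("hsdams", "hs"): 0.5,
    ("hsdams", "prog"): 0.5,
}


def _phen_pair_terms(g1: str, g2: str):
    if g1 == g2:
        return _WITHIN_COV[g1]
    return _PAIR_COV.get(frozenset((g1, g2)), ())


def _source_variance(s: InfoSource, state: PopulationState) -> float:
    if s.kind == "own":
        return state.combo(_MEMBER_VAR["own"], s.env_x, s.env_x) + state.var_e
    if s.kind == "mean":
        member = state.combo(_MEMBER_VAR[s.group], s.env_x, s.env_x)
        within = state.combo(_WITHIN_COV[s.group], s.env_x, s.env_x)
        return (member + state.var_e + (s.n_records - 1) * within) / s.n_records
    if s.kind == "pooled_ebv":
        return 1.0 / s.n_pool
    return 1.0  # unit-scaled EBV / GEBV


def _ebv_sd(s: InfoSource, state: PopulationState) -> float:
    return math.sqrt(state.var(_EBV_POP[s.group], s.env_x))


def _pair_cov(a: InfoSource, b: InfoSource, state: PopulationState) -> float:
    """Covariance between two distinct sources of the same candidate."""
    if a.is_phenotypic and b.is_phenotypic:
        return state.combo(_phen_pair_terms(a.group, b.group), a.env_x, b.env_x)
    if a.is_phenotypic or b.is_phenotypic:
        phen, ebv = (a, b) if a.is_phenotypic else (b, a)
        rel = _EBV_REL.get((ebv.group, phen.group), 0.0)
        if ebv.group == "own":  # candidate's GEBV vs its own record
            rel = 1.0 if phen.group == "own" else 0.0
        if rel == 0.0:
            return 0.0
        if ebv.kind == "pooled_ebv":
            # each group member has exactly one parent in the pool
            rel /= ebv.n_pool
        pop = _EBV_POP[ebv.group]
        return (
            rel
            * ebv.accuracy
            * state.cov(pop, ebv.env_x, phen.env_x)
            / _ebv_sd(ebv, state)
        )
    # two (pooled) EBV sources
    if a.group != b.group:
        return 0.0  # EBVs of mutually unrelated animals (sire, dam, mates)
    pop = _EBV_POP[a.group]
    corr = state.cov(pop, a.env_x, b.env_x) / (
        _ebv_sd(a, state) * _ebv_sd(b, state)
    )
    return a.accuracy * b.accuracy * corr


def _g_entry(s: InfoSource, state: PopulationState, target) -> float:
    """cov(source, candidate breeding value at ``target``)."""
    if s.is_phenotypic:
        return state.combo(_CAND_COV[s.group], s.env_x, target)
    if s.relationship == 0.0:
        return 0.0
    pop = _EBV_POP[s.group]
    return (
        s.relationship
        * s.accuracy
        * state.cov(pop, s.env_x, target)
        / _ebv_sd(s, state)
    )


def source_matrices(
    sources: list[InfoSource],
    params: RNParams | None = None,
    targets=(),
    state: PopulationState | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Build (P, G) for a list of sources and a list of goal targets.

    ``targets`` is a sequence of gradient values, optionally containing the
    symbols ``'int'`` and ``'sl'``.  Pass either plain ``params`` (an
    unselected population) or an explicit :class:`PopulationState`.
    """
    if state is None:
        if params is None:
            raise ValueError("need params or state")
        state = PopulationState.unselected(params)
    n = len(sources)
    P = np.empty((n, n))
    for i, s in enumerate(sources):
        P[i, i] = _source_variance(s, state)
        for j in range(i + 1, n):
            P[i, j] = P[j, i] = _pair_cov(s, sources[j], state)
    G = np.array(
        [[_g_entry(s, state, t) for t in targets] for s in sources]
    ).reshape(n, len(tuple(targets)))
    return P, G


# ---------------------------------------------------------------------------
# Progeny-mean index (half-sib progeny groups spread over environments)
# ---------------------------------------------------------------------------

def progeny_sources(grid: EnvGrid, n_per_env: np.ndarray) -> list[InfoSource]:
    """One half-sib progeny-mean source per environment class."""
    n_per_env = np.asarray(n_per_env, dtype=float)
    if np.any(n_per_env <= 0):
        raise ValueError("progeny group sizes must be positive")
    return [
        InfoSource(
            kind="mean",
            group="prog",
            env_x=float(x),
            relationship=0.5,
            n_records=float(n),
            a_within=0.25,
            label=f"progeny_mean[{i + 1}]",
        )
        for i, (x, n) in enumerate(zip(grid.x_means, n_per_env))
    ]


def progeny_P(
    grid: EnvGrid, params: RNParams, n_per_env: np.ndarray
) -> np.ndarray:
    """Variance-covariance matrix of per-environment progeny means.

    Diagonal (sigma2_A + sigma2_e + (n_i - 1) 0.25 sigma2_A) / n_i,
    off-diagonal 0.25 cov_A(x_i, x_j), for an unselected population.
    """
    P, _ = source_matrices(progeny_sources(grid, n_per_env), params, ())
    return P


def progeny_G(grid: EnvGrid, params: RNParams) -> np.ndarray:
    """cov(progeny mean in class i, breeding value in class j) = 0.5 cov_A."""
    sources = progeny_sources(grid, np.ones(grid.n_classes))
    _, G = source_matrices(sources, params, grid.x_means)
    return G


# ---------------------------------------------------------------------------
# Genomic (per-environment GEBV) index
# ---------------------------------------------------------------------------

def gebv_accuracy(N: float, h2: float, Me: float) -> float:
    """Accuracy of a GEBV from N reference animals: sqrt(N h2 / (N h2 + Me)).

    ``Me`` is the effective number of independent chromosome segments.
    """
    if N < 0:
        raise ValueError("reference size must be non-negative")
    if not 0 < h2 < 1:
        raise ValueError("h2 must be in (0, 1)")
    if Me <= 0:
        raise ValueError("Me must be positive")
    return math.sqrt(N * h2 / (N * h2 + Me))


def gebv_sources(grid: EnvGrid, accuracies) -> list[InfoSource]:
    """Unit-variance GEBV of the candidate itself, one per environment class."""
    return [
        InfoSource(
            kind="ebv",
            group="own",
            env_x=float(x),
            relationship=1.0,
            accuracy=float(r),
            label=f"gebv[{i + 1}]",
        )
        for i, (x, r) in enumerate(zip(grid.x_means, accuracies))
    ]


def gebv_P(accuracies: np.ndarray, rg: np.ndarray) -> np.ndarray:
    """GEBV index P: unit diagonal, off-diagonals r_g,ij * r_i * r_j."""
    accuracies = np.asarray(accuracies, dtype=float)
    if np.any((accuracies < 0) | (accuracies > 1)):
        raise ValueError("accuracies must lie in [0, 1]")
    P = np.outer(accuracies, accuracies) * np.asarray(rg, dtype=float)
    np.fill_diagonal(P, 1.0)
    return P


def gebv_G(accuracies, params: RNParams, grid: EnvGrid) -> np.ndarray:
    """cov(GEBV_i, A_j) = r_g,ij * r_i * sigma_A(x_j) for unit-variance GEBV."""
    _, G = source_matrices(
        gebv_sources(grid, accuracies), params, grid.x_means
    )
    return G


def genetic_correlation_matrix(params: RNParams, grid: EnvGrid) -> np.ndarray:
    from .rn_model import genetic_covariance_matrix

    x = grid.x_means
    sd = np.sqrt([genetic_variance(params, xi) for xi in x])
    return genetic_covariance_matrix(params, x) / np.outer(sd, sd)


# ---------------------------------------------------------------------------
# Solving the index
# ---------------------------------------------------------------------------

@dataclass
class IndexSystem:
    """A solved selection index for one candidate type.

    ``G`` holds one column per environment class of the grid the index was
    solved against; ``g_int``/``g_sl`` are the covariances of the sources
    with the intercept and slope breeding values, used for responses on the
    reaction-norm scale.  ``pruned`` lists indices of redundant sources
    whose weight was fixed at zero.
    """

    P: np.ndarray
    G: np.ndarray
    weights: np.ndarray
    sigma_I: float
    sources: list[InfoSource] | None = None
    state: PopulationState | None = None
    g_int: np.ndarray | None = None
    g_sl: np.ndarray | None = None
    r_IH: float | None = None
    pruned: list[int] = field(default_factory=list)

    def index_goal_covariance(self, v: np.ndarray) -> float:
        return float(self.weights @ self.G @ v)


def _prune_redundant(P: np.ndarray) -> list[int]:
    """Indices to keep, dropping later sources nearly collinear with earlier."""
    sd = np.sqrt(np.diag(P))
    keep: list[int] = []
    for j in range(P.shape[0]):
        if sd[j] <= 0:
            continue
        redundant = any(
            abs(P[i, j]) / (sd[i] * sd[j]) > _PRUNE_CORR for i in keep
        )
        if not redundant:
            keep.append(j)
    return keep


def solve_index(
    P: np.ndarray,
    G: np.ndarray,
    v: np.ndarray,
    goal_cov: np.ndarray | None = None,
    sources: list[InfoSource] | None = None,
    state: PopulationState | None = None,
    g_int: np.ndarray | None = None,
    g_sl: np.ndarray | None = None,
) -> IndexSystem:
    """Solve b = P^-1 G v and summarize the resulting index.

    ``goal_cov`` is the genetic covariance matrix of the goal traits (the
    per-class breeding values); when given, the accuracy of the index for
    the aggregate genotype r_IH = b'Gv / (sigma_I sigma_H) is filled in.
    Sources whose index value is (numerically) a linear duplicate of an
    earlier one are pruned with zero weight rather than ridge-regularized,
    mirroring how redundant EBV sources are dropped in practice.
    """
    P = np.asarray(P, dtype=float)
    G = np.asarray(G, dtype=float)
    v = np.asarray(v, dtype=float)
    keep = _prune_redundant(P)
    pruned = [i for i in range(P.shape[0]) if i not in keep]
    Pk = P[np.ix_(keep, keep)]
    rhs = (G @ v)[keep]
    try:
        bk = np.linalg.solve(Pk, rhs)
    except np.linalg.LinAlgError as err:
        raise DegenerateIndexError(
            f"P matrix singular after pruning sources {pruned}"
        ) from err
    b = np.zeros(P.shape[0])
    b[keep] = bk
    var_I = float(b @ P @ b)
    if var_I <= 0.0:
        raise DegenerateIndexError("index variance is not positive")
    sigma_I = math.sqrt(var_I)
    r_IH = None
    if goal_cov is not None:
        sigma_H = math.sqrt(float(v @ goal_cov @ v))
        r_IH = float(b @ G @ v) / (sigma_I * sigma_H)
    return IndexSystem(
        P=P,
        G=G,
        weights=b,
        sigma_I=sigma_I,
        sources=sources,
        state=state,
        g_int=g_int,
        g_sl=g_sl,
        r_IH=r_IH,
        pruned=pruned,
    )


def _candidate_sd(
    system: IndexSystem, params: RNParams, x: float
) -> float:
    if system.state is not None:
        return math.sqrt(system.state.var("cand", x))
    return math.sqrt(genetic_variance(params, x))


def env_accuracy(
    system: IndexSystem, params: RNParams, grid: EnvGrid, i: int
) -> float:
    """Accuracy of the index for the breeding value in environment class i."""
    num = float(system.weights @ system.G[:, i])
    den = system.sigma_I * _candidate_sd(system, params, grid.x_means[i])
    return num / den


def accuracy_profile(
    P: np.ndarray, G: np.ndarray, params: RNParams, grid: EnvGrid
) -> np.ndarray:
    """Per-class accuracy, re-solving the index for each single-class goal.

    For class i the goal is v = e_i, i.e. the index that best predicts the
    breeding value expressed in that environment.
    """
    out = np.empty(grid.n_classes)
    for i in range(grid.n_classes):
        v = np.zeros(grid.n_classes)
        v[i] = 1.0
        sys_i = solve_index(P, G, v)
        out[i] = env_accuracy(sys_i, params, grid, i)
    return out


# ---------------------------------------------------------------------------
# Conventional evaluation (ignoring GxE)
# ---------------------------------------------------------------------------

def conventional_collapse_progeny(
    P: np.ndarray, G: np.ndarray, n_per_env: np.ndarray
) -> tuple[float, np.ndarray]:
    """Pool per-environment progeny means into one overall progeny mean.

    All elements of P are averaged with weights n_i n_j / (sum n)^2 and the
    columns of G with weights n_i / sum n, which is exactly the variance
    of, and covariances with, the across-environment progeny average.
    """
    n = np.asarray(n_per_env, dtype=float)
    w = n / n.sum()
    P_bar = float(w @ np.asarray(P) @ w)
    G_bar = w @ np.asarray(G)
    return P_bar, G_bar


def conventional_progeny_accuracies(
    P: np.ndarray,
    G: np.ndarray,
    n_per_env: np.ndarray,
    params: RNParams,
    grid: EnvGrid,
) -> np.ndarray:
    """Per-class accuracy of the single pooled progeny mean."""
    P_bar, G_bar = conventional_collapse_progeny(P, G, n_per_env)
    sd_a = np.sqrt([genetic_variance(params, x) for x in grid.x_means])
    return G_bar / (math.sqrt(P_bar) * sd_a)


def conventional_collapse_gebv(
    accuracies: np.ndarray, params: RNParams, grid: EnvGrid
) -> IndexSystem:
    """Index over per-environment GEBV that ignores GxE.

    The weights maximize response in A_int under the (wrong) assumption
    that every GEBV predicts one and the same trait: P_conv has
    off-diagonals r_i r_j and the goal covariances are g_i = r_i.  The
    returned system carries the *true* P (with genetic correlations) so
    that sigma_I and the accuracies below are genuine correlations, and G
    on the unit-genetic-variance scale (G[i, j] = r_g,ij r_i).
    """
    accuracies = np.asarray(accuracies, dtype=float)
    rg = genetic_correlation_matrix(params, grid)
    P_naive = np.outer(accuracies, accuracies)
    np.fill_diagonal(P_naive, 1.0)
    keep = _prune_redundant(P_naive)
    b = np.zeros(len(accuracies))
    b[keep] = np.linalg.solve(P_naive[np.ix_(keep, keep)], accuracies[keep])
    P_true = gebv_P(accuracies, rg)
    sigma_I = math.sqrt(float(b @ P_true @ b))
    G_unit = rg * accuracies[:, None]  # G[i, j] = r_g,ij * r_i
    return IndexSystem(
        P=P_true,
        G=G_unit,
        weights=b,
        sigma_I=sigma_I,
        pruned=[i for i in range(len(accuracies)) if i not in keep],
    )


def conventional_gebv_accuracies(
    accuracies: np.ndarray, params: RNParams, grid: EnvGrid
) -> np.ndarray:
    """Per-class accuracy of the GxE-ignoring genomic index.

    The genetic variance in the evaluated environment is set to one, i.e.
    accuracy_i = b' (r_g[:, i] * r) / sigma_I.
    """
    sys_conv = conventional_collapse_gebv(accuracies, params, grid)
    return sys_conv.weights @ sys_conv.G / sys_conv.sigma_I
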