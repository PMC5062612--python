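"""Run configuration: the scalar parameter set driving every calculation.

All inputs of the package are scalars (genetic variances, selected
proportions, population sizes, ...).  :class:`RunConfig` collects them with
the basic values as defaults, round-trips losslessly through YAML, and
rejects unknown keys so typos in config files fail loudly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from .breeding_goal import BreedingGoal, proportional_goal, resilience_goal
from .env_grid import EnvGrid, build_env_grid
from .rn_model import RNParams
from .scheme_engine import SchemeConfig

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    """Scalar inputs of a run, defaulting to the basic parameter set."""

    var_int: float = 0.3
    var_sl: float = 0.05
    r_int_sl: float = 0.0
    var_e: float = 0.7
    p_male: float = 0.05
    p_female: float = 0.20
    n_progeny_per_dam: int = 10
    n_nucleus: int = 2000
    n_commercial: float = 100.0
    ref_size: float = 5000.0
    Me: float = 1200.0
    L_progeny_sires: float = 1.6
    inner_bound: float = 2.0
    n_inner: int = 11
    goal: str = "proportional"
    scheme: str = "genomic"
    resilience_rate: float = 0.3
    seed: int = 1

    def __post_init__(self) -> None:
        if self.goal not in ("proportional", "resilience"):
            raise ValueError(f"unknown goal {self.goal!r}")
        if self.scheme not in ("sib", "progeny", "genomic"):
            raise ValueError(f"unknown scheme {self.scheme!r}")

    # -- construction -----------------------------------------------------

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must contain a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)
        )

    def config_hash(self) -> str:
        """Short stable hash of the resolved parameter set, for run logs."""
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    # -- derived objects --------------------------------------------------

    def params(self) -> RNParams:
        import math

        return RNParams(
            var_int=self.var_int,
            var_sl=self.var_sl,
            cov_int_sl=self.r_int_sl * math.sqrt(self.var_int * self.var_sl),
            var_e=self.var_e,
        )

    def grid(self) -> EnvGrid:
        return build_env_grid(self.inner_bound, self.n_inner)

    def breeding_goal(self, grid: EnvGrid | None = None) -> BreedingGoal:
        grid = grid if grid is not None else self.grid()
        if self.goal == "proportional":
            return proportional_goal(grid)
        return resilience_goal(grid, rate=self.resilience_rate)

    def scheme_config(
        self, goal: BreedingGoal | None = None, **overrides
    ) -> SchemeConfig:
        if goal is None:
            goal = self.breeding_goal()
        kwargs = dict(
            scheme=self.scheme,
            goal=goal,
            p_male=self.p_male,
            p_female=self.p_female,
            n_nucleus=self.n_nucleus,
            n_progeny_per_dam=self.n_progeny_per_dam,
            n_commercial=self.n_commercial,
            ref_size=self.ref_size,
            Me=self.Me,
        )
        kwargs.update(overrides)
        cfg = SchemeConfig(**kwargs)
        if cfg.scheme == "progeny" and "L_male" not in overrides:
            cfg = dataclasses.replace(cfg, L_male=self.L_progeny_sires)
        return cfg
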