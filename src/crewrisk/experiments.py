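"""Scenario experiments: sweeps, level combinations, and the phase surface.

Three experiment families sit on top of the engine:

* one-factor sweeps over conformity or formal-rule awareness (trajectory
  comparison);
* the 3x3 low/middle/high combination matrix with boxplot summaries of the
  replicate steady-state rates;
* the (conformity, rule-awareness) phase surface of ensemble-mean unsafe
  rates at checkpoint days, with a low-rate region mask.

All scenarios in a family share the same master seed, so replicate draws are
paired across scenarios and comparisons are matched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ScenarioConfig
from .engine import Ensemble, run_replicates

__all__ = [
    "LevelMap",
    "ScenarioSummary",
    "PhaseSurface",
    "conformity_sweep",
    "rule_awareness_sweep",
    "high_norm_config",
    "combo_matrix",
    "phase_surface",
]

DEFAULT_CHECKPOINTS = (50, 100, 150, 200)


@dataclass(frozen=True)
class LevelMap:
    """Low/middle/high anchor values for the two behavioral weights."""

    conformity: dict = field(
        default_factory=lambda: {"L": 0.05, "M": 0.4, "H": 0.9}
    )
    rule_awareness: dict = field(
        default_factory=lambda: {"L": 0.1, "M": 0.4, "H": 0.9}
    )

    def __post_init__(self) -> None:
        for name, levels in (("conformity", self.conformity), ("rule_awareness", self.rule_awareness)):
            vals = [levels[k] for k in ("L", "M", "H")]
            if not all(0.0 <= v <= 1.0 for v in vals):
                raise ValueError(f"{name} levels must lie in [0, 1], got {vals}")
            if not vals[0] < vals[1] < vals[2]:
                raise ValueError(f"{name} levels must be strictly increasing, got {vals}")


@dataclass
class ScenarioSummary:
    """Boxplot summary (Tukey 1.5 IQR whiskers) of replicate steady-state rates."""

    label: str
    conformity: float
    rule_awareness: float
    rates: np.ndarray

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)

    @property
    def mean(self) -> float:
        return float(self.rates.mean())

    @property
    def q1(self) -> float:
        return float(np.percentile(self.rates, 25))

    @property
    def median(self) -> float:
        return float(np.percentile(self.rates, 50))

    @property
    def q3(self) -> float:
        return float(np.percentile(self.rates, 75))

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1

    @property
    def whisker_low(self) -> float:
        lo = self.q1 - 1.5 * self.iqr
        inside = self.rates[self.rates >= lo]
        return float(inside.min()) if inside.size else self.q1

    @property
    def whisker_high(self) -> float:
        hi = self.q3 + 1.5 * self.iqr
        inside = self.rates[self.rates <= hi]
        return float(inside.max()) if inside.size else self.q3

    @property
    def outliers(self) -> np.ndarray:
        return self.rates[(self.rates < self.whisker_low) | (self.rates > self.whisker_high)]


@dataclass
class PhaseSurface:
    """Ensemble-mean unsafe rates over a (conformity, rule-awareness) grid.

    ``rates[t, i, j]`` is the ensemble-mean unsafe rate at checkpoint day
    ``checkpoints[t]`` for ``c_grid[i]`` and ``a_grid[j]``.
    """

    c_grid: np.ndarray
    a_grid: np.ndarray
    checkpoints: tuple
    rates: np.ndarray

    def low_rate_mask(self, checkpoint: int, threshold: float = 0.1) -> np.ndarray:
        """Boolean mask of grid cells whose mean rate is below ``threshold``."""
        t = self.checkpoints.index(checkpoint)
        return self.rates[t] < threshold

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t, day in enumerate(self.checkpoints):
            for i, c in enumerate(self.c_grid):
                for j, a in enumerate(self.a_grid):
                    rows.append((day, c, a, self.rates[t, i, j]))
        return pd.DataFrame(rows, columns=["checkpoint", "conformity", "rule_awareness", "mean_rate"])


def conformity_sweep(base_config: ScenarioConfig, c_values) -> dict[float, Ensemble]:
    """One paired-seed ensemble per conformity value, all else fixed."""
    c_values = list(c_values)
    if not c_values:
        raise ValueError("c_values must be non-empty")
    return {
        float(c): run_replicates(base_config.replace(conformity=float(c)))
        for c in c_values
    }


def high_norm_config(base_config: ScenarioConfig, wn_low: float = 0.6, wn_high: float = 0.9) -> ScenarioConfig:
    """Variant with strict/high-level management norms and low conformity,
    the regime in which rule awareness is meant to be examined."""
    return base_config.replace(conformity=0.05, wn_low=wn_low, wn_high=wn_high)


def rule_awareness_sweep(base_config: ScenarioConfig, a_values) -> dict[float, Ensemble]:
    """One paired-seed ensemble per rule-awareness value, all else fixed."""
    a_values = list(a_values)
    if not a_values:
        raise ValueError("a_values must be non-empty")
    return {
        float(a): run_replicates(base_config.replace(rule_awareness=float(a)))
        for a in a_values
    }


def combo_matrix(
    base_config: ScenarioConfig, level_map: LevelMap | None = None
) -> dict[str, ScenarioSummary]:
    """The nine L/M/H combination scenarios, labelled 'L-L' ... 'H-H'.

    The first letter is the conformity level, the second the rule-awareness
    level; each summary holds the replicate steady-state rates.
    """
    level_map = level_map or LevelMap()
    out: dict[str, ScenarioSummary] = {}
    for ck, c in level_map.conformity.items():
        for ak, a in level_map.rule_awareness.items():
            ens = run_replicates(
                base_config.replace(conformity=c, rule_awareness=a)
            )
            label = f"{ck}-{ak}"
            out[label] = ScenarioSummary(label, c, a, ens.steady_state_rates())
    return out


def phase_surface(
    base_config: ScenarioConfig,
    c_grid,
    a_grid,
    checkpoints=DEFAULT_CHECKPOINTS,
) -> PhaseSurface:
    """Ensemble-mean unsafe rate at each checkpoint day over a (c, a) grid."""
    c_grid = np.asarray(list(c_grid), dtype=float)
    a_grid = np.asarray(list(a_grid), dtype=float)
    checkpoints = tuple(int(t) for t in checkpoints)
    if c_grid.size == 0 or a_grid.size == 0:
        raise ValueError("c_grid and a_grid must be non-empty")
    for t in checkpoints:
        if not 1 <= t <= base_config.n_days:
            raise ValueError(
                f"checkpoint {t} outside simulation horizon 1..{base_config.n_days}"
            )
    rates = np.zeros((len(checkpoints), c_grid.size, a_grid.size))
    for i, c in enumerate(c_grid):
        for j, a in enumerate(a_grid):
            ens = run_replicates(
                base_config.replace(conformity=float(c), rule_awareness=float(a))
            )
            mean = ens.day_mean
            for t_idx, day in enumerate(checkpoints):
                rates[t_idx, i, j] = mean[day - 1]
    return PhaseSurface(c_grid, a_grid, checkpoints, rates)
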