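"""Population state and the day-by-day simulation loop.

The engine advances all workers synchronously.  On each day, for every
worker:

1. a Bernoulli(site_risk) draw decides whether the worker is in a dangerous
   environment; unexposed workers behave safely and their state is untouched;
2. an exposed worker faces an actual risk drawn from the truncated normal
   N(ar_mu, ar_sigma^2) on [0, 1] and attempts to discover the hazard
   (probability safety_awareness x safety_knowledge);
3. a discovering worker forms a risk-acceptance threshold from their own
   attitude, the mean previous-day acceptance of their k nearest colleagues
   and their management norm, compares it with the perceived risk
   (coefficient x actual risk) and behaves unsafely iff perceived risk is
   below the threshold; an undetected hazard yields no deliberate decision
   (configurable);
4. unsafe behavior triggers an accident with probability accident_prob;
5. the attitude is updated from the outcome and the perception coefficient
   moves inversely with the attitude change.

Random-draw contract (what makes replay and the straight-line oracle exact):
each day consumes, in order, four length-N uniform vectors -- exposure,
actual-risk quantile, discovery, accident -- plus, only when
``eps_halfwidth > 0``, one uniform disturbance vector.  Vectors are drawn for
all workers regardless of exposure so the stream does not depend on
outcomes.  Initialization consumes, in order, the perception coefficients
U(p0_low, p0_high) and the management norms U(wn_low, wn_high).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .config import ConfigError, EnvironmentParams, ScenarioConfig
from .topology import TeamLayout, build_layout

__all__ = [
    "Population",
    "Trajectory",
    "Ensemble",
    "init_population",
    "step_day",
    "run_simulation",
    "run_replicates",
    "steady_state_rate",
    "truncated_normal_ppf",
]


def truncated_normal_ppf(u, mu: float, sigma: float, lo: float = 0.0, hi: float = 1.0):
    """Quantile function of N(mu, sigma^2) truncated to [lo, hi].

    Used so each actual-risk value costs exactly one uniform draw.
    """
    a = ndtr((lo - mu) / sigma)
    b = ndtr((hi - mu) / sigma)
    return mu + sigma * ndtri(a + np.asarray(u) * (b - a))


@dataclass
class Population:
    """Struct-of-arrays state for the whole crew (length-N float arrays)."""

    layout: TeamLayout
    safety_awareness: np.ndarray
    safety_knowledge: np.ndarray
    safety_attitude: np.ndarray
    perception_coeff: np.ndarray
    conformity: np.ndarray
    rule_awareness: np.ndarray
    management_norm: np.ndarray
    risk_acceptance: np.ndarray
    last_behavior: np.ndarray  # int8, 0 safe / 1 unsafe
    had_accident: np.ndarray  # bool

    @property
    def n_workers(self) -> int:
        return self.safety_attitude.shape[0]

    def copy(self) -> "Population":
        return Population(
            self.layout,
            *(getattr(self, f).copy() for f in (
                "safety_awareness", "safety_knowledge", "safety_attitude",
                "perception_coeff", "conformity", "rule_awareness",
                "management_norm", "risk_acceptance", "last_behavior",
                "had_accident",
            )),
        )


@dataclass
class Trajectory:
    """Per-day population summaries for one run."""

    n_workers: int
    unsafe_count: np.ndarray
    accident_count: np.ndarray
    exposure_count: np.ndarray
    mean_attitude: np.ndarray
    mean_acceptance: np.ndarray

    @property
    def n_days(self) -> int:
        return self.unsafe_count.shape[0]

    @property
    def days(self) -> np.ndarray:
        """1-based day index."""
        return np.arange(1, self.n_days + 1)

    @property
    def unsafe_rate(self) -> np.ndarray:
        return self.unsafe_count / self.n_workers

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "day": self.days,
                "unsafe_count": self.unsafe_count,
                "unsafe_rate": self.unsafe_rate,
                "accident_count": self.accident_count,
                "exposure_count": self.exposure_count,
                "mean_AT": self.mean_attitude,
                "mean_RA": self.mean_acceptance,
            }
        )


@dataclass
class Ensemble:
    """Replicate trajectories for one scenario plus cross-replicate summaries."""

    config: ScenarioConfig
    trajectories: list[Trajectory]

    @property
    def replicates(self) -> int:
        return len(self.trajectories)

    @property
    def rates(self) -> np.ndarray:
        """unsafe_rate matrix, shape (replicates, n_days)."""
        return np.vstack([t.unsafe_rate for t in self.trajectories])

    @property
    def day_mean(self) -> np.ndarray:
        return self.rates.mean(axis=0)

    @property
    def day_sd(self) -> np.ndarray:
        if self.replicates == 1:
            return np.zeros(self.trajectories[0].n_days)
        return self.rates.std(axis=0, ddof=1)

    def steady_state_rates(self, window: int | None = None) -> np.ndarray:
        """Per-replicate mean unsafe rate over the final ``window`` days."""
        window = self.config.steady_window if window is None else window
        return np.array(
            [steady_state_rate(t, window) for t in self.trajectories]
        )

    def steady_state_rate(self, window: int | None = None) -> float:
        return float(self.steady_state_rates(window).mean())

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for rep, traj in enumerate(self.trajectories):
            f = traj.to_frame()
            f.insert(0, "replicate", rep)
            frames.append(f)
        return pd.concat(frames, ignore_index=True)


def init_population(config: ScenarioConfig, rng: np.random.Generator) -> Population:
    """Draw the initial crew state.

    All workers start with the configured awareness/knowledge/attitude;
    perception coefficients and management norms are drawn per worker.  The
    risk acceptance is seeded with the initial attitude so the day-1
    colleague effect is defined.
    """
    config.validate()
    n = config.n_workers
    layout = build_layout(n, config.n_cols, config.n_rows, config.k_neighbors)
    p0 = rng.uniform(config.p0_low, config.p0_high, n)
    wn = rng.uniform(config.env.wn_low, config.env.wn_high, n)
    return Population(
        layout=layout,
        safety_awareness=np.full(n, config.sa0),
        safety_knowledge=np.full(n, config.sk0),
        safety_attitude=np.full(n, config.at0),
        perception_coeff=p0,
        conformity=np.full(n, config.conformity),
        rule_awareness=np.full(n, config.rule_awareness),
        management_norm=wn,
        risk_acceptance=np.full(n, config.at0),
        last_behavior=np.zeros(n, dtype=np.int8),
        had_accident=np.zeros(n, dtype=bool),
    )


def step_day(
    pop: Population,
    env: EnvironmentParams,
    rng: np.random.Generator,
    count_undetected_as_unsafe: bool = False,
) -> dict:
    """Advance the population one day in place; return the daily record."""
    n = pop.n_workers
    u_exposure = rng.random(n)
    u_ar = rng.random(n)
    u_discover = rng.random(n)
    if env.eps_halfwidth > 0:
        eps = rng.uniform(-env.eps_halfwidth, env.eps_halfwidth, n)
    else:
        eps = np.zeros(n)
    u_accident = rng.random(n)

    exposed = u_exposure < env.site_risk
    actual_risk = truncated_normal_ppf(u_ar, env.ar_mu, env.ar_sigma)
    discovered = exposed & (u_discover < pop.safety_awareness * pop.safety_knowledge)

    # colleague effect uses everyone's previous-day acceptance
    if pop.layout.neighbor_table.shape[1] > 0:
        colleague = pop.risk_acceptance[pop.layout.neighbor_table].mean(axis=1)
    else:  # degenerate one-worker team: fall back to own acceptance
        colleague = pop.risk_acceptance.copy()

    ra_formed = np.clip(
        (1.0 - pop.rule_awareness)
        * ((1.0 - pop.conformity) * pop.safety_attitude + pop.conformity * colleague)
        + pop.rule_awareness * pop.management_norm
        + eps,
        0.0,
        1.0,
    )
    perceived = pop.perception_coeff * actual_risk

    unsafe = discovered & (perceived < ra_formed)
    if count_undetected_as_unsafe:
        unsafe = unsafe | (exposed & ~discovered)
    accident = unsafe & (u_accident < env.accident_probability)

    at_prev = pop.safety_attitude
    at_new = np.clip(
        at_prev
        + np.where(
            unsafe, np.where(accident, -env.delta_accident, env.delta_lucky), 0.0
        ),
        0.0,
        1.0,
    )

    pop.risk_acceptance = np.where(discovered, ra_formed, pop.risk_acceptance)
    pop.perception_coeff = np.maximum(
        pop.perception_coeff - (at_new - at_prev), env.p_floor
    )
    pop.safety_attitude = at_new
    pop.last_behavior = unsafe.astype(np.int8)
    pop.had_accident = pop.had_accident | accident

    return {
        "unsafe_count": int(unsafe.sum()),
        "accident_count": int(accident.sum()),
        "exposure_count": int(exposed.sum()),
        "mean_attitude": float(at_new.mean()),
        "mean_acceptance": float(pop.risk_acceptance.mean()),
    }


def run_simulation(
    config: ScenarioConfig, seed: int | np.random.SeedSequence
) -> Trajectory:
    """One seeded run of ``config.n_days`` days; deterministic given (config, seed)."""
    config.validate()
    rng = np.random.default_rng(seed)
    pop = init_population(config, rng)
    d = config.n_days
    rec = {k: np.zeros(d) for k in ("mean_attitude", "mean_acceptance")}
    cnt = {k: np.zeros(d, dtype=np.int64) for k in ("unsafe_count", "accident_count", "exposure_count")}
    for day in range(d):
        r = step_day(pop, config.env, rng, config.count_undetected_as_unsafe)
        for k in cnt:
            cnt[k][day] = r[k]
        for k in rec:
            rec[k][day] = r[k]
    return Trajectory(
        n_workers=config.n_workers,
        unsafe_count=cnt["unsafe_count"],
        accident_count=cnt["accident_count"],
        exposure_count=cnt["exposure_count"],
        mean_attitude=rec["mean_attitude"],
        mean_acceptance=rec["mean_acceptance"],
    )


def replicate_seeds(config: ScenarioConfig) -> list[np.random.SeedSequence]:
    """Deterministic per-replicate seed sequences spawned from the master seed."""
    return np.random.SeedSequence(config.master_seed).spawn(config.replicates)


def run_replicates(config: ScenarioConfig) -> Ensemble:
    """Run the full replicate ensemble for one scenario."""
    config.validate()
    return Ensemble(config, [run_simulation(config, s) for s in replicate_seeds(config)])


def steady_state_rate(trajectory: Trajectory, window: int = 50) -> float:
    """Mean unsafe rate over the trailing ``window`` days of one run."""
    if not 1 <= window <= trajectory.n_days:
        raise ValueError(
            f"window must lie in [1, {trajectory.n_days}], got {window}"
        )
    return float(trajectory.unsafe_rate[-window:].mean())
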