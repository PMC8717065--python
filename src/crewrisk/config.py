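"""Scenario configuration: defaults, validation, JSON round-trip.

The defaults describe the reference crew: 200 workers on a 20x10 grid
simulated for 200 working days with 30 replicates, site risk 0.45, initial
safety awareness and knowledge 0.8, initial attitude 0.5, perception
coefficient drawn from U(0.4, 1) and per-worker management norms from
U(0.1, 0.9).  Conformity and formal-rule awareness default to their middle
levels (0.4 each).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

__all__ = ["ConfigError", "EnvironmentParams", "ScenarioConfig", "load_config"]


class ConfigError(ValueError):
    """Invalid configuration; the message names the offending field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


@dataclass(frozen=True)
class EnvironmentParams:
    """Site environment: hazard exposure, objective risk, norms, feedback.

    ``site_risk`` is the per-worker per-day probability of being in a
    dangerous environment; ``accident_prob`` is the conditional accident
    probability given unsafe behavior and defaults to the site risk.  The
    actual risk a worker faces on an exposed day follows a normal
    distribution N(ar_mu, ar_sigma^2) truncated to [0, 1].  Management norms
    are per-worker constants drawn once from U(wn_low, wn_high).
    ``delta_accident``/``delta_lucky`` are the attitude-feedback magnitudes
    and ``eps_halfwidth`` the half-width of the uniform disturbance on the
    risk-acceptance equation (0 disables it).
    """

    site_risk: float = 0.45
    ar_mu: float = 0.5
    ar_sigma: float = 0.15
    accident_prob: float | None = None
    wn_low: float = 0.1
    wn_high: float = 0.9
    eps_halfwidth: float = 0.0
    delta_accident: float = 0.1
    delta_lucky: float = 0.02
    p_floor: float = 0.01

    @property
    def accident_probability(self) -> float:
        return self.site_risk if self.accident_prob is None else self.accident_prob

    def validate(self) -> None:
        for name in ("site_risk",):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(name, f"must lie in [0, 1], got {v}")
        if self.accident_prob is not None and not 0.0 <= self.accident_prob <= 1.0:
            raise ConfigError("accident_prob", f"must lie in [0, 1], got {self.accident_prob}")
        if self.ar_sigma <= 0:
            raise ConfigError("ar_sigma", f"must be positive, got {self.ar_sigma}")
        if not 0.0 <= self.wn_low <= self.wn_high <= 1.0:
            raise ConfigError(
                "wn_low/wn_high",
                f"need 0 <= wn_low <= wn_high <= 1, got ({self.wn_low}, {self.wn_high})",
            )
        for name in ("eps_halfwidth", "delta_accident", "delta_lucky"):
            if getattr(self, name) < 0:
                raise ConfigError(name, f"must be non-negative, got {getattr(self, name)}")
        if self.p_floor <= 0:
            raise ConfigError("p_floor", f"must be positive, got {self.p_floor}")


@dataclass(frozen=True)
class ScenarioConfig:
    """Full recipe for one replicate ensemble."""

    n_workers: int = 200
    n_cols: int = 20
    n_rows: int = 10
    n_days: int = 200
    replicates: int = 30
    conformity: float = 0.4
    rule_awareness: float = 0.4
    sa0: float = 0.8
    sk0: float = 0.8
    at0: float = 0.5
    p0_low: float = 0.4
    p0_high: float = 1.0
    k_neighbors: int = 20
    steady_window: int = 50
    # an undetected hazard produces no deliberate risk decision and is not
    # counted as an unsafe act unless this flag is set
    count_undetected_as_unsafe: bool = False
    master_seed: int = 0
    env: EnvironmentParams = EnvironmentParams()

    def validate(self) -> None:
        if self.n_workers < 1:
            raise ConfigError("n_workers", f"must be >= 1, got {self.n_workers}")
        if self.n_cols * self.n_rows != self.n_workers:
            raise ConfigError(
                "n_cols/n_rows",
                f"grid {self.n_cols}x{self.n_rows} does not hold n_workers={self.n_workers}",
            )
        if self.n_days < 1:
            raise ConfigError("n_days", f"must be >= 1, got {self.n_days}")
        if self.replicates < 1:
            raise ConfigError("replicates", f"must be >= 1, got {self.replicates}")
        for name in ("conformity", "rule_awareness", "sa0", "sk0", "at0"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(name, f"must lie in [0, 1], got {v}")
        if not 0.0 < self.p0_low <= self.p0_high:
            raise ConfigError(
                "p0_low/p0_high",
                f"need 0 < p0_low <= p0_high, got ({self.p0_low}, {self.p0_high})",
            )
        if self.k_neighbors < 1:
            raise ConfigError("k_neighbors", f"must be >= 1, got {self.k_neighbors}")
        if not 1 <= self.steady_window <= self.n_days:
            raise ConfigError(
                "steady_window",
                f"must lie in [1, n_days={self.n_days}], got {self.steady_window}",
            )
        self.env.validate()

    # -- serialization --------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["env"] = dataclasses.asdict(self.env)
        return d

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "ScenarioConfig":
        data = dict(data)
        env_fields = {f.name for f in dataclasses.fields(EnvironmentParams)}
        env_data = dict(data.pop("env", {}))
        # flat env keys are accepted for CLI-override convenience
        for key in list(data):
            if key in env_fields:
                env_data[key] = data.pop(key)
        cfg_fields = {f.name for f in dataclasses.fields(cls)}
        for key in data:
            if key not in cfg_fields:
                raise ConfigError(key, "unknown configuration key")
        for key in env_data:
            if key not in env_fields:
                raise ConfigError(f"env.{key}", "unknown configuration key")
        # keep the trailing-window default usable on short horizons
        if "steady_window" not in data and "n_days" in data:
            data["steady_window"] = min(50, int(data["n_days"]))
        cfg = cls(**data, env=EnvironmentParams(**env_data)) if env_data else cls(**data)
        cfg.validate()
        return cfg

    def replace(self, **updates: Any) -> "ScenarioConfig":
        """Return a validated copy with ``updates`` applied (flat env keys ok)."""
        d = self.to_dict()
        env_fields = {f.name for f in dataclasses.fields(EnvironmentParams)}
        for key, value in updates.items():
            if key in env_fields:
                d["env"][key] = value
            else:
                d[key] = value
        return ScenarioConfig.from_dict(d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")


def load_config(source: str | Path | Mapping[str, Any] | None = None, **overrides: Any) -> ScenarioConfig:
    """Build a validated config from a JSON file, a mapping, or nothing.

    Keyword overrides take precedence over the file/mapping contents; unset
    fields fall back to the reference defaults.
    """
    data: dict[str, Any] = {}
    if source is not None:
        if isinstance(source, (str, Path)):
            path = Path(source)
            if not path.exists():
                raise FileNotFoundError(f"config file not found: {path}")
            data = json.loads(path.read_text())
        else:
            data = dict(source)
    data.update({k: v for k, v in overrides.items() if v is not None})
    return ScenarioConfig.from_dict(data)
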