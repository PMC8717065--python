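"""Deterministic miniature crews for step-through and oracle tests."""

from __future__ import annotations

import numpy as np

from .config import ScenarioConfig
from .engine import Population, init_population

__all__ = ["fixture_config", "make_fixture_team"]

_FIELD_NAMES = (
    "safety_awareness",
    "safety_knowledge",
    "safety_attitude",
    "perception_coeff",
    "conformity",
    "rule_awareness",
    "management_norm",
    "risk_acceptance",
)


def fixture_config(n: int = 6, **updates) -> ScenarioConfig:
    """A small scenario config on an (n/2) x 2 grid (default 3x2, 6 workers)."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if n == 1:
        n_cols, n_rows = 1, 1
    elif n % 2 == 0:
        n_cols, n_rows = n // 2, 2
    else:
        n_cols, n_rows = n, 1
    cfg = ScenarioConfig(
        n_workers=n, n_cols=n_cols, n_rows=n_rows, n_days=10, replicates=2,
        steady_window=5,
    )
    return cfg.replace(**updates) if updates else cfg


def make_fixture_team(
    n: int = 6,
    overrides: dict[int, dict[str, float]] | None = None,
    seed: int = 0,
    config: ScenarioConfig | None = None,
) -> Population:
    """A small deterministic team with optionally pinned per-worker values.

    ``overrides`` maps worker id -> {field name -> value}, applied verbatim
    after the seeded initialization, e.g. ``{0: {"safety_attitude": 0.9}}``.
    """
    cfg = config if config is not None else fixture_config(n)
    pop = init_population(cfg, np.random.default_rng(seed))
    for worker_id, fields in (overrides or {}).items():
        if not 0 <= worker_id < pop.n_workers:
            raise ValueError(f"unknown worker id {worker_id}")
        for name, value in fields.items():
            if name not in _FIELD_NAMES:
                raise ValueError(f"unknown worker field {name!r}")
            getattr(pop, name)[worker_id] = value
    return pop
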