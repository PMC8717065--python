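"""Per-worker safety-cognition kernel.

Each function below is one stage of the five-stage safety-cognition chain a
construction worker runs through on an exposed day:

1. hazard discovery        -- Bernoulli on safety awareness x safety knowledge
2. risk perception         -- perceived risk = perception coefficient x actual risk
3. risk acceptance         -- convex mix of own attitude, colleague acceptance and
                              the management norm, weighted by conformity and
                              formal-rule awareness
4. behavior choice         -- unsafe iff perceived risk falls below acceptance
                              (risk-homeostasis logic)
5. accident + feedback     -- accidents lower the safety attitude, lucky escapes
                              raise it; the perception coefficient moves inversely
                              with the attitude

All functions are stateless: every input, including the uniform random draw,
is explicit, so the same chain can be replayed step by step in tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "WorkerState",
    "discover_hazard",
    "update_perception_coeff",
    "perceived_risk",
    "risk_acceptance",
    "decide_behavior",
    "accident_outcome",
    "update_attitude",
    "clamp01",
]

#: lower bound kept on the perception coefficient; the attitude-coupled update
#: is unbounded below and a non-positive coefficient would invert risk semantics
P_FLOOR = 0.01


def clamp01(x: float) -> float:
    """Clamp a level/probability to the unit interval."""
    return 0.0 if x < 0.0 else (1.0 if x > 1.0 else x)


def _check_unit(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")


@dataclass
class WorkerState:
    """Cognitive and behavioral state of a single worker.

    Levels (awareness, knowledge, attitude, acceptance, conformity, rule
    awareness) are fractions in [0, 1]; the perception coefficient is a
    positive multiplier (>1 over-estimates risk, <1 under-estimates).
    ``last_behavior`` is 0 for safe, 1 for unsafe.
    """

    id: int
    position: tuple[int, int] = (0, 0)
    safety_awareness: float = 0.8
    safety_knowledge: float = 0.8
    safety_attitude: float = 0.5
    perception_coeff: float = 0.7
    conformity: float = 0.4
    rule_awareness: float = 0.4
    management_norm: float = 0.5
    risk_acceptance: float = 0.5
    last_behavior: int = 0
    had_accident: bool = False

    def __post_init__(self) -> None:
        for name in (
            "safety_awareness",
            "safety_knowledge",
            "safety_attitude",
            "conformity",
            "rule_awareness",
            "management_norm",
            "risk_acceptance",
        ):
            _check_unit(name, getattr(self, name))
        if self.perception_coeff <= 0:
            raise ValueError(
                f"perception_coeff must be positive, got {self.perception_coeff!r}"
            )
        if self.last_behavior not in (0, 1):
            raise ValueError(f"last_behavior must be 0 or 1, got {self.last_behavior!r}")


def discover_hazard(sa: float, sk: float, u: float) -> int:
    """Hazard-discovery stage.

    The worker notices the hazard with probability ``sa * sk``: low awareness
    means the worker does not look, poor knowledge means the worker cannot
    recognize what they see.

    Parameters
    ----------
    sa, sk : float
        Safety awareness and safety knowledge, in [0, 1].
    u : float
        Uniform draw in [0, 1).

    Returns
    -------
    int
        1 if the hazard is discovered, else 0.
    """
    _check_unit("sa", sa)
    _check_unit("sk", sk)
    if not 0.0 <= u < 1.0:
        raise ValueError(f"u must lie in [0, 1), got {u!r}")
    return 1 if u < sa * sk else 0


def update_perception_coeff(
    p_prev: float, at_now: float, at_prev: float, floor: float = P_FLOOR
) -> float:
    """Move the perception coefficient inversely with the attitude change.

    A worker whose attitude shifted toward risk-taking (attitude up) perceives
    the same objective hazard as smaller, and vice versa.  The coefficient is
    floored at ``floor`` so it stays positive.
    """
    if p_prev <= 0:
        raise ValueError(f"p_prev must be positive, got {p_prev!r}")
    return max(p_prev - (at_now - at_prev), floor)


def perceived_risk(p: float, ar: float) -> float:
    """Subjective risk estimate: perception coefficient times actual risk."""
    if p <= 0:
        raise ValueError(f"p must be positive, got {p!r}")
    _check_unit("ar", ar)
    return p * ar


def risk_acceptance(
    at: float, co: float, wn: float, a: float, c: float, eps: float = 0.0
) -> float:
    """Risk-acceptance threshold formed in the perceptual-reaction stage.

    ``(1-a)`` of the weight goes to the internally formed standard -- itself a
    ``(1-c)/c`` mix of the worker's own safety attitude ``at`` and the
    colleagues' acceptance ``co`` -- and ``a`` goes to the management norm
    ``wn``.  ``eps`` is a zero-mean disturbance for everything the model does
    not represent.  The result is clamped to [0, 1].
    """
    for name, value in (("at", at), ("co", co), ("wn", wn), ("a", a), ("c", c)):
        _check_unit(name, value)
    return clamp01((1.0 - a) * ((1.0 - c) * at + c * co) + a * wn + eps)


def decide_behavior(pr: float, ra: float) -> int:
    """Behavior choice: unsafe (1) iff perceived risk is below acceptance.

    A worker who perceives less danger than they are willing to tolerate takes
    the risk; perceived danger at or above the threshold yields safe behavior
    (ties resolve to safe).
    """
    if pr < 0:
        raise ValueError(f"pr must be non-negative, got {pr!r}")
    _check_unit("ra", ra)
    return 1 if pr < ra else 0


def accident_outcome(ub: int, accident_prob: float, u: float) -> int:
    """Accident stage: only unsafe behavior can end in an accident.

    Given unsafe behavior, an accident occurs with probability
    ``accident_prob`` (by default the site risk itself).
    """
    if ub not in (0, 1):
        raise ValueError(f"ub must be 0 or 1, got {ub!r}")
    _check_unit("accident_prob", accident_prob)
    if not 0.0 <= u < 1.0:
        raise ValueError(f"u must lie in [0, 1), got {u!r}")
    return 1 if (ub == 1 and u < accident_prob) else 0


def update_attitude(
    at: float,
    ub: int,
    accident: int,
    delta_accident: float = 0.1,
    delta_lucky: float = 0.02,
) -> float:
    """Attitude feedback after the day's outcome.

    An accident is a hard corrective: attitude drops by ``delta_accident``.
    Getting away with unsafe behavior breeds complacency: attitude rises by
    ``delta_lucky``.  Safe behavior leaves the attitude unchanged.  The result
    is clamped to [0, 1].
    """
    _check_unit("at", at)
    if delta_accident < 0 or delta_lucky < 0:
        raise ValueError("delta_accident and delta_lucky must be non-negative")
    if ub not in (0, 1):
        raise ValueError(f"ub must be 0 or 1, got {ub!r}")
    if ub == 0:
        return at
    if accident:
        return clamp01(at - delta_accident)
    return clamp01(at + delta_lucky)
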