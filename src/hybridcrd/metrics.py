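"""Stationary observables and substitution/addition control comparisons.

Given the stationary distribution P(k) of the social-learning chain, the
observables reported for a scenario are the average cooperation level

    Cbar = sum_k P(k) * k / Z

and the average group success

    sbar_G = sum_k P(k) * s_G(k),

where s_G(k) is the probability that a group assembled at population
state k (adaptive seats drawn hypergeometrically, agent block realized
all-or-none with probability p) reaches the threshold M.

Hybrid performance is judged against a non-hybrid control population:

substitution
    the a agent seats replace adaptive members, so the control keeps the
    full group size N with a -> 0;
addition
    the a agents are appended to an existing team, so the control is the
    smaller all-adaptive group with a -> 0 and N -> N - a.

Both deltas are (hybrid - control) on the same metric.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from math import comb
from typing import Literal

import numpy as np

from .dynamics import ModelSpec, StationaryResult, binom_safe, stationary_distribution
from .game import HybridConfig, heaviside

ControlMode = Literal["substitution", "addition"]

# float dust this small on a probability is clamped rather than rejected
_UNIT_TOL = 1e-9


def _unit_clip(x: float) -> float:
    if -_UNIT_TOL <= x <= 1.0 + _UNIT_TOL:
        return min(1.0, max(0.0, x))
    return x

__all__ = [
    "MetricReport",
    "ControlDelta",
    "avg_cooperation",
    "group_success_state",
    "group_success_vector",
    "avg_group_success",
    "metric_report",
    "control_spec",
    "control_delta",
]


@dataclass(frozen=True)
class MetricReport:
    """Cooperation level, success rate, and the per-state success profile."""

    coop_level: float
    group_success: float
    per_state_success: np.ndarray
    stationary: StationaryResult

    def __post_init__(self) -> None:
        if not 0.0 <= self.coop_level <= 1.0:
            raise ValueError(f"cooperation level out of [0, 1]: {self.coop_level}")
        if not 0.0 <= self.group_success <= 1.0:
            raise ValueError(f"group success out of [0, 1]: {self.group_success}")


@dataclass(frozen=True)
class ControlDelta:
    """Hybrid-minus-control differences for one control mode."""

    mode: ControlMode
    delta_coop: float
    delta_success: float
    hybrid_report: MetricReport
    control_report: MetricReport


def avg_cooperation(stat: StationaryResult) -> float:
    """Stationary mean fraction of cooperators, sum_k P(k) k/Z."""
    Z = stat.spec.pop.Z
    k = np.arange(Z + 1)
    return _unit_clip(float(np.dot(stat.distribution, k / Z)))


def group_success_state(k: int, spec: ModelSpec) -> float:
    """Probability a group drawn at population state ``k`` meets the threshold.

    Multivariate hypergeometric over the ``N - a`` adaptive seats (h of
    them cooperators), with the agent block adding ``a`` cooperators with
    probability ``p``:

        s_G(k) = C(Z, N-a)^-1 sum_h C(k, h) C(Z-k, N-a-h)
                 * ( p * theta(h + a - M) + (1-p) * theta(h - M) )
    """
    Z = spec.pop.Z
    if not 0 <= k <= Z:
        raise ValueError(f"cooperator count k={k} outside [0, Z={Z}]")
    g = spec.n_adaptive
    a, p, M = spec.hybrid.a, spec.hybrid.p, spec.game.M
    total = 0.0
    for h in range(g + 1):
        w = binom_safe(k, h) * binom_safe(Z - k, g - h)
        if w:
            total += w * (p * heaviside(h + a - M) + (1.0 - p) * heaviside(h - M))
    return _unit_clip(total / comb(Z, g))


def group_success_vector(spec: ModelSpec) -> np.ndarray:
    """s_G(k) for every k = 0..Z."""
    return np.array([group_success_state(k, spec) for k in range(spec.pop.Z + 1)])


def avg_group_success(stat: StationaryResult) -> float:
    """Stationary-weighted success rate, sum_k P(k) s_G(k)."""
    return _unit_clip(float(np.dot(stat.distribution, group_success_vector(stat.spec))))


def metric_report(spec: ModelSpec, stat: StationaryResult | None = None) -> MetricReport:
    """Compute all stationary observables for one model instance."""
    if stat is None:
        stat = stationary_distribution(spec)
    per_state = group_success_vector(spec)
    return MetricReport(
        coop_level=avg_cooperation(stat),
        group_success=_unit_clip(float(np.dot(stat.distribution, per_state))),
        per_state_success=per_state,
        stationary=stat,
    )


def control_spec(spec: ModelSpec, mode: ControlMode) -> ModelSpec:
    """Non-hybrid control instance for a hybrid spec.

    substitution keeps the group size (a -> 0, N unchanged); addition
    removes the agent seats entirely (a -> 0, N -> N - a).  ``p`` is
    zeroed alongside ``a`` — it is formally inert once a = 0, and zeroing
    prevents accidental use.
    """
    if spec.hybrid.a == 0:
        raise ValueError("control of a non-hybrid spec (a = 0) is undefined")
    if mode == "substitution":
        game = spec.game
    elif mode == "addition":
        game = replace(spec.game, N=spec.game.N - spec.hybrid.a)
    else:
        raise ValueError(f"unknown control mode {mode!r}")
    return ModelSpec(game=game, hybrid=HybridConfig(a=0, p=0.0), pop=spec.pop)


def control_delta(spec: ModelSpec, mode: ControlMode) -> ControlDelta:
    """Hybrid-vs-control comparison: Delta = metric(hybrid) - metric(control)."""
    hybrid_rep = metric_report(spec)
    control_rep = metric_report(control_spec(spec, mode))
    return ControlDelta(
        mode=mode,
        delta_coop=hybrid_rep.coop_level - control_rep.coop_level,
        delta_success=hybrid_rep.group_success - control_rep.group_success,
        hybrid_report=hybrid_rep,
        control_report=control_rep,
    )
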