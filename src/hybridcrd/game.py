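"""One-shot collective-risk dilemma payoffs, plain and hybrid.

The collective-risk dilemma (CRD) is an N-player threshold public goods
game: each player holds an endowment ``b`` and either cooperates,
contributing a fraction ``c`` of it, or defects and keeps everything.
If fewer than ``M`` of the N players cooperate, every player loses the
remainder of their endowment with probability ``r``.

Hybrid groups attach a block of ``a`` fixed-behavior agents to the
``N - a`` adaptive seats.  The block cooperates *as a whole* with
probability ``p`` in each interaction: with probability ``p`` all ``a``
agents contribute, with probability ``1 - p`` none do.  This perfectly
correlated two-point mixture is the model; the agents are not
independent Bernoulli(p) contributors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

Strategy = Literal["C", "D"]

__all__ = [
    "GameParams",
    "HybridConfig",
    "heaviside",
    "payoff_defector",
    "payoff_cooperator",
    "expected_payoff",
]


@dataclass(frozen=True)
class GameParams:
    """Definition of one CRD game.

    Parameters
    ----------
    N : int
        Group size (total seats, adaptive plus fixed agents), >= 2.
    M : int
        Cooperator threshold needed to avert the risk, >= 1.  M > N is
        permitted and describes a group that can never reach the
        threshold on its own — the addition-control baseline of a hybrid
        team whose adaptive members alone cannot succeed.
    r : float
        Risk probability in [0, 1]: chance of losing everything when
        the group falls short of M cooperators.
    b : float
        Initial endowment (currency units), > 0.
    c : float
        Fraction of the endowment a cooperator contributes, in (0, 1).
    """

    N: int
    M: int
    r: float
    b: float = 1.0
    c: float = 0.1

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError(f"group size N must be >= 2, got {self.N}")
        if self.M < 1:
            raise ValueError(f"threshold M must be >= 1, got {self.M}")
        if not 0.0 <= self.r <= 1.0:
            raise ValueError(f"risk probability r must lie in [0, 1], got {self.r}")
        if self.b <= 0:
            raise ValueError(f"endowment b must be positive, got {self.b}")
        if not 0.0 < self.c < 1.0:
            raise ValueError(f"contribution fraction c must lie in (0, 1), got {self.c}")


@dataclass(frozen=True)
class HybridConfig:
    """Fixed-behavior agent block attached to each group.

    ``a`` agents occupy seats in every group and cooperate as a single
    block with probability ``p`` per interaction.  ``a = 0`` encodes a
    non-hybrid (all-adaptive) control group, in which case ``p`` is inert.
    """

    a: int
    p: float

    def __post_init__(self) -> None:
        if self.a < 0:
            raise ValueError(f"agent count a must be >= 0, got {self.a}")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"agent cooperation probability p must lie in [0, 1], got {self.p}")


def heaviside(x: int) -> int:
    """Unit step with the threshold-game convention theta(0) = 1.

    Every threshold comparison in the package routes through here so
    the boundary convention lives in exactly one place.
    """
    return 0 if x < 0 else 1


def _check_j(j: int, params: GameParams) -> None:
    if not 0 <= j <= params.N:
        raise ValueError(f"cooperator count j={j} outside [0, N={params.N}]")


def payoff_defector(j: int, params: GameParams) -> float:
    """Expected payoff of a defector in a group with ``j`` cooperators.

    pi_D(j) = b * (1 - r + r * theta(j - M)): the full endowment when the
    threshold is met, the endowment discounted by the risk otherwise.
    """
    _check_j(j, params)
    return params.b * (1.0 - params.r + params.r * heaviside(j - params.M))


def payoff_cooperator(j: int, params: GameParams) -> float:
    """Expected payoff of a cooperator: pi_C(j) = pi_D(j) - c*b.

    ``j`` counts the cooperator itself, so ``j >= 1``.  The payoff may be
    negative (contribution lost on top of a missed threshold at r = 1);
    no clamping is applied.
    """
    if j < 1:
        raise ValueError(f"a cooperator is present, so j must be >= 1, got {j}")
    _check_j(j, params)
    return payoff_defector(j, params) - params.c * params.b


def expected_payoff(strategy: Strategy, i: int, hybrid: HybridConfig, params: GameParams) -> float:
    """Expected payoff of an adaptive C or D over the agent block's action.

    ``i`` is the number of adaptive cooperators in the group counting the
    focal player itself when it cooperates (callers resolve the "+1 for
    self" bookkeeping).  The agent block contributes ``a`` cooperators
    with probability ``p`` and none otherwise:

        Pi_s(i, a, p) = p * pi_s(i + a) + (1 - p) * pi_s(i)
    """
    n_adaptive = params.N - hybrid.a
    if not 0 <= i <= n_adaptive:
        raise ValueError(f"adaptive cooperator count i={i} outside [0, N-a={n_adaptive}]")
    if strategy == "C":
        if i < 1:
            raise ValueError("a focal cooperator implies i >= 1")
        pay = payoff_cooperator
    elif strategy == "D":
        pay = payoff_defector
    else:
        raise ValueError(f"strategy must be 'C' or 'D', got {strategy!r}")
    p = hybrid.p
    return p * pay(i + hybrid.a, params) + (1.0 - p) * pay(i, params)
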