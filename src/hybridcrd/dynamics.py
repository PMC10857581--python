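"""Finite-population social-learning dynamics of the hybrid CRD.

A well-mixed population of ``Z`` adaptive individuals, each holding a pure
strategy C or D, evolves by pairwise-comparison imitation with mutation.
Groups of ``N - a`` adaptive seats are sampled without replacement from the
population and joined by the fixed agent block, so an individual's fitness
is its payoff averaged over the multivariate hypergeometric distribution of
co-player compositions.  The number of cooperators ``k`` performs a
birth-death Markov chain on ``{0, ..., Z}``; with mutation the chain is
ergodic and its unique stationary distribution ``P(k)`` carries all
long-run observables.

Two transition conventions are exposed:

``with-mutation`` (default)
    T+(k) = ((Z-k)/Z) * ( mu + (1-mu) * (k/(Z-1)) * P(D->C) )
    T-(k) = (k/Z)     * ( mu + (1-mu) * ((Z-k)/(Z-1)) * P(C->D) )
    The standard pairwise-comparison rule with an additive mutation
    inflow; matches the verbal update protocol (with probability mu the
    focal flips unconditionally) and keeps the chain ergodic.

``printed``
    The same expressions without the additive ``mu`` term.  Under this
    form the boundary states are absorbing and no unique stationary
    distribution exists; it is retained for inspection only and
    :func:`stationary_distribution` refuses it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb, exp
from typing import Literal

import numpy as np

from .game import GameParams, HybridConfig, expected_payoff

TransitionsMode = Literal["with-mutation", "printed"]

__all__ = [
    "PopulationParams",
    "ModelSpec",
    "StationaryResult",
    "binom_safe",
    "fitness_cooperator",
    "fitness_defector",
    "fitness_vectors",
    "fermi_probability",
    "transition_plus",
    "transition_minus",
    "transition_matrix",
    "stationary_distribution",
]

# Fermi exponents are clamped here before exponentiation; beyond this the
# probability is 0 or 1 to double precision anyway.
_EXP_CLAMP = 700.0


@dataclass(frozen=True)
class PopulationParams:
    """Adaptive-population constants: size Z, mutation mu, selection beta."""

    Z: int
    mu: float
    beta: float

    def __post_init__(self) -> None:
        if self.Z < 2:
            raise ValueError(f"population size Z must be >= 2, got {self.Z}")
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError(f"mutation probability mu must lie in [0, 1], got {self.mu}")
        if self.beta < 0:
            raise ValueError(f"selection strength beta must be >= 0, got {self.beta}")


@dataclass(frozen=True)
class ModelSpec:
    """One fully specified model instance: game, agent block, population."""

    game: GameParams
    hybrid: HybridConfig
    pop: PopulationParams

    def __post_init__(self) -> None:
        n_adaptive = self.game.N - self.hybrid.a
        if n_adaptive < 1:
            raise ValueError(
                f"need at least one adaptive seat per group: N={self.game.N}, a={self.hybrid.a}"
            )
        if self.pop.Z < n_adaptive:
            raise ValueError(
                f"population Z={self.pop.Z} too small to fill N-a={n_adaptive} adaptive seats"
            )

    @property
    def n_adaptive(self) -> int:
        """Adaptive seats per group, N - a."""
        return self.game.N - self.hybrid.a


@dataclass(frozen=True)
class StationaryResult:
    """Stationary distribution P(k) over k = 0..Z with provenance."""

    distribution: np.ndarray
    spec: ModelSpec
    method: str = "eigenvector"
    residual: float = field(default=0.0)

    def __post_init__(self) -> None:
        d = np.asarray(self.distribution, dtype=float)
        if d.ndim != 1 or d.shape[0] != self.spec.pop.Z + 1:
            raise ValueError("distribution must be a vector over k = 0..Z")
        if not np.isclose(d.sum(), 1.0, atol=1e-12):
            raise ValueError("stationary distribution must sum to 1")
        if (d < 0).any():
            raise ValueError("stationary distribution must be non-negative")


def binom_safe(n: int, r: int) -> int:
    """C(n, r) for 0 <= r <= n, else 0.

    The out-of-domain convention makes the hypergeometric sums in the
    fitness and success formulas evaluate cleanly at the boundary states
    (k = 0 with a C focal, k = Z with a D focal) instead of erroring.
    """
    if r < 0 or n < 0 or r > n:
        return 0
    return comb(n, r)


def _check_k(k: int, Z: int) -> None:
    if not 0 <= k <= Z:
        raise ValueError(f"cooperator count k={k} outside [0, Z={Z}]")


def fitness_cooperator(k: int, spec: ModelSpec) -> float:
    """Expected payoff of a cooperator when the population holds ``k`` Cs.

    Averages the hybrid payoff over all multivariate hypergeometric draws
    of the focal's ``N - a - 1`` adaptive co-players from the other
    ``Z - 1`` individuals (``i`` cooperators among them, the focal's own
    cooperation adds one).  Returns 0 at k = 0 by convention; the
    dynamics never consume that value (the imitation factor k/(Z-1)
    vanishes there).
    """
    Z = spec.pop.Z
    _check_k(k, Z)
    if k == 0:
        return 0.0
    g = spec.n_adaptive  # adaptive seats per group
    total = 0.0
    for i in range(g):
        w = binom_safe(k - 1, i) * binom_safe(Z - k, g - 1 - i)
        if w:
            total += w * expected_payoff("C", i + 1, spec.hybrid, spec.game)
    return total / comb(Z - 1, g - 1)


def fitness_defector(k: int, spec: ModelSpec) -> float:
    """Expected payoff of a defector at population state ``k``.

    Mirror of :func:`fitness_cooperator` with the focal excluded from the
    cooperator pool; 0 by convention at k = Z.
    """
    Z = spec.pop.Z
    _check_k(k, Z)
    if k == Z:
        return 0.0
    g = spec.n_adaptive
    total = 0.0
    for i in range(g):
        w = binom_safe(k, i) * binom_safe(Z - k - 1, g - 1 - i)
        if w:
            total += w * expected_payoff("D", i, spec.hybrid, spec.game)
    return total / comb(Z - 1, g - 1)


def fitness_vectors(spec: ModelSpec) -> tuple[np.ndarray, np.ndarray]:
    """(f_C(k), f_D(k)) over k = 0..Z as arrays."""
    Z = spec.pop.Z
    fc = np.array([fitness_cooperator(k, spec) for k in range(Z + 1)])
    fd = np.array([fitness_defector(k, spec) for k in range(Z + 1)])
    return fc, fd


def fermi_probability(f_role_model: float, f_focal: float, beta: float) -> float:
    """Pairwise-comparison imitation probability 1/(1 + exp(-beta*(f_rm - f_focal)))."""
    if beta < 0:
        raise ValueError(f"selection strength beta must be >= 0, got {beta}")
    x = -beta * (f_role_model - f_focal)
    x = max(-_EXP_CLAMP, min(_EXP_CLAMP, x))
    return 1.0 / (1.0 + exp(x))


def transition_plus(k: int, spec: ModelSpec, mode: TransitionsMode = "with-mutation") -> float:
    """Probability T+(k) that the cooperator count rises from k to k+1."""
    Z = spec.pop.Z
    _check_k(k, Z)
    if k == Z:
        return 0.0
    mu, beta = spec.pop.mu, spec.pop.beta
    p_dc = 0.0
    if k > 0:
        p_dc = fermi_probability(fitness_cooperator(k, spec), fitness_defector(k, spec), beta)
    imitation = (1.0 - mu) * (k / (Z - 1)) * p_dc
    inflow = mu + imitation if mode == "with-mutation" else imitation
    return ((Z - k) / Z) * inflow


def transition_minus(k: int, spec: ModelSpec, mode: TransitionsMode = "with-mutation") -> float:
    """Probability T-(k) that the cooperator count falls from k to k-1."""
    Z = spec.pop.Z
    _check_k(k, Z)
    if k == 0:
        return 0.0
    mu, beta = spec.pop.mu, spec.pop.beta
    p_cd = 0.0
    if k < Z:
        p_cd = fermi_probability(fitness_defector(k, spec), fitness_cooperator(k, spec), beta)
    imitation = (1.0 - mu) * ((Z - k) / (Z - 1)) * p_cd
    inflow = mu + imitation if mode == "with-mutation" else imitation
    return (k / Z) * inflow


def transition_vectors(
    spec: ModelSpec, mode: TransitionsMode = "with-mutation"
) -> tuple[np.ndarray, np.ndarray]:
    """(T+, T-) over k = 0..Z, sharing one fitness evaluation per state."""
    Z = spec.pop.Z
    mu, beta = spec.pop.mu, spec.pop.beta
    fc, fd = fitness_vectors(spec)
    tp = np.zeros(Z + 1)
    tm = np.zeros(Z + 1)
    for k in range(Z + 1):
        if k < Z:
            p_dc = fermi_probability(fc[k], fd[k], beta) if k > 0 else 0.0
            imit = (1.0 - mu) * (k / (Z - 1)) * p_dc
            tp[k] = ((Z - k) / Z) * (mu + imit if mode == "with-mutation" else imit)
        if k > 0:
            p_cd = fermi_probability(fd[k], fc[k], beta) if k < Z else 0.0
            imit = (1.0 - mu) * ((Z - k) / (Z - 1)) * p_cd
            tm[k] = (k / Z) * (mu + imit if mode == "with-mutation" else imit)
    return tp, tm


def transition_matrix(spec: ModelSpec, mode: TransitionsMode = "with-mutation") -> np.ndarray:
    """Row-stochastic tridiagonal (Z+1)x(Z+1) transition matrix of the chain."""
    tp, tm = transition_vectors(spec, mode)
    Z = spec.pop.Z
    S = np.zeros((Z + 1, Z + 1))
    for k in range(Z + 1):
        if k < Z:
            S[k, k + 1] = tp[k]
        if k > 0:
            S[k, k - 1] = tm[k]
        S[k, k] = 1.0 - tp[k] - tm[k]
    return S


def _product_form(tp: np.ndarray, tm: np.ndarray) -> np.ndarray:
    """Closed-form birth-death stationary vector P(k) ∝ prod_j T+(j)/T-(j+1).

    Accumulated in log space so long products at Z ~ 100 neither overflow
    nor underflow.
    """
    Z = tp.shape[0] - 1
    logw = np.zeros(Z + 1)
    for k in range(1, Z + 1):
        logw[k] = logw[k - 1] + np.log(tp[k - 1]) - np.log(tm[k])
    logw -= logw.max()
    w = np.exp(logw)
    return w / w.sum()


def stationary_distribution(
    spec: ModelSpec,
    mode: TransitionsMode = "with-mutation",
    method: str = "eigenvector",
    cross_check_tol: float = 1e-8,
) -> StationaryResult:
    """Unique stationary distribution of the social-learning chain.

    The default method solves for the eigenvalue-1 left eigenvector of
    the row-stochastic transition matrix and cross-validates it against
    the birth-death product form P(k) T+(k) = P(k+1) T-(k+1);
    disagreement beyond ``cross_check_tol`` in sup norm raises.  The
    *returned* probabilities are the product-form values: the closed
    form is exact to floating-point rounding and satisfies detailed
    balance componentwise, whereas the raw eigenvector carries O(eps)
    absolute noise that swamps the tiny tail entries in relative terms.
    ``method='product_form'`` skips the eigen cross-check.

    Raises
    ------
    ValueError
        If ``mu == 0`` or ``mode == 'printed'``: the boundary states are
        then absorbing and the stationary distribution is not unique.
    """
    if spec.pop.mu == 0:
        raise ValueError(
            "mu = 0 makes k = 0 and k = Z absorbing; the stationary distribution "
            "is not unique. Use mu > 0."
        )
    if mode == "printed":
        raise ValueError(
            "the 'printed' transition form has no mutation inflow, so the boundary "
            "states absorb and no unique stationary distribution exists; use "
            "mode='with-mutation' (transition_matrix still exposes the printed form)."
        )
    tp, tm = transition_vectors(spec, mode)
    ref = _product_form(tp, tm)
    if method == "product_form":
        return StationaryResult(ref, spec, method="product_form", residual=0.0)

    Z = spec.pop.Z
    S = np.zeros((Z + 1, Z + 1))
    for k in range(Z + 1):
        if k < Z:
            S[k, k + 1] = tp[k]
        if k > 0:
            S[k, k - 1] = tm[k]
        S[k, k] = 1.0 - tp[k] - tm[k]
    # left eigenvector of S == right eigenvector of S^T at eigenvalue 1
    vals, vecs = np.linalg.eig(S.T)
    idx = int(np.argmin(np.abs(vals - 1.0)))
    v = np.real(vecs[:, idx])
    v = np.abs(v)
    v = np.clip(v, 0.0, None)
    v /= v.sum()
    residual = float(np.max(np.abs(v - ref)))
    if residual > cross_check_tol:
        raise ArithmeticError(
            f"eigenvector and product-form stationary vectors disagree "
            f"(sup-norm {residual:.3e} > {cross_check_tol:.1e})"
        )
    return StationaryResult(ref, spec, method="eigenvector", residual=residual)
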