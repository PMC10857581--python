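"""Fitness averaging, Fermi imitation, and the birth-death chain."""

import itertools
import math

import numpy as np
import pytest

from hybridcrd import (
    GameParams,
    HybridConfig,
    ModelSpec,
    PopulationParams,
    expected_payoff,
    fermi_probability,
    fitness_cooperator,
    fitness_defector,
    stationary_distribution,
    transition_matrix,
    transition_minus,
    transition_plus,
)
from hybridcrd.dynamics import binom_safe

from conftest import build_spec


def enumerate_fitness(strategy: str, k: int, spec: ModelSpec) -> float:
    """Brute-force fitness oracle: average the hybrid payoff over every
    co-player subset of the other Z-1 individuals (no hypergeometric
    shortcut)."""
    Z = spec.pop.Z
    g = spec.n_adaptive
    focal_c = strategy == "C"
    others = [True] * (k - (1 if focal_c else 0)) + [False] * (Z - k - (0 if focal_c else 1))
    assert len(others) == Z - 1
    total = 0.0
    count = 0
    for mates in itertools.combinations(range(Z - 1), g - 1):
        i = sum(others[m] for m in mates) + (1 if focal_c else 0)
        total += expected_payoff(strategy, i, spec.hybrid, spec.game)
        count += 1
    assert count == math.comb(Z - 1, g - 1)
    return total / count


@pytest.mark.parametrize("n,r,expected", [(5, 2, 10), (-1, 0, 0), (3, 5, 0), (0, 0, 1), (4, -1, 0)])
def test_binom_safe_boundary_convention(n, r, expected):
    assert binom_safe(n, r) == expected


@pytest.mark.parametrize("a,p", [(0, 0.0), (2, 0.5), (3, 0.2), (4, 0.9)])
@pytest.mark.parametrize("k", [1, 4, 9])
def test_fitness_matches_exhaustive_enumeration(a, p, k):
    """The hypergeometric fitness sums equal brute-force averaging over
    all co-player subsets of a Z = 10 population."""
    spec = build_spec(Z=10, r=0.7, a=a, p=p)
    assert fitness_cooperator(k, spec) == pytest.approx(
        enumerate_fitness("C", k, spec), abs=1e-12
    )
    assert fitness_defector(k, spec) == pytest.approx(
        enumerate_fitness("D", k, spec), abs=1e-12
    )


def test_fitness_boundary_conventions(toy_spec):
    """f_C(0) and f_D(Z) are defined as 0 and never consumed by the chain."""
    Z = toy_spec.pop.Z
    assert fitness_cooperator(0, toy_spec) == 0.0
    assert fitness_defector(Z, toy_spec) == 0.0
    # full-cooperation state: the C fitness is the all-cooperator payoff
    full = expected_payoff("C", toy_spec.n_adaptive, toy_spec.hybrid, toy_spec.game)
    assert fitness_cooperator(Z, toy_spec) == pytest.approx(full)
    # zero-cooperation state: the D fitness is the all-defector payoff
    empty = expected_payoff("D", 0, toy_spec.hybrid, toy_spec.game)
    assert fitness_defector(0, toy_spec) == pytest.approx(empty)


def test_risk_free_fitness_gap_is_minus_cb():
    """At r = 0 payoffs are composition-independent, so f_C - f_D = -c*b."""
    spec = build_spec(r=0.0, a=2, p=0.5)
    for k in range(1, spec.pop.Z):
        gap = fitness_cooperator(k, spec) - fitness_defector(k, spec)
        assert gap == pytest.approx(-0.1, abs=1e-12)


def test_vandermonde_normalization():
    """The hypergeometric fitness weights form a probability distribution."""
    Z, g = 30, 5
    for k in range(1, Z + 1):
        total = sum(binom_safe(k - 1, i) * binom_safe(Z - k, g - 1 - i) for i in range(g))
        assert total == math.comb(Z - 1, g - 1)


def test_fermi_probability_shape():
    assert fermi_probability(1.0, 1.0, 2.0) == pytest.approx(0.5)
    assert fermi_probability(3.0, -1.0, 0.0) == pytest.approx(0.5)
    assert fermi_probability(0.0, 0.1, 2.0) == pytest.approx(1 / (1 + math.exp(0.2)))
    # strictly increasing in the fitness advantage over a moderate range
    diffs = [-4.0, -1.0, -0.1, 0.0, 0.1, 1.0, 4.0]
    probs = [fermi_probability(d, 0.0, 5.0) for d in diffs]
    assert all(0.0 < q < 1.0 for q in probs)
    assert probs == sorted(probs)
    # overflow-safe at extreme differences (saturates without error)
    assert fermi_probability(1e6, 0.0, 5.0) == pytest.approx(1.0)
    assert fermi_probability(-1e6, 0.0, 5.0) == pytest.approx(0.0, abs=1e-300)


def test_transition_boundaries(paper_spec):
    Z = paper_spec.pop.Z
    mu = paper_spec.pop.mu
    assert transition_plus(Z, paper_spec) == 0.0
    assert transition_minus(0, paper_spec) == 0.0
    assert transition_plus(0, paper_spec) == pytest.approx(mu)
    assert transition_minus(Z, paper_spec) == pytest.approx(mu)


def test_neutral_transition_symmetry():
    """At beta = 0 relabeling C <-> D maps T-(k) onto T+(Z-k)."""
    spec = build_spec(r=0.7, a=2, p=0.5, beta=0.0, Z=30)
    for k in range(31):
        assert transition_minus(k, spec) == pytest.approx(
            transition_plus(30 - k, spec), abs=1e-14
        )


def test_printed_transitions_lack_mutation_inflow():
    """The printed form has absorbing boundaries: T+(0) = T-(Z) = 0."""
    spec = build_spec(r=0.7, a=2, p=0.5, Z=20)
    assert transition_plus(0, spec, mode="printed") == 0.0
    assert transition_minus(20, spec, mode="printed") == 0.0
    S = transition_matrix(spec, mode="printed")
    assert S[0, 0] == pytest.approx(1.0)
    assert S[20, 20] == pytest.approx(1.0)


def test_transition_matrix_is_stochastic_tridiagonal(paper_spec):
    S = transition_matrix(paper_spec)
    assert np.allclose(S.sum(axis=1), 1.0, atol=1e-14)
    assert (S >= 0).all() and (S <= 1).all()
    Z = paper_spec.pop.Z
    for i in range(Z + 1):
        for j in range(Z + 1):
            if abs(i - j) > 1:
                assert S[i, j] == 0.0


def test_mu_zero_matrix_has_absorbing_boundaries():
    spec = build_spec(r=0.7, a=2, p=0.5, Z=20, mu=0.0)
    S = transition_matrix(spec)
    assert S[0, 0] == 1.0
    assert S[20, 20] == 1.0


def test_stationary_three_state_chain_by_hand():
    """Z = 2, mu = 0.5, beta = 0: T+(0)=1/2, T+(1)=T-(1)=3/8, T-(2)=1/2,
    so the product form gives P = (3/10, 4/10, 3/10)."""
    spec = ModelSpec(
        game=GameParams(N=2, M=1, r=0.5),
        hybrid=HybridConfig(a=0, p=0.0),
        pop=PopulationParams(Z=2, mu=0.5, beta=0.0),
    )
    assert transition_plus(0, spec) == pytest.approx(0.5)
    assert transition_plus(1, spec) == pytest.approx(0.375)
    assert transition_minus(1, spec) == pytest.approx(0.375)
    assert transition_minus(2, spec) == pytest.approx(0.5)
    stat = stationary_distribution(spec)
    assert np.allclose(stat.distribution, [0.3, 0.4, 0.3], atol=1e-12)


def test_stationary_eigen_matches_product_form(paper_spec):
    eig = stationary_distribution(paper_spec, method="eigenvector")
    closed = stationary_distribution(paper_spec, method="product_form")
    assert np.max(np.abs(eig.distribution - closed.distribution)) < 1e-10
    assert eig.residual < 1e-10


def test_stationary_detailed_balance(paper_spec):
    P = stationary_distribution(paper_spec).distribution
    Z = paper_spec.pop.Z
    for k in range(Z):
        lhs = P[k] * transition_plus(k, paper_spec)
        rhs = P[k + 1] * transition_minus(k + 1, paper_spec)
        assert lhs == pytest.approx(rhs, rel=1e-10)


def test_stationary_neutral_symmetry():
    spec = build_spec(r=0.7, a=2, p=0.5, beta=0.0)
    P = stationary_distribution(spec).distribution
    assert np.allclose(P, P[::-1], atol=1e-12)


def test_stationary_refusals():
    with pytest.raises(ValueError, match="mu = 0"):
        stationary_distribution(build_spec(mu=0.0))
    with pytest.raises(ValueError, match="printed"):
        stationary_distribution(build_spec(), mode="printed")


def test_spec_validation():
    with pytest.raises(ValueError):
        build_spec(N=6, a=6)  # no adaptive seat
    with pytest.raises(ValueError):
        build_spec(Z=3, N=6, a=0)  # population cannot fill a group
    with pytest.raises(ValueError):
        PopulationParams(Z=100, mu=-0.1, beta=2.0)
    with pytest.raises(ValueError):
        fitness_cooperator(101, build_spec())
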