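"""Agent-based Monte Carlo twin of the analytical chain.

Simulates the explicit Z-agent population under the same update protocol
the transition probabilities encode: each step a focal individual is
drawn uniformly; with probability mu its strategy flips; otherwise a role
model is drawn uniformly from the other Z - 1 individuals and, when their
strategies differ, the focal imitates with the Fermi probability (a draw
of a same-strategy role model is a no-op, not resampled).

By default fitness is the exact hypergeometric expectation, so the
simulation and the analytical chain share transition probabilities
exactly and any disagreement isolates a defect in the chain construction
or the stationary solver.  A sampled-fitness mode (``groups_per_fitness``
set to an integer) estimates fitness from randomly assembled groups
instead, for robustness probes.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .dynamics import ModelSpec, fermi_probability, fitness_vectors
from .game import expected_payoff
from .metrics import group_success_vector

__all__ = ["SimulationConfig", "SimulationTrace", "run_simulation", "sample_group_success"]


@dataclass(frozen=True)
class SimulationConfig:
    spec: ModelSpec
    steps: int
    burn_in: int = 0
    seed: int = 0
    groups_per_fitness: int | str = "exact"
    record_series: bool = False
    series_thin: int = 1000

    def __post_init__(self) -> None:
        if self.burn_in < 0 or self.steps <= self.burn_in:
            raise ValueError("need steps > burn_in >= 0")
        if self.groups_per_fitness != "exact":
            if not isinstance(self.groups_per_fitness, int) or self.groups_per_fitness < 1:
                raise ValueError("groups_per_fitness must be 'exact' or an integer >= 1")


@dataclass(frozen=True)
class SimulationTrace:
    """Empirical counterparts of P(k), Cbar and sbar_G."""

    occupancy: np.ndarray
    coop_level: float
    success_estimate: float
    transitions_up: np.ndarray
    transitions_down: np.ndarray
    visits: np.ndarray
    coop_series: np.ndarray | None = None

    def to_json_summary(self) -> dict:
        return {
            "occupancy": self.occupancy.tolist(),
            "coop_level": self.coop_level,
            "success_estimate": self.success_estimate,
        }

    def write_csv(self, path: str | Path) -> None:
        """Thinned time series as CSV (columns: step, k)."""
        if self.coop_series is None:
            raise ValueError("trace was run without record_series=True")
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["step", "k"])
            writer.writerows(enumerate(self.coop_series.tolist()))

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json_summary(), indent=2))


def _sampled_fitness(
    strategies: np.ndarray, focal: int, spec: ModelSpec, n_groups: int, rng: np.random.Generator
) -> float:
    """Average payoff of ``focal`` over ``n_groups`` randomly assembled groups."""
    Z = spec.pop.Z
    others = np.delete(np.arange(Z), focal)
    g = spec.n_adaptive
    total = 0.0
    s = "C" if strategies[focal] else "D"
    for _ in range(n_groups):
        mates = rng.choice(others, size=g - 1, replace=False)
        i = int(strategies[mates].sum()) + int(strategies[focal])
        total += expected_payoff(s, i, spec.hybrid, spec.game)
    return total / n_groups


def run_simulation(config: SimulationConfig) -> SimulationTrace:
    """Run the imitation/mutation process and collect stationary statistics.

    Deterministic under a fixed seed.  Occupancy, per-state transition
    counts and visit counts are accumulated after ``burn_in`` steps; the
    success estimate re-weights the exact per-state group success by the
    empirical occupancy (the group-assembly average is analytic, so the
    estimate isolates sampling noise in the population dynamics).
    """
    spec = config.spec
    Z = spec.pop.Z
    mu, beta = spec.pop.mu, spec.pop.beta
    rng = np.random.default_rng(config.seed)
    exact = config.groups_per_fitness == "exact"

    if exact:
        fc, fd = fitness_vectors(spec)
        # imitation success probabilities per state, both directions
        p_dc = np.array([fermi_probability(fc[k], fd[k], beta) for k in range(Z + 1)])
        p_cd = np.array([fermi_probability(fd[k], fc[k], beta) for k in range(Z + 1)])

    strategies = np.zeros(Z, dtype=np.int8)
    strategies[rng.choice(Z, size=Z // 2, replace=False)] = 1
    k = int(strategies.sum())

    occupancy = np.zeros(Z + 1, dtype=np.int64)
    up = np.zeros(Z + 1, dtype=np.int64)
    down = np.zeros(Z + 1, dtype=np.int64)
    visits = np.zeros(Z + 1, dtype=np.int64)
    series: list[int] = []

    # pre-drawn random numbers in blocks keep the Python loop tight
    block = 100_000
    for start in range(0, config.steps, block):
        n = min(block, config.steps - start)
        focals = rng.integers(0, Z, size=n)
        mut_draws = rng.random(size=n)
        rm_offsets = rng.integers(1, Z, size=n)  # role model = (focal + offset) % Z, uniform over others
        imit_draws = rng.random(size=n)
        for t in range(n):
            step = start + t
            recording = step >= config.burn_in
            if recording:
                visits[k] += 1
            focal = focals[t]
            s_f = strategies[focal]
            if mut_draws[t] < mu:
                strategies[focal] = 1 - s_f
                new_k = k + (1 if s_f == 0 else -1)
            else:
                rm = (focal + rm_offsets[t]) % Z
                s_r = strategies[rm]
                new_k = k
                if s_r != s_f:
                    if exact:
                        prob = p_dc[k] if s_f == 0 else p_cd[k]
                    else:
                        f_focal = _sampled_fitness(
                            strategies, focal, spec, config.groups_per_fitness, rng
                        )
                        f_rm = _sampled_fitness(
                            strategies, rm, spec, config.groups_per_fitness, rng
                        )
                        prob = fermi_probability(f_rm, f_focal, beta)
                    if imit_draws[t] < prob:
                        strategies[focal] = s_r
                        new_k = k + (1 if s_f == 0 else -1)
            if recording:
                if new_k > k:
                    up[k] += 1
                elif new_k < k:
                    down[k] += 1
                occupancy[new_k] += 1
                if config.record_series and step % config.series_thin == 0:
                    series.append(new_k)
            k = new_k

    occ = occupancy / occupancy.sum()
    coop = float(np.dot(occ, np.arange(Z + 1) / Z))
    success = float(np.dot(occ, group_success_vector(spec)))
    return SimulationTrace(
        occupancy=occ,
        coop_level=coop,
        success_estimate=success,
        transitions_up=up,
        transitions_down=down,
        visits=visits,
        coop_series=np.array(series) if config.record_series else None,
    )


def sample_group_success(
    spec: ModelSpec, k: int, n_samples: int, seed: int | np.random.Generator = 0
) -> float:
    """Monte Carlo estimate of the per-state group success s_G(k).

    Draws ``n_samples`` groups of N - a adaptive members without
    replacement from a population with ``k`` cooperators, realizes the
    agent block all-or-none with probability p, and counts threshold
    attainment.  Unbiased for :func:`~hybridcrd.metrics.group_success_state`.
    """
    Z = spec.pop.Z
    if not 0 <= k <= Z:
        raise ValueError(f"cooperator count k={k} outside [0, Z={Z}]")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    g = spec.n_adaptive
    a, p, M = spec.hybrid.a, spec.hybrid.p, spec.game.M
    h = rng.hypergeometric(k, Z - k, g, size=n_samples)
    block = rng.random(size=n_samples) < p
    successes = np.where(block, h + a, h) >= M
    return float(successes.mean())
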