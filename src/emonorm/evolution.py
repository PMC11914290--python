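"""The evolutionary Monte Carlo loop.

One generation consists of z Monte Carlo steps. In each step a uniformly
drawn focal agent either mutates (probability mu: strategy and emotional
profile redrawn uniformly) or undergoes social learning: the focal plays z
donation games against random opponents, a distinct uniformly drawn model
agent plays z games as well, and the focal adopts the model's traits
jointly with the Fermi (pairwise-comparison) probability. Reputation
updates during fitness evaluation persist in the public state.

``run_generation``/``run_simulation`` default to a numba-compiled
per-generation kernel; ``monte_carlo_step``/``evaluate_fitness`` expose the
same dynamics step by step. Both paths are built from the same compiled
primitives and consume the identical draw sequence from a shared
``numpy.random.Generator``, so they agree exactly under a shared seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels as _k
from .metrics import Trajectory
from .model_core import (EmotionalProfile, NormPolicy, Params, Reputation,
                         Strategy, Agent)

__all__ = ["Population", "GenerationRecord", "ActTally", "fermi_probability",
           "evaluate_fitness", "monte_carlo_step", "run_generation",
           "run_simulation", "run_frozen_simulation"]


@dataclass
class Population:
    """State of the z agents as parallel integer arrays."""
    strategies: np.ndarray
    profiles: np.ndarray
    reputations: np.ndarray

    def __post_init__(self):
        self.strategies = np.ascontiguousarray(self.strategies, dtype=np.int64)
        self.profiles = np.ascontiguousarray(self.profiles, dtype=np.int64)
        self.reputations = np.ascontiguousarray(self.reputations, dtype=np.int64)
        if not (len(self.strategies) == len(self.profiles)
                == len(self.reputations)):
            raise ValueError("trait arrays must have equal length")
        if len(self.strategies) < 2:
            raise ValueError("population needs at least 2 agents")

    @property
    def z(self) -> int:
        return len(self.strategies)

    @classmethod
    def random(cls, z: int, rng: np.random.Generator) -> "Population":
        """Uniformly random strategies, profiles and reputations."""
        return cls(rng.integers(0, 4, z), rng.integers(0, 2, z),
                   rng.integers(0, 2, z))

    @classmethod
    def monomorphic(cls, strategy: Strategy, profile: EmotionalProfile,
                    z: int, rng: np.random.Generator | None = None,
                    reputation: Reputation | None = None) -> "Population":
        """All agents share one (strategy, profile); reputations random
        unless a fixed one is given."""
        if reputation is not None:
            reps = np.full(z, int(reputation))
        elif rng is not None:
            reps = rng.integers(0, 2, z)
        else:
            raise ValueError("give either rng or a fixed reputation")
        return cls(np.full(z, int(strategy)), np.full(z, int(profile)), reps)

    @classmethod
    def from_counts(cls, counts: np.ndarray,
                    rng: np.random.Generator) -> "Population":
        """Build from a (4 strategies x 2 profiles) count matrix; agent
        order follows the cells, reputations uniformly random."""
        counts = np.asarray(counts, dtype=np.int64)
        if counts.shape != (4, 2) or (counts < 0).any():
            raise ValueError("counts must be a nonnegative (4, 2) matrix")
        strategies, profiles = [], []
        for s in range(4):
            for p in range(2):
                strategies.extend([s] * int(counts[s, p]))
                profiles.extend([p] * int(counts[s, p]))
        z = int(counts.sum())
        return cls(np.array(strategies), np.array(profiles),
                   rng.integers(0, 2, z))

    def agents(self) -> list[Agent]:
        return [Agent(Strategy(int(s)), EmotionalProfile(int(p)),
                      Reputation(int(r)))
                for s, p, r in zip(self.strategies, self.profiles,
                                   self.reputations)]

    def strategy_frequencies(self) -> np.ndarray:
        return np.bincount(self.strategies, minlength=4) / self.z

    def cooperative_ep_frequency(self) -> float:
        return float((self.profiles == int(EmotionalProfile.COOPERATIVE)).mean())

    def good_frequency(self) -> float:
        return float(self.reputations.mean())


@dataclass
class GenerationRecord:
    """End-of-generation summary used to assemble a Trajectory."""
    index: int
    coop_acts: int
    total_acts: int
    strategy_freq: np.ndarray
    coop_ep_freq: float
    good_freq: float


@dataclass
class ActTally:
    """Accumulator for the generation's donation-act bookkeeping."""
    coop: int = 0
    total: int = 0

    def add(self, donations: int, acts: int) -> None:
        self.coop += donations
        self.total += acts


def fermi_probability(f_focal: float, f_model: float, beta: float) -> float:
    """Probability that the focal adopts the model's traits:
    1 / (1 + exp(-beta (f_model - f_focal)))."""
    if beta < 0:
        raise ValueError(f"beta must be >= 0, got {beta}")
    return float(_k.fermi(f_focal, f_model, beta))


def evaluate_fitness(pop: Population, focal_index: int, policy: NormPolicy,
                     params: Params, rng: np.random.Generator,
                     tally: ActTally | None = None) -> float:
    """Fitness of one agent from z games against random opponents.

    The focal plays z games with uniformly drawn partners (never itself);
    public reputations update as the games proceed. Returns the average
    payoff per game (or the sum, under ``fitness_aggregation='sum'``).
    Donation counts accrue to ``tally`` when given.
    """
    if not 0 <= focal_index < pop.z:
        raise IndexError(f"focal index {focal_index} out of range")
    pay_sum, donations = _k.play_games(
        pop.strategies, pop.profiles, pop.reputations, focal_index, pop.z,
        policy.base.table, policy.emotion.table, policy.gamma,
        params.b, params.c, params.epsilon, params.alpha, params.chi,
        params.exec_mode_code, rng)
    if tally is not None:
        tally.add(int(donations), 2 * pop.z)
    if params.fitness_aggregation == "mean":
        return float(pay_sum) / pop.z
    return float(pay_sum)


def monte_carlo_step(pop: Population, policy: NormPolicy, params: Params,
                     rng: np.random.Generator,
                     tally: ActTally | None = None) -> None:
    """One Monte Carlo step: mutation or Fermi social learning, in place."""
    z = pop.z
    focal = _k._randbelow(rng, z)
    if rng.random() < params.mu:
        pop.strategies[focal] = _k._randbelow(rng, 4)
        pop.profiles[focal] = _k._randbelow(rng, 2)
        return
    f_focal = evaluate_fitness(pop, focal, policy, params, rng, tally)
    model = _k._randbelow(rng, z - 1)
    if model >= focal:
        model += 1
    f_model = evaluate_fitness(pop, model, policy, params, rng, tally)
    if rng.random() < fermi_probability(f_focal, f_model, params.beta):
        pop.strategies[focal] = pop.strategies[model]
        pop.profiles[focal] = pop.profiles[model]


def run_generation(pop: Population, policy: NormPolicy, params: Params,
                   rng: np.random.Generator, index: int = 0,
                   use_kernel: bool = True) -> GenerationRecord:
    """z Monte Carlo steps plus the end-of-generation snapshot.

    ``use_kernel=False`` runs the step-level Python path instead of the
    compiled per-generation kernel; both give identical results for an
    identical generator state.
    """
    if use_kernel:
        coop, acts = _k.run_generation_kernel(
            pop.strategies, pop.profiles, pop.reputations,
            policy.base.table, policy.emotion.table, policy.gamma,
            params.b, params.c, params.mu, params.beta, params.epsilon,
            params.alpha, params.chi, params.exec_mode_code,
            params.fit_mode_code, rng)
        coop, acts = int(coop), int(acts)
    else:
        tally = ActTally()
        for _ in range(pop.z):
            monte_carlo_step(pop, policy, params, rng, tally)
        coop, acts = tally.coop, tally.total
    return GenerationRecord(index, coop, acts, pop.strategy_frequencies(),
                            pop.cooperative_ep_frequency(),
                            pop.good_frequency())


def _records_to_trajectory(records, params: Params,
                           seed: int | None) -> Trajectory:
    return Trajectory(
        params=params,
        coop_acts=np.array([r.coop_acts for r in records], dtype=np.int64),
        total_acts=np.array([r.total_acts for r in records], dtype=np.int64),
        strategy_freq=np.array([r.strategy_freq for r in records]),
        coop_ep_freq=np.array([r.coop_ep_freq for r in records]),
        good_freq=np.array([r.good_freq for r in records]),
        seed=seed,
    )


def run_simulation(params: Params, policy: NormPolicy,
                   rng: np.random.Generator | None = None,
                   seed: int | None = None,
                   use_kernel: bool = True) -> Trajectory:
    """One full run: random initial population, ``params.generations``
    generations, per-generation records and the run-level eta.

    Randomness comes from ``rng`` when given, else from ``seed`` (falling
    back to ``params.seed``); a fixed seed reproduces the trajectory
    exactly.
    """
    if rng is None:
        if seed is None:
            seed = params.seed
        rng = np.random.default_rng(seed)
    pop = Population.random(params.z, rng)
    records = [run_generation(pop, policy, params, rng, index=g,
                              use_kernel=use_kernel)
               for g in range(params.generations)]
    return _records_to_trajectory(records, params, seed)


def run_frozen_simulation(pop: Population, policy: NormPolicy, params: Params,
                          rng: np.random.Generator | None = None,
                          seed: int | None = None) -> Trajectory:
    """Reputation dynamics with evolution switched off.

    Trait counts are exactly preserved: each of the z steps per generation
    plays the z evaluation games of one random focal agent, with no
    mutation and no imitation. Used to compare the stochastic engine
    against the analytic frozen-composition oracle.
    """
    if rng is None:
        if seed is None:
            seed = params.seed
        rng = np.random.default_rng(seed)
    records = []
    for g in range(params.generations):
        coop, acts = _k.run_frozen_generation_kernel(
            pop.strategies, pop.profiles, pop.reputations,
            policy.base.table, policy.emotion.table, policy.gamma,
            params.b, params.c, params.epsilon, params.alpha, params.chi,
            params.exec_mode_code, rng)
        records.append(GenerationRecord(g, int(coop), int(acts),
                                        pop.strategy_frequencies(),
                                        pop.cooperative_ep_frequency(),
                                        pop.good_frequency()))
    return _records_to_trajectory(records, params, seed)
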