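"""Analytic reputation dynamics for frozen trait compositions.

Because the norms here are donor-focused — a verdict depends only on the
donor's own prior reputation, realized action and emotional profile — each
agent's reputation evolves as an autonomous two-state Markov chain once the
distribution of its own actions is fixed. For unconditional strategies
(AllC, AllD) the chain is exact; for Disc/pDisc the action distribution
depends on the population fraction of GOOD reputations, which is treated in
mean field and resolved by fixed-point iteration of the per-cell chains.

These closed forms serve as the independent oracle for the stochastic
engine in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .model_core import (EmotionalProfile, NormPolicy, Params, Strategy)

__all__ = ["FrozenComposition", "ReducibleChainError",
           "reputation_transition_kernel", "stationary_good_fraction",
           "population_good_fraction", "expected_eta_frozen"]


class ReducibleChainError(ValueError):
    """The two-state chain has no unique stationary distribution."""


@dataclass(frozen=True)
class FrozenComposition:
    """Fixed trait counts: a (4 strategies x 2 profiles) matrix summing to z."""
    counts: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=np.int64)
        if c.shape != (4, 2) or (c < 0).any() or c.sum() < 2:
            raise ValueError("counts must be a nonnegative (4, 2) matrix "
                             "with at least 2 agents")
        object.__setattr__(self, "counts", c)
        c.setflags(write=False)

    @property
    def z(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def monomorphic(cls, strategy: Strategy, profile: EmotionalProfile,
                    z: int) -> "FrozenComposition":
        c = np.zeros((4, 2), dtype=np.int64)
        c[int(strategy), int(profile)] = z
        return cls(c)

    @classmethod
    def from_dict(cls, cells: dict) -> "FrozenComposition":
        c = np.zeros((4, 2), dtype=np.int64)
        for (s, p), n in cells.items():
            c[int(s), int(p)] += n
        return cls(c)

    def weights(self) -> np.ndarray:
        return self.counts / self.z

    def cells(self):
        """Yield ((strategy, profile), weight) for occupied cells."""
        w = self.weights()
        for s in range(4):
            for p in range(2):
                if self.counts[s, p]:
                    yield (Strategy(s), EmotionalProfile(p)), float(w[s, p])


def _cooperation_prob(strategy: Strategy, good_fraction: float,
                      params: Params) -> float:
    """Probability that one realized act of this strategy is a cooperation,
    given the mean-field GOOD fraction among partners."""
    g_seen = (good_fraction * (1 - params.alpha)
              + (1 - good_fraction) * params.alpha)
    if strategy == Strategy.ALLC:
        q = 1.0
    elif strategy == Strategy.ALLD:
        q = 0.0
    elif strategy == Strategy.DISC:
        q = g_seen
    else:  # PDISC
        q = 1.0 - g_seen
    if params.execution_error_mode == "flip":
        return q * (1 - params.epsilon) + (1 - q) * params.epsilon
    return q * (1 - params.epsilon)  # coop_fails


def _good_verdict_prob(policy: NormPolicy, rep: int, action: int,
                       profile: int, chi: float) -> float:
    """P(assigned GOOD | prior rep, realized action, profile), marginal over
    the gamma coin and the chi assignment flip."""
    v = (policy.gamma * policy.emotion.table[rep, action, profile]
         + (1 - policy.gamma) * policy.base.table[rep, action])
    return (1 - chi) * v + chi * (1 - v)


def reputation_transition_kernel(composition: FrozenComposition,
                                 focal_cell: tuple,
                                 policy: NormPolicy, params: Params,
                                 good_fraction: float | None = None
                                 ) -> np.ndarray:
    """Per-judged-interaction reputation kernel for one (strategy, profile).

    Returns the 2x2 row-stochastic matrix ``K[r, r']`` over (BAD=0, GOOD=1),
    marginalizing over perception (alpha), execution (epsilon), the gamma
    coin, the norm verdict and the chi assignment flip. The partner GOOD
    fraction defaults to the self-consistent mean-field value of the whole
    composition.
    """
    strategy, profile = focal_cell
    if good_fraction is None:
        good_fraction = population_good_fraction(composition, policy, params)
    pc = _cooperation_prob(Strategy(strategy), good_fraction, params)
    K = np.empty((2, 2))
    for r in (0, 1):
        p_good = (pc * _good_verdict_prob(policy, r, 1, int(profile), params.chi)
                  + (1 - pc) * _good_verdict_prob(policy, r, 0, int(profile),
                                                  params.chi))
        K[r, 0] = 1 - p_good
        K[r, 1] = p_good
    return K


def stationary_good_fraction(kernel: np.ndarray) -> float:
    """Stationary P(GOOD) of a two-state chain: P(B->G)/(P(B->G)+P(G->B)).

    Raises :class:`ReducibleChainError` when both off-diagonal entries are
    zero (the chain is reducible and the answer depends on the initial
    condition).
    """
    K = np.asarray(kernel, dtype=float)
    if K.shape != (2, 2) or (K < -1e-12).any() or \
            not np.allclose(K.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("kernel must be a 2x2 row-stochastic matrix")
    p_bg = K[0, 1]
    p_gb = K[1, 0]
    if p_bg == 0.0 and p_gb == 0.0:
        raise ReducibleChainError(
            "both reputations are absorbing; the stationary GOOD fraction "
            "depends on the initial condition")
    return p_bg / (p_bg + p_gb)


def _iterate_good_fraction(composition: FrozenComposition, policy: NormPolicy,
                           params: Params, g0: float, tol: float,
                           max_iter: int) -> float:
    cells = list(composition.cells())
    g_cell = {cell: g0 for cell, _ in cells}
    g = g0
    for _ in range(max_iter):
        new = {}
        for cell, _w in cells:
            K = reputation_transition_kernel(composition, cell, policy,
                                             params, good_fraction=g)
            gc = g_cell[cell]
            new[cell] = gc * K[1, 1] + (1 - gc) * K[0, 1]
        g_new = sum(w * new[cell] for cell, w in cells)
        delta = max(abs(new[c] - g_cell[c]) for c, _ in cells)
        g_cell = new
        g = g_new
        if delta < tol:
            return g
    warnings.warn("mean-field good-fraction iteration did not converge "
                  f"to {tol} in {max_iter} steps", stacklevel=2)
    return g


def population_good_fraction(composition: FrozenComposition,
                             policy: NormPolicy, params: Params,
                             tol: float = 1e-10,
                             max_iter: int = 100_000) -> float:
    """Self-consistent mean-field GOOD fraction of a frozen composition.

    Iterates the per-cell chains from GOOD fraction 0.5 until the sup-norm
    change falls below ``tol``. Error-free conditional-strategy compositions
    can make the mean-field map non-contracting (a continuum of fixed
    points); this is detected by re-solving from extreme initial conditions
    and flagged with a warning.
    """
    g = _iterate_good_fraction(composition, policy, params, 0.5, tol, max_iter)
    g_lo = _iterate_good_fraction(composition, policy, params, 0.01, tol,
                                  max_iter)
    g_hi = _iterate_good_fraction(composition, policy, params, 0.99, tol,
                                  max_iter)
    if max(abs(g - g_lo), abs(g - g_hi)) > 1e-6:
        warnings.warn(
            "multiple mean-field fixed points detected; returning the "
            "solution initialised at GOOD fraction 0.5", stacklevel=2)
    return g


def expected_eta_frozen(composition: FrozenComposition, policy: NormPolicy,
                        params: Params) -> float:
    """Expected cooperation index of a frozen composition.

    Fraction of realized cooperative acts per potential-donation act under
    the stationary mean-field reputation distribution, marginalizing over
    partner cell, perception error and execution error.
    """
    g = population_good_fraction(composition, policy, params)
    return float(sum(w * _cooperation_prob(cell[0], g, params)
                     for cell, w in composition.cells()))
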