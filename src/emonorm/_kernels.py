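"""Numba-compiled inner loops of the donation-game simulator.

Everything here works on plain integers and small integer arrays:

* actions   — DEFECT=0, COOPERATE=1
* reputations — BAD=0, GOOD=1
* strategies — ALLC=0, ALLD=1, DISC=2, PDISC=3
* emotional profiles — COOPERATIVE=0, COMPETITIVE=1

Norm tables are integer arrays of GOOD/BAD verdicts: the base (emotion-free)
norm is indexed ``base[prior_rep, action]`` and the emotion-based norm
``emo[prior_rep, action, profile]``.

The public object layer in :mod:`emonorm.model_core` and the step-level
operations in :mod:`emonorm.evolution` call these same primitives, so the
fast per-generation kernel and the step-by-step Python path consume an
identical random-draw sequence from a shared ``numpy.random.Generator`` and
produce byte-identical results under the same seed.
"""

import numpy as np
from numba import njit

# strategy codes
ALLC = 0
ALLD = 1
DISC = 2
PDISC = 3

# execution-error semantics
EXEC_FLIP = 0        # realized action is the opposite of the intended one
EXEC_COOP_FAILS = 1  # only intended cooperation can fail (becomes defection)

# fitness aggregation over the z evaluation games
FIT_MEAN = 0
FIT_SUM = 1

_JIT = dict(cache=True, nogil=True)


@njit(inline="always", **_JIT)
def _randbelow(rng, n):
    """Uniform integer in [0, n) from a single float draw.

    Used instead of ``Generator.integers`` so that every caller — jitted or
    not — consumes exactly one draw per index, keeping the Python step path
    and the generation kernel on the same stream.
    """
    k = int(rng.random() * n)
    if k >= n:  # guard the (measure-zero) u == 1.0 edge
        k = n - 1
    return k


@njit(inline="always", **_JIT)
def prescribe(strategy, perceived_rep):
    """Action (0/1) prescribed by a strategy given the perceived reputation."""
    if strategy == ALLC:
        return 1
    if strategy == ALLD:
        return 0
    if strategy == DISC:
        return perceived_rep       # cooperate iff perceived GOOD
    return 1 - perceived_rep       # pDisc: cooperate iff perceived BAD


@njit(inline="always", **_JIT)
def perceive(true_rep, alpha, u):
    """Reputation as perceived under assessment error alpha (u ~ U[0,1))."""
    if u < alpha:
        return 1 - true_rep
    return true_rep


@njit(inline="always", **_JIT)
def execute(intended, epsilon, mode, u):
    """Realized action under execution error epsilon (u ~ U[0,1))."""
    if u < epsilon:
        if mode == EXEC_FLIP:
            return 1 - intended
        if intended == 1:          # coop_fails: only cooperation can misfire
            return 0
    return intended


@njit(inline="always", **_JIT)
def judge(base, emo, gamma, prior_rep, action, profile, chi, u_gamma, u_chi):
    """Public verdict on a donor.

    With probability gamma the emotion-based table is consulted, otherwise
    the base table; the nominal verdict is then flipped with the assignment
    error probability chi.
    """
    if u_gamma < gamma:
        verdict = emo[prior_rep, action, profile]
    else:
        verdict = base[prior_rep, action]
    if u_chi < chi:
        return 1 - verdict
    return verdict


@njit(inline="always", **_JIT)
def fermi(f_focal, f_model, beta):
    """Pairwise-comparison adoption probability 1/(1+exp(-beta*(fm-ff)))."""
    x = beta * (f_model - f_focal)
    if x < -500.0:
        return 0.0
    if x > 500.0:
        return 1.0
    return 1.0 / (1.0 + np.exp(-x))


@njit(**_JIT)
def interact(strat, prof, rep, i, j, base, emo, gamma,
             b, c, epsilon, alpha, chi, exec_mode, rng):
    """One pairwise donation-game interaction between agents i and j.

    Both players perceive each other's public reputation (assessment error
    alpha), act through the execution-error channel, and are then both
    judged as donors from their PRE-interaction reputations; the two public
    reputations are updated simultaneously.

    Returns (action_i, action_j, payoff_i, payoff_j); mutates ``rep``.
    """
    ri = rep[i]
    rj = rep[j]
    seen_j = perceive(rj, alpha, rng.random())   # i's view of j
    seen_i = perceive(ri, alpha, rng.random())   # j's view of i
    ai = execute(prescribe(strat[i], seen_j), epsilon, exec_mode, rng.random())
    aj = execute(prescribe(strat[j], seen_i), epsilon, exec_mode, rng.random())
    ni = judge(base, emo, gamma, ri, ai, prof[i], chi, rng.random(), rng.random())
    nj = judge(base, emo, gamma, rj, aj, prof[j], chi, rng.random(), rng.random())
    rep[i] = ni
    rep[j] = nj
    pay_i = b * aj - c * ai
    pay_j = b * ai - c * aj
    return ai, aj, pay_i, pay_j


@njit(**_JIT)
def play_games(strat, prof, rep, focal, n_games, base, emo, gamma,
               b, c, epsilon, alpha, chi, exec_mode, rng):
    """Focal agent plays ``n_games`` against uniformly random other agents.

    Reputation updates persist in the shared public state as the games
    proceed. Returns (payoff_sum of the focal agent, donation count over
    both players' realized actions); each game contributes two potential
    donation acts.
    """
    z = strat.shape[0]
    payoff_sum = 0.0
    donations = 0
    for _ in range(n_games):
        j = _randbelow(rng, z - 1)
        if j >= focal:
            j += 1
        ai, aj, pay_i, _ = interact(strat, prof, rep, focal, j, base, emo,
                                    gamma, b, c, epsilon, alpha, chi,
                                    exec_mode, rng)
        payoff_sum += pay_i
        donations += ai + aj
    return payoff_sum, donations


@njit(**_JIT)
def run_generation_kernel(strat, prof, rep, base, emo, gamma, b, c, mu, beta,
                          epsilon, alpha, chi, exec_mode, fit_mode, rng):
    """One generation = z Monte Carlo steps, fully compiled.

    Each step: a uniformly drawn focal agent either mutates (probability mu;
    strategy and profile redrawn uniformly) or plays z games, after which a
    distinct uniformly drawn model agent plays z games and the focal adopts
    the model's traits with the Fermi probability. Returns the generation's
    (cooperative acts, total acts) tally over all evaluation games.
    """
    z = strat.shape[0]
    coop = 0
    acts = 0
    for _ in range(z):
        focal = _randbelow(rng, z)
        if rng.random() < mu:
            strat[focal] = _randbelow(rng, 4)
            prof[focal] = _randbelow(rng, 2)
            continue
        pay_f, don_f = play_games(strat, prof, rep, focal, z, base, emo,
                                  gamma, b, c, epsilon, alpha, chi,
                                  exec_mode, rng)
        coop += don_f
        acts += 2 * z
        model = _randbelow(rng, z - 1)
        if model >= focal:
            model += 1
        pay_m, don_m = play_games(strat, prof, rep, model, z, base, emo,
                                  gamma, b, c, epsilon, alpha, chi,
                                  exec_mode, rng)
        coop += don_m
        acts += 2 * z
        if fit_mode == FIT_MEAN:
            f_f = pay_f / z
            f_m = pay_m / z
        else:
            f_f = pay_f
            f_m = pay_m
        if rng.random() < fermi(f_f, f_m, beta):
            strat[focal] = strat[model]
            prof[focal] = prof[model]
    return coop, acts


@njit(**_JIT)
def run_frozen_generation_kernel(strat, prof, rep, base, emo, gamma, b, c,
                                 epsilon, alpha, chi, exec_mode, rng):
    """One generation with evolution disabled: reputations and payoffs only.

    z steps; each step a uniformly drawn focal agent plays z games. No
    mutation, no imitation — trait counts are exactly preserved, which is
    what the analytic frozen-composition oracle assumes.
    """
    z = strat.shape[0]
    coop = 0
    acts = 0
    for _ in range(z):
        focal = _randbelow(rng, z)
        _, don = play_games(strat, prof, rep, focal, z, base, emo, gamma,
                            b, c, epsilon, alpha, chi, exec_mode, rng)
        coop += don
        acts += 2 * z
    return coop, acts
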