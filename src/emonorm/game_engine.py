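"""A single pairwise donation-game interaction.

Both players simultaneously perceive, act and are judged as donors; the
payoff matrix is the donation game: cooperating costs the donor c and
confers b on the recipient, so (C,C) -> b-c each, (D,C) -> b for the
exploiter and -c for the exploited, (D,D) -> 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels as _k
from .model_core import (Action, Agent, Emotion, NormPolicy, Params,
                         Reputation, express_emotion)

__all__ = ["InteractionResult", "payoff", "play_interaction"]


@dataclass(frozen=True)
class InteractionResult:
    """Outcome of one interaction, in (player i, player j) order."""
    actions: tuple[Action, Action]
    payoffs: tuple[float, float]
    emotions: tuple[Emotion, Emotion]
    new_reputations: tuple[Reputation, Reputation]
    donations: int  # number of realized cooperative acts, 0..2


def payoff(own_action: Action, opp_action: Action, b: float, c: float) -> float:
    """Donation-game payoff: own cooperation costs c, partner's confers b."""
    if not b > c > 0:
        raise ValueError(f"need b > c > 0, got b={b}, c={c}")
    return b * int(opp_action) - c * int(own_action)


def play_interaction(agent_i: Agent, agent_j: Agent, policy: NormPolicy,
                     params: Params, rng: np.random.Generator) -> InteractionResult:
    """Play one full interaction and update both public reputations.

    Each player perceives the other's reputation through the assessment
    error channel, realizes their prescribed action through the execution
    error channel, and is judged as a donor from their pre-interaction
    reputation (independent gamma and chi draws per player); the two
    verdicts are applied simultaneously.
    """
    if agent_i is agent_j:
        raise ValueError("an agent cannot interact with itself")
    strat = np.array([int(agent_i.strategy), int(agent_j.strategy)], dtype=np.int64)
    prof = np.array([int(agent_i.profile), int(agent_j.profile)], dtype=np.int64)
    rep = np.array([int(agent_i.reputation), int(agent_j.reputation)], dtype=np.int64)
    ai, aj, pay_i, pay_j = _k.interact(
        strat, prof, rep, 0, 1, policy.base.table, policy.emotion.table,
        policy.gamma, params.b, params.c, params.epsilon, params.alpha,
        params.chi, params.exec_mode_code, rng)
    ai, aj = Action(int(ai)), Action(int(aj))
    agent_i.reputation = Reputation(int(rep[0]))
    agent_j.reputation = Reputation(int(rep[1]))
    return InteractionResult(
        actions=(ai, aj),
        payoffs=(float(pay_i), float(pay_j)),
        emotions=(express_emotion(agent_i.profile, ai, aj),
                  express_emotion(agent_j.profile, aj, ai)),
        new_reputations=(agent_i.reputation, agent_j.reputation),
        donations=int(ai) + int(aj),
    )
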