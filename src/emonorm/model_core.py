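"""Domain types and stateless single-step rules of the model.

The model is a donation game played under indirect reciprocity: every agent
carries an evolving strategy, a fixed-per-lifetime emotional profile, and a
public binary reputation. Moral judgement of a donor is made either by an
emotion-free base norm (a 4-entry table over the donor's prior reputation
and action) or, with probability ``gamma``, by an emotion-based norm (an
8-entry table that additionally conditions on the donor's expressed
emotional profile). Three error channels perturb the process: execution
errors (epsilon), reputation assessment errors (alpha) and reputation
assignment errors (chi).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

from . import _kernels as _k

__all__ = [
    "Action", "Reputation", "Strategy", "EmotionalProfile", "Emotion",
    "Agent", "BaseNorm", "EmotionNorm", "NormPolicy", "Params",
    "parse_norm_string", "prescribe_action", "perceive_reputation",
    "execute_action", "express_emotion", "judge",
    "IS_BASE_STRING", "IS_EMOTION_STRING", "EBIS_EMOTION_STRING",
]


class Action(IntEnum):
    """The two moves of the donation game; COOPERATE is the donation."""
    DEFECT = 0
    COOPERATE = 1


class Reputation(IntEnum):
    """Binary public reputation."""
    BAD = 0
    GOOD = 1


class Strategy(IntEnum):
    """The four pure/reactive strategies of the reputation game."""
    ALLC = 0    # always cooperate
    ALLD = 1    # always defect
    DISC = 2    # cooperate with GOOD partners, defect otherwise
    PDISC = 3   # paradoxical: cooperate with BAD partners


class EmotionalProfile(IntEnum):
    """Fixed emotional disposition; symbols n ("nice") and m ("mean")."""
    COOPERATIVE = 0   # n — joy on mutual cooperation, regret on exploiting
    COMPETITIVE = 1   # m — the reverse


class Emotion(IntEnum):
    """Instantaneous expression, a deterministic function of the outcome."""
    JOY = 0
    REGRET = 1
    ANGER = 2
    NEUTRAL = 3


@dataclass
class Agent:
    """One individual: evolving traits plus current public reputation."""
    strategy: Strategy
    profile: EmotionalProfile
    reputation: Reputation


# norm-string position -> table index, both in the canonical print order
_BASE_ORDER = ((1, 1), (1, 0), (0, 1), (0, 0))  # (gc, gd, bc, bd)
_EMO_ORDER = (
    (1, 1, 0), (1, 1, 1), (1, 0, 0), (1, 0, 1),  # gcn gcm gdn gdm
    (0, 1, 0), (0, 1, 1), (0, 0, 0), (0, 0, 1),  # bcn bcm bdn bdm
)
_CHAR = {1: "G", 0: "B"}


def _chars_to_bits(s: str) -> list[int]:
    bits = []
    for pos, ch in enumerate(s.upper(), start=1):
        if ch == "G":
            bits.append(1)
        elif ch == "B":
            bits.append(0)
        else:
            raise ValueError(
                f"invalid norm character {ch!r} at position {pos}: "
                "expected 'G' or 'B'"
            )
    return bits


@dataclass(frozen=True)
class BaseNorm:
    """Emotion-free norm: (donor prior reputation, donor action) -> verdict.

    ``table[rep, action]`` holds GOOD=1 / BAD=0, with rep and action in the
    integer encodings of :class:`Reputation` and :class:`Action`. The string
    form lists the four verdicts in the order (gc, gd, bc, bd).
    """
    table: np.ndarray

    def __post_init__(self):
        t = np.ascontiguousarray(np.asarray(self.table, dtype=np.int64))
        if t.shape != (2, 2) or not np.isin(t, (0, 1)).all():
            raise ValueError("base norm table must be 2x2 over {0,1}")
        object.__setattr__(self, "table", t)
        t.setflags(write=False)

    @classmethod
    def from_string(cls, s: str) -> "BaseNorm":
        if len(s) != 4:
            raise ValueError(f"base norm string must have length 4, got {len(s)}")
        bits = _chars_to_bits(s)
        t = np.empty((2, 2), dtype=np.int64)
        for bit, idx in zip(bits, _BASE_ORDER):
            t[idx] = bit
        return cls(t)

    def to_string(self) -> str:
        return "".join(_CHAR[int(self.table[idx])] for idx in _BASE_ORDER)

    def __getitem__(self, key) -> Reputation:
        rep, action = key
        return Reputation(int(self.table[int(rep), int(action)]))


@dataclass(frozen=True)
class EmotionNorm:
    """Emotion-based norm: (prior reputation, action, profile) -> verdict.

    ``table[rep, action, profile]``; the string form lists the eight
    verdicts in the order (gcn, gcm, gdn, gdm, bcn, bcm, bdn, bdm).
    """
    table: np.ndarray

    def __post_init__(self):
        t = np.ascontiguousarray(np.asarray(self.table, dtype=np.int64))
        if t.shape != (2, 2, 2) or not np.isin(t, (0, 1)).all():
            raise ValueError("emotion norm table must be 2x2x2 over {0,1}")
        object.__setattr__(self, "table", t)
        t.setflags(write=False)

    @classmethod
    def from_string(cls, s: str) -> "EmotionNorm":
        if len(s) != 8:
            raise ValueError(f"emotion norm string must have length 8, got {len(s)}")
        bits = _chars_to_bits(s)
        t = np.empty((2, 2, 2), dtype=np.int64)
        for bit, idx in zip(bits, _EMO_ORDER):
            t[idx] = bit
        return cls(t)

    @classmethod
    def lift(cls, base: BaseNorm) -> "EmotionNorm":
        """Profile-blind 8-entry copy of a 4-entry base norm."""
        t = np.repeat(base.table[:, :, None], 2, axis=2)
        return cls(t)

    def to_string(self) -> str:
        return "".join(_CHAR[int(self.table[idx])] for idx in _EMO_ORDER)

    def __getitem__(self, key) -> Reputation:
        rep, action, profile = key
        return Reputation(int(self.table[int(rep), int(action), int(profile)]))


def parse_norm_string(s: str):
    """Parse a 4-character string into a BaseNorm or 8-character into an
    EmotionNorm. Characters are 'G'/'B', case-insensitive."""
    if len(s) == 4:
        return BaseNorm.from_string(s)
    if len(s) == 8:
        return EmotionNorm.from_string(s)
    raise ValueError(f"norm string must have length 4 or 8, got {len(s)}")


#: Image Scoring: cooperation -> GOOD, defection -> BAD, emotion ignored.
IS_BASE_STRING = "GBGB"
#: Image Scoring lifted to the 8-entry encoding (profile-blind).
IS_EMOTION_STRING = "GGBBGGBB"
#: Emotion-Based Image Scoring: like IS except a GOOD donor who defects
#: while displaying the cooperative profile keeps a GOOD reputation.
EBIS_EMOTION_STRING = "GGGBGGBB"


@dataclass(frozen=True)
class NormPolicy:
    """A base norm, an emotion-based norm, and the mixing probability gamma.

    Each judgement consults the emotion-based table with probability gamma
    and the base table otherwise.
    """
    base: BaseNorm
    emotion: EmotionNorm
    gamma: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError(f"gamma must be in [0, 1], got {self.gamma}")

    @classmethod
    def image_scoring(cls, gamma: float = 0.0) -> "NormPolicy":
        """The baseline: both tables are Image Scoring, so gamma is inert."""
        return cls(BaseNorm.from_string(IS_BASE_STRING),
                   EmotionNorm.from_string(IS_EMOTION_STRING), gamma)

    @classmethod
    def ebis(cls, gamma: float) -> "NormPolicy":
        """Emotion-Based Image Scoring over an Image-Scoring base."""
        return cls(BaseNorm.from_string(IS_BASE_STRING),
                   EmotionNorm.from_string(EBIS_EMOTION_STRING), gamma)

    def with_gamma(self, gamma: float) -> "NormPolicy":
        return dataclasses.replace(self, gamma=gamma)


_EXEC_MODES = {"flip": _k.EXEC_FLIP, "coop_fails": _k.EXEC_COOP_FAILS}
_FIT_MODES = {"mean": _k.FIT_MEAN, "sum": _k.FIT_SUM}


@dataclass(frozen=True)
class Params:
    """Full parameter record of one simulation.

    Defaults are the study conditions: donation-game benefit b=5 and cost
    c=1, population size z=50, mutation probability mu=1/z, selection
    intensity beta=1, and error probabilities epsilon=alpha=chi=0.002.
    """
    b: float = 5.0
    c: float = 1.0
    z: int = 50
    mu: float | None = None          # None -> 1/z
    beta: float = 1.0
    epsilon: float = 0.002
    alpha: float = 0.002
    chi: float = 0.002
    generations: int = 10_000
    burn_in: int = 1_000
    seed: int | None = None
    execution_error_mode: str = "flip"
    fitness_aggregation: str = "mean"

    def __post_init__(self):
        if self.mu is None:
            object.__setattr__(self, "mu", 1.0 / self.z)
        if not self.b > self.c > 0:
            raise ValueError(f"need b > c > 0, got b={self.b}, c={self.c}")
        if self.z < 2:
            raise ValueError(f"population size must be >= 2, got {self.z}")
        for name in ("mu", "epsilon", "alpha", "chi"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability, got {p}")
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if not 0 <= self.burn_in < self.generations:
            raise ValueError(
                f"need 0 <= burn_in < generations, got {self.burn_in} "
                f"vs {self.generations}")
        if self.execution_error_mode not in _EXEC_MODES:
            raise ValueError(
                f"execution_error_mode must be one of {sorted(_EXEC_MODES)}")
        if self.fitness_aggregation not in _FIT_MODES:
            raise ValueError(
                f"fitness_aggregation must be one of {sorted(_FIT_MODES)}")

    @property
    def exec_mode_code(self) -> int:
        return _EXEC_MODES[self.execution_error_mode]

    @property
    def fit_mode_code(self) -> int:
        return _FIT_MODES[self.fitness_aggregation]

    def replace(self, **kw) -> "Params":
        return dataclasses.replace(self, **kw)


def prescribe_action(strategy: Strategy, perceived_rep: Reputation) -> Action:
    """Action a strategy prescribes against a partner of the perceived
    reputation: ALLC/ALLD unconditionally, DISC cooperates with GOOD,
    PDISC with BAD."""
    return Action(_k.prescribe(int(strategy), int(perceived_rep)))


def perceive_reputation(true_rep: Reputation, alpha: float,
                        rng: np.random.Generator) -> Reputation:
    """Perceived reputation: flipped with assessment-error probability alpha."""
    return Reputation(_k.perceive(int(true_rep), alpha, rng.random()))


def execute_action(intended: Action, epsilon: float,
                   rng: np.random.Generator, mode: str = "flip") -> Action:
    """Realized action under execution error epsilon.

    In the default ``flip`` mode the realized action is the opposite of the
    intended one with probability epsilon; in ``coop_fails`` mode only
    intended cooperation can misfire.
    """
    return Action(_k.execute(int(intended), epsilon, _EXEC_MODES[mode],
                             rng.random()))


def express_emotion(profile: EmotionalProfile, own_action: Action,
                    opp_action: Action) -> Emotion:
    """Deterministic expressed emotion for a joint outcome.

    Cooperative profiles express joy on mutual cooperation and regret upon
    exploiting (defecting against a cooperator); competitive profiles the
    reverse. Both express anger when exploited and neutral on mutual
    defection.
    """
    if opp_action == Action.COOPERATE:
        if own_action == Action.COOPERATE:  # mutual cooperation
            return (Emotion.JOY if profile == EmotionalProfile.COOPERATIVE
                    else Emotion.REGRET)
        # exploiting the other
        return (Emotion.REGRET if profile == EmotionalProfile.COOPERATIVE
                else Emotion.JOY)
    if own_action == Action.COOPERATE:      # being exploited
        return Emotion.ANGER
    return Emotion.NEUTRAL                  # mutual defection


def judge(policy: NormPolicy, prior_rep: Reputation, action: Action,
          profile: EmotionalProfile, chi: float,
          rng: np.random.Generator) -> Reputation:
    """Public verdict on a donor under the mixed norm policy.

    With probability ``policy.gamma`` the emotion-based table is consulted
    (indexed by the donor's prior reputation, realized action and emotional
    profile), otherwise the base table; the nominal verdict is flipped with
    assignment-error probability chi.
    """
    return Reputation(_k.judge(policy.base.table, policy.emotion.table,
                               policy.gamma, int(prior_rep), int(action),
                               int(profile), chi, rng.random(), rng.random()))
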