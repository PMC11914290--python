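"""Unit tests for the domain types and single-step rules."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emonorm import (Action, BaseNorm, EBIS_EMOTION_STRING, Emotion,
                     EmotionNorm, EmotionalProfile, IS_BASE_STRING,
                     IS_EMOTION_STRING, NormPolicy, Params, Reputation,
                     Strategy, execute_action, express_emotion, judge,
                     parse_norm_string, perceive_reputation,
                     prescribe_action)

C, D = Action.COOPERATE, Action.DEFECT
G, B = Reputation.GOOD, Reputation.BAD
N, M = EmotionalProfile.COOPERATIVE, EmotionalProfile.COMPETITIVE


class TestEnums:
    def test_cardinalities(self):
        assert len(Action) == 2
        assert len(Reputation) == 2
        assert len(Strategy) == 4
        assert len(EmotionalProfile) == 2
        assert len(Emotion) == 4


class TestPrescribeAction:
    @pytest.mark.parametrize("strategy,rep,expected", [
        (Strategy.ALLC, G, C), (Strategy.ALLC, B, C),
        (Strategy.ALLD, G, D), (Strategy.ALLD, B, D),
        (Strategy.DISC, G, C), (Strategy.DISC, B, D),
        (Strategy.PDISC, G, D), (Strategy.PDISC, B, C),
    ])
    def test_full_table(self, strategy, rep, expected):
        assert prescribe_action(strategy, rep) == expected


class TestErrorChannels:
    def test_perception_edge_probabilities(self, rng):
        assert perceive_reputation(G, 0.0, rng) == G
        assert perceive_reputation(G, 1.0, rng) == B
        assert perceive_reputation(B, 1.0, rng) == G

    def test_execution_edge_probabilities(self, rng):
        assert execute_action(C, 0.0, rng) == C
        assert execute_action(D, 1.0, rng) == C  # symmetric flip
        assert execute_action(C, 1.0, rng) == D

    def test_coop_fails_mode_never_flips_defection(self, rng):
        assert execute_action(D, 1.0, rng, mode="coop_fails") == D
        assert execute_action(C, 1.0, rng, mode="coop_fails") == D

    def test_perception_flip_fraction_is_binomial(self, rng):
        n, alpha = 100_000, 0.2
        flips = sum(perceive_reputation(G, alpha, rng) == B for _ in range(n))
        se = np.sqrt(alpha * (1 - alpha) / n)
        assert abs(flips / n - alpha) < 3 * se

    def test_execution_flip_fraction_is_binomial(self, rng):
        n, eps = 100_000, 0.002
        flips = sum(execute_action(C, eps, rng) == D for _ in range(n))
        se = np.sqrt(eps * (1 - eps) / n)
        assert abs(flips / n - eps) < 3 * se


class TestExpressEmotion:
    @pytest.mark.parametrize("profile,own,opp,expected", [
        (N, C, C, Emotion.JOY), (M, C, C, Emotion.REGRET),
        (N, D, C, Emotion.REGRET), (M, D, C, Emotion.JOY),
        (N, C, D, Emotion.ANGER), (M, C, D, Emotion.ANGER),
        (N, D, D, Emotion.NEUTRAL), (M, D, D, Emotion.NEUTRAL),
    ])
    def test_full_table(self, profile, own, opp, expected):
        assert express_emotion(profile, own, opp) == expected

    @given(profile=st.sampled_from(list(EmotionalProfile)),
           opp=st.sampled_from([C, D]))
    @settings(derandomize=True, max_examples=20)
    def test_profile_independent_when_not_rewarded(self, profile, opp):
        """Exploited players show anger and mutual defectors neutrality,
        regardless of profile."""
        if opp == D:
            assert express_emotion(profile, D, opp) == Emotion.NEUTRAL
        assert express_emotion(profile, C, D) == Emotion.ANGER


class TestNormStrings:
    def test_image_scoring_base(self):
        norm = parse_norm_string("GBGB")
        assert isinstance(norm, BaseNorm)
        assert norm[G, C] == G and norm[G, D] == B
        assert norm[B, C] == G and norm[B, D] == B

    def test_ebis_emotion_norm(self):
        norm = parse_norm_string("GGGBGGBB")
        assert isinstance(norm, EmotionNorm)
        # the distinguishing cell: a GOOD defector with cooperative profile
        # keeps a GOOD reputation
        assert norm[G, D, N] == G
        assert norm[G, D, M] == B
        assert norm[B, D, N] == B

    def test_case_insensitive(self):
        assert parse_norm_string("gbgb").to_string() == "GBGB"

    @pytest.mark.parametrize("bad,pos", [("GXGB", 2), ("XGGB", 1),
                                         ("GGGBGGBX", 8)])
    def test_invalid_character_names_position(self, bad, pos):
        with pytest.raises(ValueError, match=f"position {pos}"):
            parse_norm_string(bad)

    @pytest.mark.parametrize("bad", ["", "GBG", "GBGBG", "GBGBGBGBG"])
    def test_invalid_length(self, bad):
        with pytest.raises(ValueError, match="length"):
            parse_norm_string(bad)

    def test_round_trip_all_strings(self):
        """format(parse(s)) == s for every valid 4- and 8-character norm."""
        for k in (4, 8):
            for bits in itertools.product("GB", repeat=k):
                s = "".join(bits)
                assert parse_norm_string(s).to_string() == s

    def test_lifted_norm_differs_from_ebis_in_one_cell(self):
        lifted = EmotionNorm.lift(BaseNorm.from_string(IS_BASE_STRING))
        assert lifted.to_string() == IS_EMOTION_STRING
        ebis = EmotionNorm.from_string(EBIS_EMOTION_STRING)
        diff = (lifted.table != ebis.table).sum()
        assert diff == 1 and lifted[G, D, N] != ebis[G, D, N]


class TestJudge:
    def test_table1_spot_checks(self, rng):
        ebis = NormPolicy.ebis(1.0)
        assert judge(ebis, G, D, N, 0.0, rng) == G
        assert judge(ebis, G, D, M, 0.0, rng) == B
        is_ = NormPolicy.image_scoring()
        assert judge(is_, B, C, N, 0.0, rng) == G
        # certain assignment error flips the nominal BAD verdict
        assert judge(is_, G, D, N, 1.0, rng) == G

    def test_gamma_zero_never_consults_emotion_table(self, rng):
        """With gamma=0 the verdict matches the base table even when the
        emotion table disagrees everywhere (and vice versa for gamma=1)."""
        base = BaseNorm.from_string("GBGB")
        anti = EmotionNorm(1 - EmotionNorm.lift(base).table)
        pol0 = NormPolicy(base, anti, 0.0)
        pol1 = NormPolicy(base, anti, 1.0)
        for rep in (B, G):
            for act in (D, C):
                for prof in (N, M):
                    for _ in range(5):
                        assert judge(pol0, rep, act, prof, 0.0, rng) \
                            == base[rep, act]
                        assert judge(pol1, rep, act, prof, 0.0, rng) \
                            == anti[rep, act, prof]

    def test_ebis_competitive_profile_matches_image_scoring(self, rng):
        """Judged under EBIS, a competitive-profile donor receives exactly
        the Image Scoring verdict in every cell."""
        ebis = NormPolicy.ebis(1.0)
        is_base = BaseNorm.from_string(IS_BASE_STRING)
        for rep in (B, G):
            for act in (D, C):
                assert judge(ebis, rep, act, M, 0.0, rng) == is_base[rep, act]


class TestParams:
    def test_mu_defaults_to_one_over_z(self):
        assert Params(z=50).mu == pytest.approx(0.02)
        assert Params(z=25).mu == pytest.approx(0.04)

    @pytest.mark.parametrize("kw", [
        dict(b=1.0, c=1.0), dict(b=0.5, c=1.0), dict(z=1),
        dict(epsilon=1.5), dict(alpha=-0.1), dict(beta=-1.0),
        dict(burn_in=10, generations=10), dict(execution_error_mode="maybe"),
        dict(fitness_aggregation="median"),
    ])
    def test_invalid_parameters_rejected(self, kw):
        with pytest.raises(ValueError):
            Params(**kw)

    def test_norm_tables_are_immutable(self):
        pol = NormPolicy.ebis(0.5)
        with pytest.raises(ValueError):
            pol.base.table[0, 0] = 1
        with pytest.raises(ValueError):
            NormPolicy(pol.base, pol.emotion, 1.5)
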