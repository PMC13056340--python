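"""RSA listeners/speakers, their limits, and the mixture likelihoods."""

import itertools

import numpy as np
import pandas as pd
import pytest

from refgame.rsa import (
    ROLE_ORDER,
    RSAMixtureParams,
    _alpha_quadrature,
    _condition_role_probs,
    listener,
    literal_listener,
    mixture_loglik,
    response_probability,
    speaker,
)
from refgame.strategies import accepts, Strategy
from refgame.task_model import DEFAULT_BANK, Message, Referent, make_trial

R = Referent.from_code
M = Message.of

SIMPLE = make_trial(M("red"), (R("square-red"), R("triangle-red"), R("circle-blue")))
COMPLEX = make_trial(M("red"), (R("circle-red"), R("triangle-red"), R("circle-green")))


def by_role(trial, dist):
    out = {}
    for pos, role in enumerate(trial.roles):
        out[role] = out.get(role, 0.0) + dist[pos]
    return out


class TestListeners:
    def test_literal_listener_uniform_over_matches(self):
        d = by_role(SIMPLE, literal_listener(M("red"), SIMPLE))
        assert d["target"] == pytest.approx(0.5)
        assert d["competitor"] == pytest.approx(0.5)
        assert d["distractor"] == 0.0

    def test_unambiguous_point_mass(self):
        t = make_trial(M("green"), (R("circle-green"), R("square-red"), R("triangle-blue")))
        assert literal_listener(M("green"), t)[0] == 1.0

    def test_first_order_prefers_simple_target_two_to_one(self):
        # literal-speaker likelihoods 1 vs 1/2 give a (2/3, 1/3) posterior
        d = by_role(SIMPLE, listener(1, M("red"), SIMPLE))
        assert d["target"] == pytest.approx(2 / 3)
        assert d["competitor"] == pytest.approx(1 / 3)

    def test_first_order_flat_on_complex(self):
        d = by_role(COMPLEX, listener(1, M("red"), COMPLEX))
        assert d["target"] == pytest.approx(0.5)

    def test_second_order_resolves_complex(self):
        d1 = by_role(COMPLEX, listener(2, M("red"), COMPLEX, alpha=1.0))
        assert d1["target"] > 0.5
        d_inf = by_role(COMPLEX, listener(2, M("red"), COMPLEX, alpha=60.0))
        assert d_inf["target"] == pytest.approx(1.0, abs=1e-6)

    def test_normalization(self, scenarios):
        for s in scenarios:
            t = s.trial()
            for level in (0, 1, 2):
                for alpha in (0.5, 1.0, 4.0):
                    d = listener(level, t.message, t, alpha=alpha)
                    assert d.sum() == pytest.approx(1.0, abs=1e-9)
                    assert (d >= -1e-12).all()

    def test_alpha_monotonicity(self, scenarios):
        """Target probability under L1 (simple) and L2 (complex) never
        decreases as the speaker gets greedier."""
        for s in scenarios:
            t = s.trial()
            level = 1 if s.condition == "simple" else 2
            probs = [
                by_role(t, listener(level, t.message, t, alpha=a))["target"]
                for a in (0.25, 1.0, 2.0, 8.0, 32.0)
            ]
            assert all(b >= a - 1e-9 for a, b in zip(probs, probs[1:]))

    def test_greedy_limit_matches_strategy_acceptance(self, scenarios):
        """As alpha grows, each listener's maximally probable referents are
        exactly the corresponding strategy's accepted set where that strategy
        solves, and a tie where it does not."""
        for s in scenarios:
            t = s.trial()
            for level, strat in ((0, Strategy.A), (1, Strategy.B), (2, Strategy.C)):
                d = listener(level, t.message, t, alpha=100.0)
                argmax = set(np.flatnonzero(d > d.max() - 1e-7))
                accepted = {
                    i for i, r in enumerate(t.referents) if accepts(strat, t.message, r, t)
                }
                if len(accepted) == 1:
                    assert argmax == accepted
                else:
                    assert len(argmax) >= 2


class TestSpeakers:
    def test_literal_speaker_single_option(self):
        s = speaker(0, R("square-red"), SIMPLE)
        assert s == {M("red"): 1.0}

    def test_literal_speaker_splits_two_messages(self):
        s = speaker(0, R("triangle-red"), SIMPLE)
        assert s[M("red")] == pytest.approx(0.5)
        assert s[M("triangle")] == pytest.approx(0.5)

    def test_greedy_pragmatic_speaker_prefers_unambiguous_message(self):
        s = speaker(1, R("triangle-red"), SIMPLE, alpha=80.0)
        assert s[M("triangle")] == pytest.approx(1.0, abs=1e-6)

    def test_inexpressible_referent_raises(self):
        t = make_trial(M("red"), (R("square-red"), R("triangle-red"), R("square-blue")),
                       bank=DEFAULT_BANK)
        with pytest.raises(ValueError):
            speaker(0, R("square-blue"), t)


class TestResponseNoise:
    def test_uniform_mixing(self):
        p = np.array([1.0, 0.0, 0.0])
        out = response_probability(p, 0.3)
        assert out == pytest.approx([0.8, 0.1, 0.1])
        assert out.sum() == pytest.approx(1.0)

    def test_truncnorm_variant_normalizes(self):
        out = response_probability(np.array([0.7, 0.3, 0.0]), 0.2, model="truncnorm")
        assert out.sum() == pytest.approx(1.0)
        assert out[0] > out[1] > out[2]


class TestMixtureLikelihood:
    def _dataset(self, rows):
        df = pd.DataFrame(rows)
        df["trial_index"] = df.groupby("participant_id").cumcount()
        return df

    def test_pure_literal_type_on_complex(self):
        df = self._dataset(
            [
                {"participant_id": 0, "condition": "complex", "response_role": "target"}
                for _ in range(6)
            ]
        )
        p = RSAMixtureParams(weights=(1.0, 0.0, 0.0), sigma_noise=1e-12)
        ll = mixture_loglik(df, p)
        assert ll == pytest.approx(np.log(0.5) * np.ones(6))

    def test_pure_second_order_near_ceiling(self):
        p = RSAMixtureParams(
            weights=(0.0, 0.0, 1.0), a_alpha=50.0, b_alpha=1.0, sigma_noise=1e-6
        )
        probs = _condition_role_probs("complex", 2, 50.0, DEFAULT_BANK)
        assert probs[0] > 0.95
        probs_s = _condition_role_probs("simple", 2, 50.0, DEFAULT_BANK)
        assert probs_s[0] > 0.95

    def test_chance_data_prefers_literal_over_second_order(self):
        rows = []
        for pid in range(8):
            for i in range(12):
                rows.append(
                    {
                        "participant_id": pid,
                        "condition": "complex",
                        "response_role": "target" if i % 2 == 0 else "competitor",
                    }
                )
        df = self._dataset(rows)
        l0 = RSAMixtureParams(weights=(1.0, 0.0, 0.0), a_alpha=8, sigma_noise=0.01)
        l2 = RSAMixtureParams(weights=(0.0, 0.0, 1.0), a_alpha=8, sigma_noise=0.01)
        assert mixture_loglik(df, l0).sum() > mixture_loglik(df, l2).sum()

    def test_pointwise_sums_to_enumerated_marginal(self):
        """Sequential pointwise contributions sum to the participant marginal
        computed by brute-force enumeration over types and alpha nodes."""
        df = self._dataset(
            [
                {"participant_id": 0, "condition": c, "response_role": r}
                for c, r in [
                    ("simple", "target"),
                    ("complex", "competitor"),
                    ("unambiguous", "target"),
                    ("simple", "competitor"),
                ]
            ]
        )
        params = RSAMixtureParams(
            weights=(0.3, 0.45, 0.25), a_alpha=2.0, b_alpha=1.5, sigma_noise=0.1
        )
        ll = mixture_loglik(df, params, n_nodes=8)

        alphas, aw = _alpha_quadrature(2.0, 1.5, 8)
        total = 0.0
        for w, level in zip(params.weights, range(3)):
            for a, wa in zip(alphas, aw):
                prod = w * wa
                for c, r in zip(df["condition"], df["response_role"]):
                    probs = response_probability(
                        _condition_role_probs(c, level, float(a), DEFAULT_BANK), 0.1
                    )
                    prod *= probs[ROLE_ORDER.index(r)]
                total += prod
        assert ll.sum() == pytest.approx(np.log(total), abs=1e-9)

    def test_flexible_variant_brute_force(self):
        """Flexible (per-quarter type) marginal agrees with enumeration over
        the per-quarter type assignments."""
        rows = []
        for i, (c, r) in enumerate(
            [("simple", "target"), ("simple", "competitor"),
             ("complex", "target"), ("complex", "target")]
        ):
            rows.append(
                {"participant_id": 0, "condition": c, "response_role": r,
                 "trial_index": i, "quartile": i}  # one trial per quarter
            )
        df = pd.DataFrame(rows)
        weights = ((0.5, 0.3, 0.2), (0.2, 0.5, 0.3), (0.1, 0.2, 0.7), (1 / 3,) * 3)
        params = RSAMixtureParams(
            weights=weights, a_alpha=3.0, b_alpha=0.8, sigma_noise=0.05
        )
        ll = mixture_loglik(df, params, n_nodes=6)

        alphas, aw = _alpha_quadrature(3.0, 0.8, 6)
        total = 0.0
        for a, wa in zip(alphas, aw):
            prod_a = 1.0
            for q, (c, r) in enumerate(zip(df["condition"], df["response_role"])):
                s = 0.0
                for level in range(3):
                    probs = response_probability(
                        _condition_role_probs(c, level, float(a), DEFAULT_BANK), 0.05
                    )
                    s += weights[q][level] * probs[ROLE_ORDER.index(r)]
                prod_a *= s
            total += wa * prod_a
        assert ll.sum() == pytest.approx(np.log(total), abs=1e-9)

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            RSAMixtureParams(weights=(0.5, 0.6, 0.2))
        with pytest.raises(ValueError):
            RSAMixtureParams(weights=(0.5, 0.5, 0.0), sigma_noise=-0.1)
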