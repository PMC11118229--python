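"""The unilateral finite-class Bayesian recursion and elimination rule 1."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaitbayes.core import ALL_CLASS_PAIRS, ClassPair, GaitEvent, WalkingActivity
from gaitbayes.fc_besis import (
    Decision,
    advance_event_prior,
    decide,
    eliminate_rule1,
    init_prior,
    marginals,
    update_with_likelihoods,
)
from gaitbayes import evaluate as ev
from gaitbayes import simulator as sim


def pair(a, e):
    return ClassPair(WalkingActivity(a), GaitEvent(e))


class TestInitPrior:
    def test_uniform_over_full_class_set(self):
        state = init_prior(ALL_CLASS_PAIRS)
        assert len(state.classes) == 56
        np.testing.assert_allclose(state.probs, 1 / 56)

    @pytest.mark.parametrize("n", [1, 4])
    def test_uniform_over_subsets(self, n):
        state = init_prior(ALL_CLASS_PAIRS[:n])
        np.testing.assert_allclose(state.probs, 1 / n)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            init_prior([])


class TestStep:
    def test_equal_likelihoods_leave_posterior_unchanged(self, rng):
        probs = rng.dirichlet(np.ones(5))
        state = init_prior(ALL_CLASS_PAIRS[:5])
        state = update_with_likelihoods(state, probs * 0 + 1.0)
        before = state.probs.copy()
        after = update_with_likelihoods(state, np.full(5, 0.37))
        np.testing.assert_allclose(after.probs, before)

    def test_two_class_arithmetic(self):
        state = init_prior(ALL_CLASS_PAIRS[:2])
        out = update_with_likelihoods(state, np.array([0.8, 0.2]))
        np.testing.assert_allclose(out.probs, [0.8, 0.2])
        assert out.normalizer == pytest.approx(0.5)

    @settings(deadline=None, max_examples=25)
    @given(seed=st.integers(0, 10_000))
    def test_normalization_and_oracle_equivalence(self, seed):
        # oracle: enumerate all 56 classes, eliminated ones held at mass 0
        rng = np.random.default_rng(seed)
        keep = rng.random(56) < 0.5
        keep[rng.integers(56)] = True
        classes = tuple(c for c, k in zip(ALL_CLASS_PAIRS, keep) if k)
        prior = rng.dirichlet(np.ones(len(classes)))
        lik = rng.random(len(classes)) + 1e-3

        full_prior = np.zeros(56)
        full_prior[keep] = prior
        full_lik = np.zeros(56)
        full_lik[keep] = lik
        oracle = full_prior * full_lik
        oracle /= oracle.sum()

        state = init_prior(classes)
        state = type(state)(classes=classes, probs=prior, t=0)
        out = update_with_likelihoods(state, lik)
        assert out.probs.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(out.probs, oracle[keep], atol=1e-12)

    def test_zero_normalizer_resets_to_uniform(self):
        state = init_prior(ALL_CLASS_PAIRS[:4])
        out = update_with_likelihoods(state, np.zeros(4))
        np.testing.assert_allclose(out.probs, 0.25)


class TestEliminateRule1:
    def test_tau1_one_keeps_unique_maximizer(self):
        state = init_prior(ALL_CLASS_PAIRS[:4])
        lik = np.array([0.1, 0.9, 0.3, 0.2])
        out = eliminate_rule1(state, lik, tau1=1.0)
        assert out.classes == (ALL_CLASS_PAIRS[1],)
        assert out.probs == pytest.approx([1.0])

    def test_event_admissibility_keeps_current_and_successor(self):
        state = init_prior(ALL_CLASS_PAIRS)
        out = eliminate_rule1(
            state, np.ones(56), current_event=GaitEvent.IC, tau1=0.01
        )
        events = {int(p.event) for p in out.classes}
        assert events == {int(GaitEvent.IC), int(GaitEvent.LR)}

    def test_equal_likelihoods_no_event_leave_set_unchanged(self):
        state = init_prior(ALL_CLASS_PAIRS)
        out = eliminate_rule1(state, np.ones(56), tau1=0.5)
        assert out.classes == state.classes

    def test_fail_open_when_event_part_would_empty(self):
        # ratio survivor has an inadmissible event: the event part is skipped
        state = init_prior(ALL_CLASS_PAIRS[:8])  # LW x 8 events
        lik = np.zeros(8)
        lik[4] = 1.0  # PS only
        out = eliminate_rule1(state, lik, current_event=GaitEvent.IC, tau1=1.0)
        assert out.classes == (pair(1, 5),)

    def test_elimination_preserves_relative_order(self, rng):
        state = init_prior(ALL_CLASS_PAIRS[:10])
        lik = rng.random(10) + 0.05
        stepped = update_with_likelihoods(state, lik)
        pruned = eliminate_rule1(stepped, lik, tau1=0.5)
        kept = [stepped.classes.index(c) for c in pruned.classes]
        np.testing.assert_array_equal(
            np.argsort(pruned.probs), np.argsort(stepped.probs[kept])
        )


class TestMarginals:
    def test_activity_collapse(self):
        state = init_prior([pair(1, 1), pair(1, 2)])
        act, evt = marginals(state)
        assert act[0] == pytest.approx(1.0)
        assert evt[:2] == pytest.approx([0.5, 0.5])

    def test_event_collapse(self):
        state = init_prior([pair(1, 1), pair(2, 1)])
        act, evt = marginals(state)
        assert evt[0] == pytest.approx(1.0)

    def test_joint_mass_splits(self):
        state = init_prior([pair(1, 1), pair(2, 2)])
        state = type(state)(classes=state.classes, probs=np.array([0.6, 0.4]), t=0)
        act, evt = marginals(state)
        assert act[:2] == pytest.approx([0.6, 0.4])
        assert evt[:2] == pytest.approx([0.6, 0.4])
        assert act.sum() == pytest.approx(1.0)


class TestDecide:
    def make_state(self, probs):
        state = init_prior(ALL_CLASS_PAIRS[: len(probs)])
        return type(state)(classes=state.classes, probs=np.asarray(probs), t=0)

    def test_confident_activity_recognized(self):
        state = self.make_state([0.95, 0.05])  # (LW,IC), (LW,LR)
        d = decide(state, theta=0.9)
        assert d.activity == WalkingActivity.LW
        assert d.event == GaitEvent.IC

    def test_below_threshold_undecided(self):
        state = self.make_state([0.6, 0.4])
        d = decide(state, theta=0.9)
        assert d.event is None

    def test_tie_below_threshold_is_undecided(self):
        # two activities at 0.5 each: no tie can reach a threshold above 0.5,
        # so the decision must be withheld
        state = init_prior([pair(1, 1), pair(2, 1)])
        d = decide(state, theta=0.9)
        assert d.activity is None
        assert d.event == GaitEvent.IC  # event marginal is 1.0

    def test_majority_tie_breaks_to_lowest_code(self):
        from gaitbayes.evaluate import segment_verdicts

        t, v = segment_verdicts(np.array([1, 1, 1, 1]), np.array([2, 1, 2, 1]))
        np.testing.assert_array_equal(v, [1])

    def test_latency_in_sample_periods(self):
        state = self.make_state([1.0])
        d = decide(state, theta=0.9, samples_since_onset=7, fs=100.0)
        assert d.latency_ms == pytest.approx(70.0)
        assert isinstance(d, Decision)


class TestEventHazard:
    def test_mass_flows_to_successor_event(self):
        post = np.zeros(56)
        post[0] = 1.0  # (LW, IC)
        out = advance_event_prior(post, 0.1)
        assert out[0] == pytest.approx(0.9)
        assert out[1] == pytest.approx(0.1)  # (LW, LR)
        assert out.sum() == pytest.approx(1.0)

    def test_wraps_at_cycle_end(self):
        post = np.zeros(56)
        post[7] = 1.0  # (LW, TSw)
        out = advance_event_prior(post, 0.25)
        assert out[0] == pytest.approx(0.25)  # back to (LW, IC)

    def test_zero_hazard_is_identity(self, rng):
        post = rng.dirichlet(np.ones(56))
        np.testing.assert_array_equal(advance_event_prior(post, 0.0), post)


class TestOnlineRecognition:
    def test_strong_separation_decides_within_100ms(self):
        # strongly separated emissions: the first confident correct activity
        # decision of each segment arrives in under 100 ms.  Input filtering
        # is disabled so the measurement isolates the inference latency from
        # the low-pass filter's settling time at segment steps.
        em = sim.EmissionModel(separation=200.0, noise_sd=10.0)
        cfg = ev.ReplayConfig(filter_input=False)
        train = sim.concat_datasets(
            sim.generate_dataset(sim.ProtocolSpec(direction=d, seed=s), emission=em)
            for d, s in [(1, 41), (2, 42)]
        )
        models = ev.train_models(train, config=cfg)
        test = sim.generate_dataset(sim.ProtocolSpec(direction=1, seed=43), emission=em)
        res = ev.replay(test, models, mode="fc", config=cfg)
        # steady segments only: unilateral transition/steady confusability is
        # inherent (trunk yaw levels overlap mid-transition at any separation
        # scale) and is what the bilateral rules address
        lats = []
        for a, b, code in ev.segments(test.label_codes("right")[:, 0]):
            if WalkingActivity(code).is_steady:
                hits = np.flatnonzero(res.decisions["right"][a:b, 0] == code)
                assert hits.size, "steady segment never recognized"
                lats.append(hits[0] * 10.0)
        assert len(lats) >= 5
        assert np.mean(lats) < 100.0
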