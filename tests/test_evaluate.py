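"""Replay engine determinism and the evaluation metrics."""

import numpy as np
import pytest

from gaitbayes import evaluate as ev
from gaitbayes import simulator as sim


class TestReplay:
    def test_deterministic(self, eval_dataset, models):
        a = ev.replay(eval_dataset, models, mode="ber-fc")
        b = ev.replay(eval_dataset, models, mode="ber-fc")
        for side in ("right", "left"):
            np.testing.assert_array_equal(a.decisions[side], b.decisions[side])
            np.testing.assert_array_equal(a.class_counts[side], b.class_counts[side])
        assert len(a.predictions) == len(b.predictions)

    def test_invalid_mode_rejected(self, eval_dataset, models):
        with pytest.raises(ValueError):
            ev.replay(eval_dataset, models, mode="banana")

    def test_bers_reduce_mean_class_count(self, replay_pair):
        fc = ev.class_count_stats(replay_pair["fc"])["both"][0]
        ber = ev.class_count_stats(replay_pair["ber-fc"])["both"][0]
        assert ber <= fc

    def test_counts_bounded_by_class_set(self, replay_pair):
        for res in replay_pair.values():
            for side in ("right", "left"):
                c = res.class_counts[side]
                assert c.min() >= 1
                assert c.max() <= 56

    def test_recognizes_held_out_trial(self, eval_dataset, replay_pair):
        res = replay_pair["ber-fc"]
        for side in ("right", "left"):
            truth = eval_dataset.label_codes(side)
            t, v = ev.segment_verdicts(truth[:, 0], res.decisions[side][:, 0])
            assert ev.accuracy(t, v) >= 0.8


class TestSegmentsAndVerdicts:
    def test_segments_rle(self):
        segs = ev.segments(np.array([1, 1, 2, 2, 2, 1]))
        assert segs == [(0, 2, 1), (2, 5, 2), (5, 6, 1)]

    def test_majority_verdict_ignores_undecided(self):
        truth = np.array([1, 1, 1, 1, 2, 2, 2, 2])
        decided = np.array([0, 1, 1, 3, 0, 0, 2, 2])
        t, v = ev.segment_verdicts(truth, decided)
        np.testing.assert_array_equal(t, [1, 2])
        np.testing.assert_array_equal(v, [1, 2])

    def test_segment_with_no_decisions_is_undecided(self):
        t, v = ev.segment_verdicts(np.array([1, 1]), np.array([0, 0]))
        np.testing.assert_array_equal(v, [0])


class TestConfusion:
    def test_perfect_decisions_are_diagonal(self):
        t = np.array([1, 2, 3, 1])
        cm = ev.confusion(t, t, 3)
        assert np.trace(cm.counts) == 4
        assert cm.percent[0, 0] == pytest.approx(100.0)

    def test_single_column_collapse(self):
        cm = ev.confusion(np.array([1, 2, 3]), np.array([2, 2, 2]), 3)
        np.testing.assert_array_equal(cm.counts.sum(axis=0), [0, 3, 0])

    def test_hand_built_three_segment_toy(self):
        # manual count oracle: truth (1,2,1), verdicts (1,3,1)
        cm = ev.confusion(np.array([1, 2, 1]), np.array([1, 3, 1]), 3)
        expected = np.array([[2, 0, 0], [0, 0, 1], [0, 0, 0]])
        np.testing.assert_array_equal(cm.counts, expected)

    def test_row_percentages_sum_to_100(self, rng):
        t = rng.integers(1, 4, 60)
        p = rng.integers(1, 4, 60)
        cm = ev.confusion(t, p, 3)
        sums = cm.percent.sum(axis=1)
        np.testing.assert_allclose(sums[cm.counts.sum(axis=1) > 0], 100.0, atol=0.01)

    def test_macro_recall_of_constant_predictor_is_chance(self):
        truth = np.repeat([1, 2, 3, 4, 5, 6, 7], [30, 5, 5, 2, 2, 2, 2])
        pred = np.ones_like(truth)
        assert ev.macro_recall(truth, pred, 7) == pytest.approx(1 / 7)


class TestTimingReport:
    def make_result(self, predictions):
        n = 400
        return ev.ReplayResult(
            times=np.arange(n) / 100.0,
            mode="ber-fc",
            config=ev.ReplayConfig(),
            decisions={s: np.zeros((n, 2), dtype=int) for s in ("right", "left")},
            map_decisions={s: np.zeros((n, 2), dtype=int) for s in ("right", "left")},
            class_counts={s: np.ones(n, dtype=int) for s in ("right", "left")},
            predictions=predictions,
        )

    def test_sign_convention_and_mpt(self):
        from gaitbayes.transition import predict
        from gaitbayes.core import GaitEvent, WalkingActivity

        ds = sim.generate_dataset(
            sim.ProtocolSpec(direction=1, cycle_time=1.0, cycle_cv=0.0, seed=0),
            emission=sim.EmissionModel(noise_sd=0.0),
        )
        # right IC onsets at integer seconds; issue at 3.08 inside the LC cycle
        p = predict(WalkingActivity.LC, GaitEvent.LR, mgct=1.0, now=3.08)
        rep = ev.timing_report(self.make_result([("right", p)]), ds)
        row = rep.table.iloc[0]
        assert row.real_hc == pytest.approx(4.0)
        assert row.mpt_ms == pytest.approx(920.0)
        # predicted 3.98, real 4.0 -> prediction early -> positive MTD
        assert row.mtd_ms == pytest.approx(20.0, abs=1e-6)

    def test_no_predictions_raises(self):
        ds = sim.generate_dataset(sim.ProtocolSpec(direction=1, seed=0))
        with pytest.raises(ValueError):
            ev.timing_report(self.make_result([]), ds)


class TestEngineMatchesOperations:
    def test_fc_replay_equals_manual_recursion(self, eval_dataset, models):
        # replicate the engine's unilateral path with the public operations
        from gaitbayes.core import CLASS_EVENT_CODES
        from gaitbayes.fc_besis import (
            advance_event_prior,
            event_admissible_mask,
            likelihood_ratio_mask,
        )

        cfg = ev.ReplayConfig()
        res = ev.replay(eval_dataset, models, mode="fc", config=cfg, keep_posteriors=True)
        feats = ev._prepare_features(eval_dataset, cfg)
        ll = models["right"].log_likelihood_matrix(feats["right"])

        post = np.full(56, 1 / 56)
        chain = None
        for i in range(250):
            lik = np.exp(ll[i] - ll[i].max())
            keep = likelihood_ratio_mask(lik, cfg.tau1)
            if chain is not None:
                k2 = keep & event_admissible_mask(CLASS_EVENT_CODES, chain)
                if k2.any():
                    keep = k2
            prior = np.where(
                keep, np.maximum(advance_event_prior(post, cfg.event_hazard),
                                 cfg.mass_floor), 0.0
            )
            prior /= prior.sum()
            p = prior * lik
            post = p / p.sum()
            evm = np.bincount(CLASS_EVENT_CODES, weights=post, minlength=9)[1:]
            chain = int(np.argmax(evm)) + 1
            np.testing.assert_allclose(res.posteriors["right"][i], post, atol=1e-12)
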