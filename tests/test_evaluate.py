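"""Event-level flagging, confusion counting, two-threshold ROC, HMM baseline."""

import numpy as np
import pytest

from repanom.cdtw import Segment
from repanom.evaluate import (
    SessionScores,
    event_confusion,
    fit_hmm_baseline,
    flag,
    hmm_score,
    roc_and_auc,
    session_scores,
)


def _segments(bounds, partial_ends=True):
    segs = []
    for k, (a, b) in enumerate(zip(bounds[:-1], bounds[1:])):
        partial = partial_ends and (k == 0 or k == len(bounds) - 2)
        segs.append(Segment(a, b, partial))
    return segs


class TestFlag:
    def test_infinite_thresholds_flag_nothing(self, rng):
        ps = rng.uniform(0, 1, 50)
        rs = rng.standard_normal((50, 3))
        assert not flag(ps, rs, np.inf, np.inf).any()

    def test_zero_recon_threshold_flags_nonzero_errors(self):
        ps = np.zeros(5)
        rs = np.zeros((5, 2))
        rs[3, 1] = 0.4
        f = flag(ps, rs, np.inf, 0.0)
        assert f.tolist() == [False, False, False, True, False]

    def test_negative_scores_count_via_absolute_value(self):
        rs = np.zeros((3, 1))
        rs[1, 0] = -9.0
        assert flag(np.zeros(3), rs, np.inf, 5.0).tolist() == [False, True, False]

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            flag(np.zeros(2), None, -1.0, 0.0)


class TestEventConfusion:
    def test_hand_computed_counts(self):
        # 10 interior periods of length 10; 6 events, 5 with a flagged sample;
        # 2 normal periods flagged => precision 5/7, recall 5/6
        segs = _segments(list(range(0, 121, 10)), partial_ends=False)
        events = [(10 * k + 2, 10 * k + 5, "jerk") for k in range(6)]
        flags = np.zeros(120, dtype=bool)
        for s, e, _ in events[:5]:
            flags[s] = True
        flags[65] = True  # FP period 6
        flags[118] = True  # FP period 11
        c = event_confusion(flags, events, segs)
        assert (c.tp, c.fn, c.fp) == (5, 1, 2)
        assert c.precision == pytest.approx(5 / 7)
        assert c.recall == pytest.approx(5 / 6)
        assert c.f1 == pytest.approx(2 * (5 / 7) * (5 / 6) / (5 / 7 + 5 / 6))

    def test_all_flagged(self):
        segs = _segments([0, 10, 20, 30], partial_ends=False)
        events = [(12, 15, "jerk")]
        c = event_confusion(np.ones(30, dtype=bool), events, segs)
        assert c.tp == 1 and c.recall == 1.0
        assert c.fp == c.n_normal_periods == 2

    def test_no_flags(self):
        segs = _segments([0, 10, 20], partial_ends=False)
        c = event_confusion(np.zeros(20, dtype=bool), [(2, 4, "jerk")], segs)
        assert (c.tp, c.fp, c.recall, c.precision) == (0, 0, 0.0, 0.0)

    def test_partial_periods_not_counted_as_normal(self):
        segs = _segments([0, 10, 20, 30])  # first and last partial
        c = event_confusion(np.ones(30, dtype=bool), [(12, 14, "x")], segs)
        assert c.n_normal_periods == 0

    def test_overlapping_events_rejected(self):
        segs = _segments([0, 10, 20])
        with pytest.raises(ValueError, match="overlap"):
            event_confusion(np.zeros(20, dtype=bool), [(1, 5, "a"), (4, 8, "b")], segs)

    def test_flags_inside_flagged_events_change_nothing(self, rng):
        segs = _segments(list(range(0, 60, 10)), partial_ends=False)
        events = [(12, 18, "jerk")]
        flags = np.zeros(50, dtype=bool)
        flags[13] = True
        base = event_confusion(flags, events, segs)
        flags[14:18] = True  # extra flags within the already-detected event
        again = event_confusion(flags, events, segs)
        assert (base.tp, base.fp) == (again.tp, again.fp)


def _scores_from_maxima(event_max, period_max):
    return SessionScores(
        np.asarray(event_max, float),
        np.full(len(event_max), -np.inf),
        np.asarray(period_max, float),
        np.full(len(period_max), -np.inf),
    )


class TestRocAndAuc:
    def test_perfect_separation_auc_one(self):
        res = roc_and_auc([_scores_from_maxima([5.0, 6.0, 7.0], [1.0] * 20)])
        assert res.auc == pytest.approx(1.0)
        assert res.best["f1"] == pytest.approx(1.0)
        assert res.best["fpr"] == 0.0

    def test_random_scores_auc_near_half(self, rng):
        ev = rng.standard_normal(100)
        pd = rng.standard_normal(300)
        res = roc_and_auc([_scores_from_maxima(ev, pd)])
        assert res.auc == pytest.approx(0.5, abs=0.1)

    def test_frontier_monotone_and_anchored(self, rng):
        res = roc_and_auc(
            [_scores_from_maxima(rng.uniform(0, 2, 30), rng.uniform(0, 1.5, 80))]
        )
        F = res.frontier
        assert tuple(F[0]) == (0.0, 0.0) and tuple(F[-1]) == (1.0, 1.0)
        assert np.all(np.diff(F[:, 0]) >= 0) and np.all(np.diff(F[:, 1]) >= 0)
        assert 0.0 <= res.auc <= 1.0

    def test_monotone_transform_invariance(self, rng):
        # AUC depends only on score order: a strictly increasing transform of
        # both streams leaves the curve unchanged
        ep, er = rng.uniform(0, 2, 40), rng.uniform(0, 3, 40)
        pp, pr = rng.uniform(0, 1.2, 90), rng.uniform(0, 2.2, 90)
        base = roc_and_auc([SessionScores(ep, er, pp, pr)])

        def f(x):
            return np.expm1(x)  # strictly increasing

        trans = roc_and_auc([SessionScores(f(ep), f(er), f(pp), f(pr))])
        assert trans.auc == pytest.approx(base.auc, abs=1e-12)
        assert trans.best["f1"] == pytest.approx(base.best["f1"], abs=1e-12)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            roc_and_auc([_scores_from_maxima([], [1.0, 2.0])])


class TestSessionScores:
    def test_maxima_extracted_per_event_and_period(self):
        ps = np.arange(30, dtype=float)
        rs = np.zeros((30, 2))
        rs[25, 0] = 42.0
        segs = _segments([0, 10, 20, 30], partial_ends=False)
        events = [(2, 5, "jerk")]
        sc = session_scores(ps, rs, events, segs)
        assert sc.event_phase_max.tolist() == [4.0]
        assert sc.period_phase_max.tolist() == [19.0, 29.0]
        assert sc.period_recon_max.tolist() == [0.0, 42.0]


@pytest.fixture(scope="module")
def hmm_and_data():
    rng = np.random.default_rng(0)
    # two alternating regimes: an easy sequence structure for the HMM
    def seq(T):
        states = (np.arange(T) // 20) % 2
        return rng.standard_normal((T, 4)) * 0.3 + states[:, None] * 2.0

    train = [seq(300) for _ in range(3)]
    model = fit_hmm_baseline(train, n_states=3, n_mix=2, max_iter=15, seed=1)
    return model, train, seq


class TestHmmBaseline:

    def test_window_counting(self, hmm_and_data, rng):
        model, train, _ = hmm_and_data
        X = train[0][:100]
        out = hmm_score(model, X, window=30, stride=1)
        assert out.shape == (100,)
        with pytest.raises(ValueError):
            hmm_score(model, X[:10], window=30)

    def test_window_equals_sequence_gives_constant_score(self, hmm_and_data):
        model, train, _ = hmm_and_data
        X = train[0][:30]
        out = hmm_score(model, X, window=30)
        assert np.unique(out).size == 1

    def test_seed_determinism(self):
        rng = np.random.default_rng(5)
        train = [rng.standard_normal((200, 3))]
        a = fit_hmm_baseline(train, 2, 2, max_iter=5, seed=9)
        b = fit_hmm_baseline(train, 2, 2, max_iter=5, seed=9)
        np.testing.assert_array_equal(a.transmat_, b.transmat_)
        np.testing.assert_array_equal(a.means_, b.means_)

    def test_em_monotone_loglik(self, hmm_and_data):
        model, _, _ = hmm_and_data
        hist = np.asarray(model.monitor_.history)
        assert np.all(np.diff(hist) >= -1e-6)

    def test_corrupted_data_scores_worse(self, hmm_and_data):
        model, train, seq = hmm_and_data
        clean = seq(120)
        corrupted = clean.copy()
        corrupted[40:60] += 25.0  # large injected jumps
        s_clean = hmm_score(model, clean, window=30)
        s_bad = hmm_score(model, corrupted, window=30)
        assert s_bad[40:60].max() > s_clean.max()


class TestCrossvalStructure:
    def test_fold_partition(self):
        from repanom.evaluate import crossval
        from repanom.pipeline import PipelineConfig
        from repanom.simulate import generate_benchmark

        cohort = generate_benchmark(4, train_reps=8, test_normal_reps=8,
                                    anomaly_spec=(), seed=0)
        # events are required for the ROC; give each test session one label
        for subj in cohort:
            subj["test"][0].anomaly_events = [(10, 30, "jerk")]
        res = crossval(cohort, 2, PipelineConfig(), seed=0, include_hmm=False)
        tested = [s for fold in res.fold_subjects for s in fold]
        assert sorted(tested) == [f"S{i:02d}" for i in range(4)]
        assert all(len(f) == 2 for f in res.fold_subjects)
        res2 = crossval(cohort, 2, PipelineConfig(), seed=0, include_hmm=False)
        assert res.fold_subjects == res2.fold_subjects
        assert res.pooled.auc == res2.pooled.auc

    def test_degenerate_fold_counts_rejected(self):
        from repanom.evaluate import crossval

        with pytest.raises(ValueError):
            crossval([{"subject_id": "a", "train": [], "test": []}] * 3, 1)
        with pytest.raises(ValueError):
            crossval([{"subject_id": "a", "train": [], "test": []}] * 2, 4)
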