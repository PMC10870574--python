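"""Similarity-threshold calibration and review-percentage scoring."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from actionreview.review import (
    TfidfEmbeddingSpace,
    calibrate_threshold,
    compute_session_metrics,
    detect_reviews,
    f1_from_counts,
)


def brute_force_best_f1(sims, labels):
    """Independent oracle: exhaustive scan over every candidate cut."""
    sims = np.asarray(sims, float)
    labels = np.asarray(labels, bool)
    distinct = np.unique(sims)
    cuts = ([distinct[0] - 1e-9]
            + [(a + b) / 2 for a, b in zip(distinct[:-1], distinct[1:])]
            + [distinct[-1] + 1e-9])
    best = -1.0
    for t in cuts:
        pred = sims > t
        tp = int((pred & labels).sum())
        fp = int((pred & ~labels).sum())
        fn = int((~pred & labels).sum())
        best = max(best, f1_from_counts(tp, fp, fn))
    return best


class TestCalibration:
    def test_separated_classes_give_f1_one_at_smallest_gap_midpoint(self):
        sims = [0.1, 0.2, 0.3, 0.7, 0.8, 0.9]
        labels = [False, False, False, True, True, True]
        cal = calibrate_threshold(sims, labels)
        assert cal.f_score == 1.0
        assert cal.threshold == pytest.approx(0.5)

    def test_single_class_labels_rejected(self):
        with pytest.raises(ValueError):
            calibrate_threshold([0.1, 0.2], [True, True])

    def test_random_labels_approach_all_positive_baseline(self):
        rng = np.random.default_rng(0)
        rates = []
        for _ in range(20):
            sims = rng.random(90)
            labels = rng.random(90) < 1 / 3
            if labels.all() or not labels.any():
                continue
            p = labels.mean()
            cal = calibrate_threshold(sims, labels)
            rates.append(cal.f_score - 2 * p / (p + 1))
        # best F1 is at least the all-positive baseline and not much above it
        assert min(rates) >= -1e-12
        assert np.mean(rates) < 0.15

    def test_equals_exhaustive_scan_on_random_sets(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            sims = np.round(rng.random(90), 3)
            labels = rng.random(90) < rng.uniform(0.1, 0.9)
            if labels.all() or not labels.any():
                continue
            cal = calibrate_threshold(sims, labels)
            assert cal.f_score == pytest.approx(
                brute_force_best_f1(sims, labels), abs=1e-12)

    def test_grid_has_midpoints_plus_extremes(self):
        sims = np.linspace(0, 1, 90)
        labels = np.array([False] * 45 + [True] * 45)
        cal = calibrate_threshold(sims, labels)
        assert len(cal.grid) == 91

    @settings(max_examples=40, deadline=None)
    @given(st.lists(st.tuples(st.floats(0, 1, allow_nan=False),
                              st.booleans()), min_size=4, max_size=60))
    def test_calibration_oracle_property(self, pairs):
        sims = [p[0] for p in pairs]
        labels = [p[1] for p in pairs]
        if all(labels) or not any(labels):
            return
        cal = calibrate_threshold(sims, labels)
        assert cal.f_score == pytest.approx(brute_force_best_f1(sims, labels),
                                            abs=1e-12)
        # reported F dominates every grid candidate
        assert (cal.grid.f_score <= cal.f_score + 1e-12).all()


class TestDetectReviews:
    def _space(self, texts):
        return TfidfEmbeddingSpace().fit(texts)

    def test_zero_prior_recommendations_all_negative(self):
        space = self._space(["aa bb cc"])
        gens = [("s2", 0, "aa bb cc"), ("s2", 1, "dd ee ff")]
        out = detect_reviews(gens, [], space, threshold=0.1)
        assert all(not j.is_review for j in out)
        assert all(j.max_similarity == float("-inf") for j in out)

    def test_identical_text_has_unit_similarity(self):
        space = self._space(["morning jogging routine felt good",
                            "sleep went badly this week"])
        gens = [("s2", 0, "morning jogging routine felt good")]
        recs = [("s1", 3, "morning jogging routine felt good")]
        out = detect_reviews(gens, recs, space, threshold=0.99)
        assert out[0].max_similarity == pytest.approx(1.0)
        assert out[0].is_review
        assert (out[0].matched_session_id, out[0].matched_index) == ("s1", 3)

    def test_one_dialogue_counts_once_despite_multiple_matches(self):
        space = self._space(["xx yy zz", "xx yy ww"])
        gens = [("s2", 0, "xx yy zz")]
        recs = [("s1", 0, "xx yy zz"), ("s1", 1, "xx yy zz")]
        out = detect_reviews(gens, recs, space, threshold=0.5)
        assert len(out) == 1 and out[0].is_review

    def test_raising_threshold_never_increases_reviews(self):
        rng = np.random.default_rng(1)
        vocab = ["alpha", "beta", "gamma", "delta", "epsilon"]
        texts = [" ".join(rng.choice(vocab, 4)) for _ in range(30)]
        space = self._space(texts)
        gens = [("s2", i, t) for i, t in enumerate(texts[:20])]
        recs = [("s1", i, t) for i, t in enumerate(texts[20:])]
        counts = []
        for thr in np.linspace(0, 1, 11):
            out = detect_reviews(gens, recs, space, thr)
            counts.append(sum(j.is_review for j in out))
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestOverlapSweep:
    def test_detection_gap_shrinks_as_lexical_overlap_grows(self):
        """Mean |detected review% - true review%| decreases monotonically as
        the token overlap between review summaries and their source
        recommendation summaries increases (3 overlap levels)."""
        rng = np.random.default_rng(6)
        vocab = [f"tok{i:02d}" for i in range(60)]
        gaps = []
        for overlap in (1, 3, 6):
            diffs = []
            for _ in range(40):
                src = list(rng.choice(vocab, 8, replace=False))
                rec_text = " ".join(src)
                n_dialogues = 20
                true_reviews = 4
                gens = []
                for i in range(n_dialogues):
                    if i < true_reviews:
                        words = src[:overlap] + list(
                            rng.choice(vocab[30:], 8 - overlap, replace=False))
                    else:
                        words = list(rng.choice(vocab[30:], 8, replace=False))
                    gens.append(("t", i, " ".join(words)))
                space = TfidfEmbeddingSpace().fit(
                    [rec_text] + [g[2] for g in gens])
                out = detect_reviews(gens, [("p", 0, rec_text)], space, 0.30)
                detected = 100.0 * sum(j.is_review for j in out) / n_dialogues
                diffs.append(abs(detected - 100.0 * true_reviews / n_dialogues))
            gaps.append(float(np.mean(diffs)))
        assert gaps[0] >= gaps[1] >= gaps[2]


class TestSessionMetrics:
    def _judged(self, n, flagged):
        from actionreview.review import ReviewJudgment
        return [ReviewJudgment("s2", i, 0.9 if i < flagged else 0.0,
                               i < flagged) for i in range(n)]

    def test_percentage_arithmetic(self):
        m = compute_session_metrics("s2", "c", self._judged(30, 3), 4, 5)
        assert m.review_percentage == pytest.approx(10.0)

    def test_zero_flagged(self):
        m = compute_session_metrics("s2", "c", self._judged(30, 0), 4, 5)
        assert m.review_percentage == 0.0

    def test_empty_session_defensive_error(self):
        with pytest.raises(ValueError):
            compute_session_metrics("s2", "c", [], 0, 0)

    def test_truth_metrics_match_independent_recount(self, small_corpus):
        """Latent session metrics equal a recount straight from the labels."""
        from actionreview.generate import truth_session_metrics
        m = truth_session_metrics(small_corpus).set_index("session_id")
        labels = small_corpus.truth.labels
        for sid, grp in labels.groupby("session_id"):
            if sid not in m.index:
                continue
            assert m.loc[sid, "n_dialogues"] == len(grp)
            assert m.loc[sid, "n_reviewing"] == int((grp.kind == "review").sum())
            assert m.loc[sid, "review_percentage"] == pytest.approx(
                100.0 * (grp.kind == "review").sum() / len(grp))
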