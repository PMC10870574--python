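"""Synthetic corpus generator: determinism, calibration, label consistency."""

import re

import numpy as np
import pytest
from scipy import stats

from actionreview.config import GeneratorConfig, OutcomeEffects
from actionreview.generate import generate_corpus, generate_outcomes, render_dialogue
from actionreview.transcript import session_to_record
from actionreview._templates import ACTIVITY_NOUNS


def _cfg(**kw):
    base = dict(seed=7, n_clients=10, n_therapists=4, n_organizations=2)
    base.update(kw)
    return GeneratorConfig(**base)


class TestDeterminism:
    def test_same_config_same_corpus(self):
        a = generate_corpus(_cfg())
        b = generate_corpus(_cfg())
        assert [session_to_record(s) for s in a.sessions] == \
               [session_to_record(s) for s in b.sessions]
        assert a.assessments.equals(b.assessments)
        assert a.truth.labels.equals(b.truth.labels)

    def test_numeric_mode_deterministic(self):
        a = generate_corpus(_cfg(), render_text=False)
        b = generate_corpus(_cfg(), render_text=False)
        assert a.truth.clients.equals(b.truth.clients)
        assert a.assessments.equals(b.assessments)


class TestConfigValidation:
    def test_sessions_mean_below_three_with_zero_sd_rejected(self):
        with pytest.raises(ValueError):
            _cfg(sessions_per_client=(2.0, 0.0))

    def test_review_probability_bounds(self):
        with pytest.raises(ValueError):
            _cfg(review_probability=1.5)

    def test_window_order(self):
        with pytest.raises(ValueError):
            _cfg(window_days=(70, 50))


class TestStructure:
    def test_zero_review_probability_plants_no_reviews(self):
        c = generate_corpus(_cfg(review_probability=0.0))
        assert (c.truth.labels.kind != "review").all()
        assert (c.truth.clients.mean_review_pct == 0).all()

    def test_recommendation_rate_matches_truncated_distribution(self):
        cfg = _cfg(n_clients=50, recs_per_session=(4.7, 3.2))
        c = generate_corpus(cfg, render_text=False)
        counts = np.array([ps.n_recs for ps in c.planned])
        # Oracle: expectation of round(N(4.7, 3.2)) clipped to [1, 8],
        # by exact enumeration of the rounding cells.
        mu, sd = 4.7, 3.2
        vals = np.arange(1, 9)
        p = np.diff(stats.norm.cdf((vals[:-1] + 0.5 - mu) / sd))
        probs = np.concatenate([[stats.norm.cdf((1.5 - mu) / sd)], p,
                                [stats.norm.sf((7.5 - mu) / sd)]])
        expected = float(np.dot(vals, probs))
        se = counts.std(ddof=1) / np.sqrt(len(counts))
        assert abs(counts.mean() - expected) < 3 * se
        assert abs(expected - 4.7) < 0.25  # truncation barely moves the mean

    def test_dialogue_count_marginals(self):
        c = generate_corpus(_cfg(n_clients=40), render_text=False)
        nd = np.array([ps.n_dialogues for ps in c.planned])
        se = nd.std(ddof=1) / np.sqrt(len(nd))
        assert abs(nd.mean() - 31.5) < max(3 * se, 1.0)

    def test_reviews_reference_previous_session_same_client(self, small_corpus):
        labels = small_corpus.truth.labels
        sess_no = {sid: int(sid.split("_s")[1])
                   for sid in labels.session_id.unique()}
        rev = labels[labels.kind == "review"]
        key = labels.set_index(["session_id", "index"]).is_action_recommendation
        assert len(rev) > 0
        for _, row in rev.iterrows():
            assert row.reviews_session_id.split("_s")[0] == row.client_id
            assert sess_no[row.reviews_session_id] == sess_no[row.session_id] - 1
            # every review target is a recommendation in the truth table
            assert bool(key.loc[(row.reviews_session_id, int(row.reviews_index))])

    def test_cascade_consistency_of_truth_labels(self, small_corpus):
        lab = small_corpus.truth.labels
        assert (~lab.is_action_recommendation | lab.is_plan).all()

    def test_sessions_at_least_three_and_spaced(self, small_corpus):
        by_client = {}
        for s in small_corpus.sessions:
            by_client.setdefault(s.client_id, []).append(s.date)
        for dates in by_client.values():
            dates = sorted(dates)
            assert len(dates) >= 3
            assert all((b - a).days >= 5 for a, b in zip(dates, dates[1:]))


class TestRendering:
    def test_review_requires_source_context(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            render_dialogue("review", rng)

    def test_review_shares_content_tokens_with_source(self):
        rng = np.random.default_rng(0)
        utts = render_dialogue("review", rng, context="gentle cooking routine")
        text = " ".join(u.text for u in utts)
        for tok in ("gentle", "cooking", "routine"):
            assert re.search(rf"\b{tok}\b", text)

    def test_filler_avoids_activity_vocabulary(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            text = " ".join(u.text for u in render_dialogue("filler", rng))
            toks = {t.strip(".,!?").lower() for t in text.split()}
            assert not toks & set(ACTIVITY_NOUNS)

    def test_recommendation_word_counts_in_budget(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            utts = render_dialogue("recommendation", rng,
                                   context="morning jogging routine")
            total = sum(u.word_count for u in utts)
            assert 250 <= total <= 350
            assert {u.speaker for u in utts} == {"therapist", "client"}

    def test_label_text_consistency(self, small_corpus):
        """A whole-word match for the planted activity noun exists in every
        recommendation and review dialogue's rendered text."""
        labels = small_corpus.truth.labels
        for s, ps in zip(small_corpus.sessions, small_corpus.planned):
            lab = labels[labels.session_id == s.session_id]
            bounds = np.cumsum([0] + [10] * len(ps.dialogues))
            for _, row in lab.iterrows():
                if row.kind in ("recommendation", "review"):
                    i = int(row["index"])
                    block = s.utterances[bounds[i]:bounds[i + 1]]
                    text = " ".join(u.text for u in block)
                    assert re.search(rf"\b{row.noun}\b", text)


class TestOutcomes:
    EFF = OutcomeEffects(intercept=0.0, beta_review=0.0, beta_interaction=0.0,
                         beta_initial=0.0, beta_dialogues=0.0, beta_recs=0.0,
                         beta_days=0.0)

    def test_null_model_returns_initial(self):
        rng = np.random.default_rng(0)
        final, y, clipped = generate_outcomes(
            1.0, 12, self.EFF, mean_dialogues=30, mean_recs_prev=4,
            days_examined=60, therapist_effect=0.0, noise_sd=0.0, rng=rng)
        assert y == 0.0 and final == 12 and not clipped

    def test_higher_review_gives_larger_change(self):
        rng = np.random.default_rng(0)
        eff = OutcomeEffects(intercept=0.0, beta_review=0.5, beta_interaction=0.0,
                             beta_initial=0.0, beta_dialogues=0.0, beta_recs=0.0,
                             beta_days=0.0)
        _, y_lo, _ = generate_outcomes(0.5, 12, eff, mean_dialogues=30,
                                       mean_recs_prev=4, days_examined=60,
                                       therapist_effect=0.0, noise_sd=0.0, rng=rng)
        _, y_hi, _ = generate_outcomes(2.0, 12, eff, mean_dialogues=30,
                                       mean_recs_prev=4, days_examined=60,
                                       therapist_effect=0.0, noise_sd=0.0, rng=rng)
        assert y_hi > y_lo

    def test_zero_initial_score_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            generate_outcomes(1.0, 0, self.EFF, mean_dialogues=30,
                              mean_recs_prev=4, days_examined=60,
                              therapist_effect=0.0, noise_sd=0.0, rng=rng)

    def test_no_cross_client_leakage(self, small_corpus):
        lab = small_corpus.truth.labels
        rev = lab[lab.kind == "review"]
        assert (rev.reviews_session_id.str.split("_s").str[0]
                == rev.client_id).all()
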