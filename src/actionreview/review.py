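"""Review detection by semantic similarity and the review-percentage metric.

For each micro-dialogue of session t (its general summary), similarity is
taken against every action-recommendation summary of the client's previous
retained session t-1; the maximum decides. A dialogue whose maximum
similarity strictly exceeds the calibrated threshold is deemed to review a
recommendation, and counts once regardless of how many recommendations it
exceeds the threshold against. The threshold is calibrated by maximizing F1
over a labeled set of summary pairs.

``review_percentage`` for session t is 100 * (reviewing dialogues) / (all
micro-dialogues of session t), defined from each client's second session on.

The default embedding space is TF-IDF with cosine similarity (deterministic
and dependency-light); any embedder with the same interface — e.g. a neural
sentence encoder — can be substituted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.feature_extraction.text import TfidfVectorizer

from .detect import TFIDF_KWARGS


@dataclass
class ReviewJudgment:
    session_id: str
    index: int
    max_similarity: float
    is_review: bool
    matched_session_id: Optional[str] = None
    matched_index: Optional[int] = None


@dataclass
class ThresholdCalibration:
    threshold: float
    precision: float
    recall: float
    f_score: float
    grid: pd.DataFrame = field(repr=False)


@dataclass
class SessionMetrics:
    session_id: str
    client_id: str
    n_dialogues: int
    n_action_recommendations: int
    n_recs_prev: int
    n_reviewing: int

    def __post_init__(self) -> None:
        if self.n_dialogues <= 0:
            raise ValueError(f"session {self.session_id} has no micro-dialogues "
                             "(impossible after exclusion)")
        if self.n_reviewing > self.n_dialogues:
            raise ValueError("n_reviewing cannot exceed n_dialogues")

    @property
    def review_percentage(self) -> float:
        return 100.0 * self.n_reviewing / self.n_dialogues


class TfidfEmbeddingSpace:
    """Cosine similarity on L2-normalized TF-IDF vectors.

    Similarity is symmetric and self-similarity is maximal (= 1 for any
    non-empty text within the fitted vocabulary).
    """

    def __init__(self):
        self.vectorizer = TfidfVectorizer(**TFIDF_KWARGS)
        self.fitted_ = False

    def fit(self, texts: Sequence[str]) -> "TfidfEmbeddingSpace":
        self.vectorizer.fit(list(texts))
        self.fitted_ = True
        return self

    def embed(self, texts: Sequence[str]):
        if not self.fitted_:
            raise ValueError("embedding space must be fitted first")
        return self.vectorizer.transform(list(texts))

    def similarity_matrix(self, texts_a: Sequence[str],
                          texts_b: Sequence[str]) -> np.ndarray:
        # TfidfVectorizer L2-normalizes rows, so the dot product is cosine.
        return (self.embed(texts_a) @ self.embed(texts_b).T).toarray()


def f1_from_counts(tp: int, fp: int, fn: int) -> float:
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0


def calibrate_threshold(similarities: Sequence[float],
                        labels: Sequence[bool]) -> ThresholdCalibration:
    """Pick the similarity cut maximizing F1 over the labeled pairs.

    Candidates are the midpoints between consecutive distinct sorted
    similarities plus one candidate below the minimum and one above the
    maximum; prediction is strict (similarity > threshold). Ties in F1 break
    toward the smallest threshold. The full candidate grid is returned.
    """
    s = np.asarray(similarities, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape or s.ndim != 1 or not s.size:
        raise ValueError("similarities and labels must be equal-length 1-D")
    if y.all() or not y.any():
        raise ValueError("threshold calibration requires both label classes")
    distinct = np.unique(s)
    candidates = [distinct[0] - 1e-9]
    candidates += [0.5 * (a + b) for a, b in zip(distinct[:-1], distinct[1:])]
    candidates.append(distinct[-1] + 1e-9)

    rows = []
    for t in candidates:
        pred = s > t
        tp = int(np.sum(pred & y))
        fp = int(np.sum(pred & ~y))
        fn = int(np.sum(~pred & y))
        prec = tp / (tp + fp) if tp + fp else np.nan
        rec = tp / (tp + fn) if tp + fn else np.nan
        rows.append({"threshold": t, "tp": tp, "fp": fp, "fn": fn,
                     "precision": prec, "recall": rec,
                     "f_score": f1_from_counts(tp, fp, fn)})
    grid = pd.DataFrame(rows)
    best = int(grid.f_score.idxmax())  # idxmax returns first max = smallest cut
    b = grid.iloc[best]
    return ThresholdCalibration(threshold=float(b.threshold),
                                precision=float(b.precision),
                                recall=float(b.recall),
                                f_score=float(b.f_score), grid=grid)


def detect_reviews(general_summaries: Sequence[tuple[str, int, str]],
                   rec_summaries: Sequence[tuple[str, int, str]],
                   space: TfidfEmbeddingSpace,
                   threshold: float) -> list[ReviewJudgment]:
    """Judge which session-t dialogues review a session t-1 recommendation.

    ``general_summaries``: (session_id, dialogue_index, summary) for every
    micro-dialogue of session t. ``rec_summaries``: same triples for the
    previous session's action-recommendation dialogues. With zero prior
    recommendations every judgment is negative (max similarity -inf).
    """
    judgments = []
    if not rec_summaries:
        return [ReviewJudgment(sid, idx, float("-inf"), False)
                for sid, idx, _ in general_summaries]
    sims = space.similarity_matrix([t for _, _, t in general_summaries],
                                   [t for _, _, t in rec_summaries])
    for i, (sid, idx, _) in enumerate(general_summaries):
        j = int(np.argmax(sims[i]))
        mx = float(sims[i, j])
        hit = mx > threshold
        judgments.append(ReviewJudgment(
            session_id=sid, index=idx, max_similarity=mx, is_review=hit,
            matched_session_id=rec_summaries[j][0] if hit else None,
            matched_index=rec_summaries[j][1] if hit else None))
    return judgments


def compute_session_metrics(session_id: str, client_id: str,
                            judgments: Sequence[ReviewJudgment],
                            n_action_recommendations: int,
                            n_recs_prev: int) -> SessionMetrics:
    """Aggregate judgments for session t into the per-session metrics row."""
    return SessionMetrics(
        session_id=session_id, client_id=client_id,
        n_dialogues=len(judgments),
        n_action_recommendations=n_action_recommendations,
        n_recs_prev=n_recs_prev,
        n_reviewing=int(sum(j.is_review for j in judgments)))


def metrics_frame(metrics: Sequence[SessionMetrics]) -> pd.DataFrame:
    rows = [{
        "session_id": m.session_id, "client_id": m.client_id,
        "n_dialogues": m.n_dialogues, "n_recs": m.n_action_recommendations,
        "n_recs_prev": m.n_recs_prev, "n_reviewing": m.n_reviewing,
        "review_percentage": m.review_percentage,
    } for m in metrics]
    return pd.DataFrame(rows, columns=["session_id", "client_id", "n_dialogues",
                                       "n_recs", "n_recs_prev", "n_reviewing",
                                       "review_percentage"])
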