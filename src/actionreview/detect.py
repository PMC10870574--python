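"""Two-stage detection of action recommendations and extractive summaries.

Stage 1 classifies micro-dialogues that discuss future plans; stage 2 decides
which stage-1 positives qualify as action recommendations (an activity the
therapist recommends, aligned with treatment goals but without a fixed
deadline). Both stages sit behind a uniform fit/predict/decision-score
interface with TF-IDF features (unigram+bigram, lowercased, sublinear tf) and
linear learners: a regularized logistic model for stage 1 and an online
max-margin (passive-aggressive) learner for stage 2. Any text classifier with
the same interface can be dropped in.

Summaries are deterministic extractive stand-ins for generative models:
recommendation summaries take the therapist utterance with the highest
recommendation-cue lexicon score; general summaries take the two most central
utterances by TF-IDF cosine centrality.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.feature_extraction.text import TfidfVectorizer
from sklearn.linear_model import LogisticRegression, SGDClassifier
from sklearn.pipeline import Pipeline

from ._templates import REC_CUES
from .transcript import THERAPIST, MicroDialogue

REC_CUE_LEXICON = frozenset(REC_CUES)

TFIDF_KWARGS = dict(lowercase=True, ngram_range=(1, 2), sublinear_tf=True)


@dataclass
class DialogueLabels:
    session_id: str
    index: int
    is_plan: bool
    is_action_recommendation: bool
    plan_score: float
    rec_score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.is_action_recommendation and not self.is_plan:
            raise ValueError("cascade violation: recommendation implies plan")


@dataclass
class ClassifierEvaluation:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def precision(self) -> Optional[float]:
        d = self.tp + self.fp
        return self.tp / d if d else None

    @property
    def recall(self) -> Optional[float]:
        d = self.tp + self.fn
        return self.tp / d if d else None

    def to_dict(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
                "precision": self.precision, "recall": self.recall}


class TextStageClassifier:
    """TF-IDF + linear-margin classifier behind a uniform interface.

    ``stage`` selects the default learner: ``plans`` uses a regularized
    logistic model, ``recommendations`` an online passive-aggressive
    max-margin learner. The decision threshold is 0 (sign of the margin).
    """

    def __init__(self, stage: str = "plans", random_state: int = 0,
                 estimator=None):
        if stage not in ("plans", "recommendations"):
            raise ValueError("stage must be 'plans' or 'recommendations'")
        self.stage = stage
        if estimator is None:
            if stage == "plans":
                estimator = LogisticRegression(C=10.0, max_iter=2000)
            else:
                # online passive-aggressive max-margin learner
                estimator = SGDClassifier(loss="hinge", penalty=None,
                                          learning_rate="pa1", eta0=1.0,
                                          max_iter=1000,
                                          random_state=random_state)
        self.pipeline = Pipeline([
            ("tfidf", TfidfVectorizer(**TFIDF_KWARGS)),
            ("clf", estimator),
        ])
        self.fitted_ = False

    def fit(self, texts: Sequence[str], labels: Sequence[bool]) -> "TextStageClassifier":
        y = np.asarray(labels, dtype=bool)
        classes = np.unique(y)
        if classes.size < 2:
            missing = "positive" if not classes.size or not classes[0] else "negative"
            raise ValueError(
                f"training data for stage {self.stage!r} contains a single class; "
                f"missing {missing} examples")
        self.pipeline.fit(list(texts), y)
        self.fitted_ = True
        return self

    def decision_scores(self, texts: Sequence[str]) -> np.ndarray:
        clf = self.pipeline.named_steps["clf"]
        X = self.pipeline.named_steps["tfidf"].transform(list(texts))
        if hasattr(clf, "decision_function"):
            return np.asarray(clf.decision_function(X), dtype=float)
        proba = clf.predict_proba(X)[:, 1]
        return np.log(proba / (1 - proba))

    def predict(self, texts: Sequence[str]) -> np.ndarray:
        return self.decision_scores(texts) > 0


def train_stage_classifier(texts: Sequence[str], labels: Sequence[bool],
                           stage: str, random_state: int = 0) -> TextStageClassifier:
    return TextStageClassifier(stage=stage, random_state=random_state).fit(texts, labels)


def classify_cascade(classifier_plans: TextStageClassifier,
                     classifier_recs: TextStageClassifier,
                     dialogues: Sequence[MicroDialogue]) -> list[DialogueLabels]:
    """Apply the two-stage cascade: stage 2 sees only stage-1 positives."""
    if not dialogues:
        return []
    texts = [d.text for d in dialogues]
    plan_scores = classifier_plans.decision_scores(texts)
    is_plan = plan_scores > 0
    rec_scores = np.full(len(dialogues), np.nan)
    idx = np.flatnonzero(is_plan)
    if idx.size:
        rec_scores[idx] = classifier_recs.decision_scores([texts[i] for i in idx])
    out = []
    for i, d in enumerate(dialogues):
        rec = bool(is_plan[i]) and rec_scores[i] > 0
        out.append(DialogueLabels(
            session_id=d.session_id, index=d.index,
            is_plan=bool(is_plan[i]), is_action_recommendation=rec,
            plan_score=float(plan_scores[i]),
            rec_score=float(rec_scores[i]) if is_plan[i] else None))
    return out


class ExtractiveSummarizer:
    """Deterministic extractive summarizer over micro-dialogues.

    Fit once on a corpus of dialogue texts to establish the TF-IDF vocabulary;
    ``summarize`` is then pure (repeated calls identical).
    """

    def __init__(self, top_k_general: int = 2):
        self.top_k_general = top_k_general
        self.vectorizer = TfidfVectorizer(**TFIDF_KWARGS)
        self.fitted_ = False

    def fit(self, texts: Sequence[str]) -> "ExtractiveSummarizer":
        self.vectorizer.fit(list(texts))
        self.fitted_ = True
        return self

    @staticmethod
    def _cue_score(text: str) -> int:
        tokens = [t.strip(".,!?;:'\"").lower() for t in text.split()]
        return sum(t in REC_CUE_LEXICON for t in tokens)

    def summarize(self, dialogue: MicroDialogue, mode: str,
                  labels: Optional[DialogueLabels] = None) -> str:
        if mode not in ("general", "recommendation"):
            raise ValueError("mode must be 'general' or 'recommendation'")
        if mode == "recommendation" and labels is not None \
                and not labels.is_action_recommendation:
            raise ValueError(
                f"dialogue {dialogue.session_id}/{dialogue.index} is not flagged "
                "as an action recommendation")
        utts = dialogue.utterances
        if len(utts) == 1:
            return utts[0].text
        if mode == "recommendation":
            candidates = [u for u in utts if u.speaker == THERAPIST] or list(utts)
            scores = [self._cue_score(u.text) for u in candidates]
            return candidates[int(np.argmax(scores))].text
        if not self.fitted_:
            raise ValueError("summarizer must be fitted before general summaries")
        X = self.vectorizer.transform([u.text for u in utts])
        sim = (X @ X.T).toarray()
        centrality = sim.mean(axis=1)
        k = min(self.top_k_general, len(utts))
        # Stable top-k: ties go to the earlier utterance; output in order.
        order = np.argsort(-centrality, kind="stable")[:k]
        return " ".join(utts[i].text for i in sorted(order))


def evaluate_detection(predicted: Sequence[bool], truth: Sequence[bool]
                       ) -> ClassifierEvaluation:
    p, t = np.asarray(predicted, dtype=bool), np.asarray(truth, dtype=bool)
    if p.shape != t.shape:
        raise ValueError("predicted and truth label vectors differ in length")
    return ClassifierEvaluation(
        tp=int(np.sum(p & t)), fp=int(np.sum(p & ~t)),
        fn=int(np.sum(~p & t)), tn=int(np.sum(~p & ~t)))
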