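"""Synthetic therapy-corpus generator with planted ground truth.

Generates a fully labeled corpus with the statistical structure the analysis
assumes: clients nested in therapists nested in organizations; three or more
sessions per client inside a 50-70 day assessment window, at least five days
apart; ~31.5 micro-dialogues per session; 1-8 action recommendations per
session; cross-session review dialogues that lexically revisit a prior
recommendation; and PHQ-9/GAD-7 outcomes whose cube-root change score follows
a linear model in log1p(review percentage) with a review-by-initial-score
interaction.

Every micro-dialogue carries a latent label (filler / plan / recommendation /
review-of-recommendation) recorded in a :class:`GroundTruth` sidecar that the
pipeline proper never reads — it exists for tests and evaluation only.

Micro-dialogues are rendered so that each planted block totals 300-320 words
with every proper prefix under 300; greedy 300-word segmentation therefore
recovers the planted boundaries exactly, which keeps detector evaluation
against the latent labels well defined.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from datetime import date as _date, timedelta
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import _templates as T
from .config import GeneratorConfig, OutcomeEffects, VIOLATION_RULES
from .cohort import INSTRUMENT_MAX, severity_of
from .transcript import CLIENT, THERAPIST, Session, Utterance

logger = logging.getLogger(__name__)

KIND_FILLER = "filler"
KIND_PLAN = "plan"
KIND_RECOMMENDATION = "recommendation"
KIND_REVIEW = "review"


@dataclass
class DialoguePlan:
    """Latent description of one planted micro-dialogue."""
    kind: str
    phrase: Optional[str] = None          # activity phrase for rec/review
    noun: Optional[str] = None            # activity noun (whole-word anchor)
    topic: Optional[str] = None           # event/filler topic word
    reviews: Optional[tuple[str, int]] = None  # (session_id, dialogue index)


@dataclass
class PlannedSession:
    session_id: str
    client_id: str
    therapist_id: str
    org_id: str
    date: _date
    duration_min: float
    dialogues: list[DialoguePlan]
    n_dialogues: int
    n_recs: int
    n_reviews: int


@dataclass
class GroundTruth:
    """Latent labels and planted parameters of a synthetic corpus."""
    labels: pd.DataFrame          # one row per micro-dialogue
    clients: pd.DataFrame         # one row per client (latents + outcomes)
    effects: dict                 # instrument -> OutcomeEffects actually used
    planted_violations: dict      # rule -> list of client_ids / session_ids
    clip_events: dict             # instrument -> count of clipped final scores

    def labels_for(self, session_id: str) -> pd.DataFrame:
        return self.labels[self.labels.session_id == session_id]


@dataclass
class SyntheticCorpus:
    config: GeneratorConfig
    sessions: list[Session]              # rendered (or placeholder) transcripts
    planned: list[PlannedSession]
    assessments: pd.DataFrame            # client_id, instrument, score, date
    truth: GroundTruth
    rendered: bool = True

    def sessions_by_client(self) -> dict[str, list[Session]]:
        out: dict[str, list[Session]] = {}
        for s in self.sessions:
            out.setdefault(s.client_id, []).append(s)
        return out


# ---------------------------------------------------------------------------
# Dialogue rendering

def _pad_sentence(rng: np.random.Generator, n: int) -> str:
    return " ".join(rng.choice(T.PAD_WORDS, size=n))


def render_dialogue(kind: str, rng: np.random.Generator,
                    context: Optional[str] = None,
                    topic: Optional[str] = None) -> list[Utterance]:
    """Render one ~300-320 word micro-dialogue of the given kind.

    ``context`` is the activity phrase; required for ``review`` (the source
    recommendation's phrase) and for ``recommendation``. ``topic`` is the
    event/filler topic word for the other kinds.
    """
    if kind not in (KIND_FILLER, KIND_PLAN, KIND_RECOMMENDATION, KIND_REVIEW):
        raise ValueError(f"unknown dialogue kind {kind!r}")
    if kind == KIND_REVIEW and not context:
        raise ValueError("review rendering requires the source recommendation phrase")
    if kind == KIND_RECOMMENDATION and not context:
        raise ValueError("recommendation rendering requires an activity phrase")
    if kind in (KIND_PLAN, KIND_FILLER) and not topic:
        topic = str(rng.choice(T.EVENT_NOUNS if kind == KIND_PLAN else T.FILLER_TOPICS))

    backbone = [variants[int(rng.integers(len(variants)))]
                for variants in T.BACKBONES[kind]]
    slot = {"p": context, "e": topic, "f": topic}
    n_utts = 10
    first_speaker = backbone[0][0]
    # Per-utterance word targets: nine 28-32 word utterances (prefix < 300),
    # last utterance sized to land the total in [302, 320].
    targets = list(rng.integers(28, 33, size=n_utts - 1))
    prefix = int(sum(targets))
    targets.append(300 - prefix + int(rng.integers(2, 21)))

    utterances: list[Utterance] = []
    for j in range(n_utts):
        code = first_speaker if j % 2 == 0 else ("C" if first_speaker == "T" else "T")
        if j < len(backbone):
            code, sentence = backbone[j]
            sentence = sentence.format(**slot)
        else:
            pool = T.GENERIC_THERAPIST if code == "T" else T.GENERIC_CLIENT
            sentence = str(rng.choice(pool))
        words = sentence.split()
        need = targets[j] - len(words)
        if need > 0:
            sentence = sentence + " " + _pad_sentence(rng, need)
        speaker = THERAPIST if code == "T" else CLIENT
        utterances.append(Utterance(speaker, sentence))
    return utterances


# ---------------------------------------------------------------------------
# Outcome generation

def generate_outcomes(latent_log_review: float, initial_score: int,
                      effects: OutcomeEffects, *, mean_dialogues: float,
                      mean_recs_prev: float, days_examined: int,
                      therapist_effect: float, noise_sd: float,
                      rng: np.random.Generator,
                      instrument: str = "PHQ9",
                      discretize: bool = True) -> tuple[float, float, bool]:
    """Draw a final score from the planted outcome model.

    The cube-root change score is linear in the client's latent transformed
    review percentage, the initial score, their interaction, and the session
    covariates; the final score is recovered by inverting the change formula
    and clipping/rounding to the instrument range.

    Returns ``(final_score, y, clipped)`` where ``y`` is the planted
    cube-root change score before score discretization.
    """
    if initial_score <= 0:
        raise ValueError("initial_score must be positive (change score undefined "
                         "at zero and below the inclusion minimum)")
    beta_review = effects.beta_review
    if effects.beta_review_by_severity:
        try:
            label = severity_of(instrument, initial_score).label
        except ValueError:
            label = "below_threshold"
        beta_review = effects.beta_review_by_severity.get(label, beta_review)
    y = (effects.intercept
         + beta_review * latent_log_review
         + effects.beta_initial * initial_score
         + effects.beta_interaction * latent_log_review * initial_score
         + effects.beta_dialogues * mean_dialogues
         + effects.beta_recs * mean_recs_prev
         + effects.beta_days * days_examined
         + therapist_effect
         + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0))
    change_pct = y ** 3
    final_raw = initial_score * (1.0 - change_pct / 100.0)
    hi = INSTRUMENT_MAX[instrument]
    clipped = final_raw < -0.5 or final_raw > hi + 0.5
    if discretize:
        final = float(int(np.clip(round(final_raw), 0, hi)))
    else:
        final = float(np.clip(final_raw, 0.0, float(hi)))
    return final, y, clipped


# ---------------------------------------------------------------------------
# Corpus generation

def _trunc_round(rng, mean, sd, lo, hi, size=None):
    x = np.rint(rng.normal(mean, sd, size=size))
    return np.clip(x, lo, hi).astype(int)


def _session_days(rng, n: int, window: int, min_gap: int) -> list[int]:
    d0 = int(rng.integers(0, 5))
    if n == 1:
        return [d0]
    days = [d0]
    budget = window - d0 - min_gap * (n - 1)
    assert budget >= 0
    for _ in range(n - 1):
        extra = int(rng.integers(0, min(8, budget) + 1))
        budget -= extra
        days.append(days[-1] + min_gap + extra)
    return days


def _assign_violators(rng, client_ids: Sequence[str],
                      fractions: dict) -> dict[str, list[str]]:
    order = list(rng.permutation(np.asarray(client_ids)))
    assigned: dict[str, list[str]] = {r: [] for r in VIOLATION_RULES}
    pos = 0
    for rule in VIOLATION_RULES:
        k = int(round(fractions.get(rule, 0.0) * len(client_ids)))
        assigned[rule] = [str(c) for c in order[pos:pos + k]]
        pos += k
    return assigned


def generate_corpus(config: GeneratorConfig,
                    render_text: bool = True) -> SyntheticCorpus:
    """Generate a synthetic corpus and its ground truth.

    With ``render_text=False`` a numeric corpus is generated: the latent
    structure (counts, dates, outcomes) is drawn from the same distributions
    but transcripts and per-dialogue labels are omitted, which keeps large
    replicate simulation studies cheap. Determinism holds within each mode.
    """
    fast = not render_text
    rng = np.random.default_rng(config.seed)
    n_org, n_th, n_cl = config.n_organizations, config.n_therapists, config.n_clients

    org_ids = [f"org{k:03d}" for k in range(n_org)]
    th_ids = [f"th{k:03d}" for k in range(n_th)]
    client_ids = [f"cl{k:04d}" for k in range(n_cl)]
    th_org = rng.integers(0, n_org, size=n_th)
    org_eff = rng.normal(0.0, config.org_sd, size=n_org)
    th_eff = org_eff[th_org] + rng.normal(0.0, config.therapist_sd, size=n_th)
    client_th = rng.integers(0, n_th, size=n_cl)

    violators = _assign_violators(rng, client_ids, config.violation_fractions)
    rule_of = {c: r for r, cs in violators.items() for c in cs}
    planted_violations: dict[str, list[str]] = {r: list(v) for r, v in violators.items()}
    # duration/dialogues are session-level rules; replace client lists with
    # the planted session ids below.
    planted_violations["duration"] = []
    planted_violations["dialogues"] = []

    effects = {"PHQ9": config.phq9_effects, "GAD7": config.effects_gad7}
    d_mean, d_sd = config.dialogues_per_session
    r_mean, r_sd = config.recs_per_session
    s_mean, s_sd = config.sessions_per_client
    win_lo, win_hi = config.window_days
    gap = config.min_intersession_days

    planned_sessions: list[PlannedSession] = []
    label_rows: list[dict] = []
    client_rows: list[dict] = []
    assess_rows: list[dict] = []
    clip_events = {"PHQ9": 0, "GAD7": 0}

    for ci, cid in enumerate(client_ids):
        rule = rule_of.get(cid)
        tid = int(client_th[ci])
        start = _date(2022, 1, 6) + timedelta(days=int(rng.integers(0, 365)))
        window = 45 if rule == "window" else int(rng.integers(win_lo, win_hi + 1))
        n_sess = int(_trunc_round(rng, s_mean, s_sd, 3, 12))
        if rule in ("duration", "dialogues"):
            n_sess = max(n_sess, 6)
        capacity = 1 + (window - 4) // gap
        n_sess = min(n_sess, capacity)
        if rule == "spacing":
            n_sess = 3
            d0 = int(rng.integers(0, 5))
            days = [d0, d0 + 3, d0 + 3 + gap + int(rng.integers(0, 5))]
        else:
            days = _session_days(rng, n_sess, window, gap)
        durations = np.clip(rng.normal(45.0, 15.0, size=n_sess), 20.0, 80.0)
        mid = n_sess // 2
        if rule == "duration":
            durations[mid] = 10.0

        # Per-session structure. Constant mode draws one value per client so
        # the review-percentage regressor is cluster-constant.
        if config.constant_session_structure:
            nd = np.full(n_sess, _trunc_round(rng, d_mean, d_sd, 15, 55))
            nr = np.full(n_sess, _trunc_round(rng, r_mean, r_sd, 1, 8))
            k_const = int(rng.binomial(int(nr[0]), config.review_probability))
        else:
            nd = _trunc_round(rng, d_mean, d_sd, 15, 55, size=n_sess)
            nr = _trunc_round(rng, r_mean, r_sd, 1, 8, size=n_sess)
            k_const = 0
        nd, nr = nd.astype(int), nr.astype(int)
        if rule == "dialogues":
            nd[mid], nr[mid] = 8, 2

        noun_perm = rng.permutation(np.asarray(T.ACTIVITY_NOUNS))
        noun_ctr = 0
        prev_recs: list[tuple[str, int, str]] = []   # (session_id, index, phrase)
        n_prev_recs = 0
        review_pcts: list[float] = []
        rows_nd: list[int] = []
        rows_rprev: list[int] = []

        for t in range(n_sess):
            sid = f"{cid}_s{t + 1:02d}"
            if t == 0:
                k_t = 0
            elif config.constant_session_structure:
                k_t = min(k_const, n_prev_recs, max(int(nd[t]) - int(nr[t]) - 4, 0))
            else:
                k_t = int(rng.binomial(n_prev_recs, config.review_probability))
                k_t = min(k_t, max(int(nd[t]) - int(nr[t]) - 4, 0))
            n_plan = int(rng.integers(2, 6))
            n_plan = min(n_plan, max(int(nd[t]) - int(nr[t]) - k_t - 1, 0))
            n_fill = int(nd[t]) - int(nr[t]) - k_t - n_plan

            dialogues: list[DialoguePlan] = []
            if not fast:
                for _ in range(int(nr[t])):
                    noun = str(noun_perm[noun_ctr % len(noun_perm)])
                    noun_ctr += 1
                    setting = str(rng.choice(T.ACTIVITY_SETTINGS))
                    dialogues.append(DialoguePlan(KIND_RECOMMENDATION,
                                                  phrase=f"{setting} {noun} routine",
                                                  noun=noun))
                if k_t:
                    chosen = rng.choice(len(prev_recs), size=k_t, replace=False)
                    for j in sorted(int(c) for c in chosen):
                        src_sid, src_idx, src_phrase = prev_recs[j]
                        dialogues.append(DialoguePlan(
                            KIND_REVIEW, phrase=src_phrase,
                            noun=src_phrase.split()[1], reviews=(src_sid, src_idx)))
                for _ in range(n_plan):
                    dialogues.append(DialoguePlan(
                        KIND_PLAN, topic=str(rng.choice(T.EVENT_NOUNS))))
                for _ in range(n_fill):
                    dialogues.append(DialoguePlan(
                        KIND_FILLER, topic=str(rng.choice(T.FILLER_TOPICS))))
                order = rng.permutation(len(dialogues))
                dialogues = [dialogues[int(i)] for i in order]

            ps = PlannedSession(
                session_id=sid, client_id=cid, therapist_id=th_ids[tid],
                org_id=org_ids[int(th_org[tid])],
                date=start + timedelta(days=int(days[t])),
                duration_min=float(round(durations[t], 1)),
                dialogues=dialogues, n_dialogues=int(nd[t]),
                n_recs=int(nr[t]), n_reviews=k_t)
            planned_sessions.append(ps)
            if rule == "duration" and t == mid:
                planted_violations["duration"].append(sid)
            if rule == "dialogues" and t == mid:
                planted_violations["dialogues"].append(sid)

            n_prev_recs = int(nr[t])
            if not fast:
                prev_recs = [(sid, i, d.phrase) for i, d in enumerate(dialogues)
                             if d.kind == KIND_RECOMMENDATION]
                for i, d in enumerate(dialogues):
                    label_rows.append({
                        "session_id": sid, "client_id": cid, "index": i,
                        "kind": d.kind,
                        "is_plan": d.kind in (KIND_PLAN, KIND_RECOMMENDATION),
                        "is_action_recommendation": d.kind == KIND_RECOMMENDATION,
                        "reviews_session_id": d.reviews[0] if d.reviews else None,
                        "reviews_index": d.reviews[1] if d.reviews else None,
                        "noun": d.noun, "phrase": d.phrase, "topic": d.topic,
                    })
            if t >= 1:
                review_pcts.append(100.0 * k_t / int(nd[t]))
                rows_nd.append(int(nd[t]))
                rows_rprev.append(int(nr[t - 1]))

        latent_x = float(np.mean(np.log1p(review_pcts))) if review_pcts else 0.0
        mean_rp = float(np.mean(review_pcts)) if review_pcts else 0.0

        # Instruments on file.
        u = rng.random()
        p_both = config.p_both_instruments
        p_phq_only = max(config.p_phq9 - p_both, 0.0)
        has_phq = u < p_both + p_phq_only
        has_gad = u < p_both or u >= p_both + p_phq_only
        init_phq = int(_trunc_round(rng, 12.2, 5.7, 1, 27))
        init_gad = int(_trunc_round(rng, 11.1, 4.8, 1, 21))
        if rule == "score":
            init_phq = int(rng.integers(1, 5))
            init_gad = int(rng.integers(1, 5))
        else:
            avail = [v for v, h in ((init_phq, has_phq), (init_gad, has_gad)) if h]
            if avail and max(avail) < 5:
                if has_phq and (not has_gad or init_phq >= init_gad):
                    init_phq = 5
                else:
                    init_gad = 5

        row = {"client_id": cid, "therapist_id": th_ids[tid],
               "org_id": org_ids[int(th_org[tid])],
               "n_sessions": n_sess, "window_days": window,
               "latent_log_review": latent_x, "mean_review_pct": mean_rp,
               "has_phq9": has_phq, "has_gad7": has_gad,
               "planted_rule": rule}
        mean_nd = float(np.mean(rows_nd)) if rows_nd else float(nd[0])
        mean_rprev = float(np.mean(rows_rprev)) if rows_rprev else float(nr[0])
        for inst, has, init in (("PHQ9", has_phq, init_phq),
                                ("GAD7", has_gad, init_gad)):
            if not has:
                row[f"initial_{inst.lower()}"] = None
                row[f"final_{inst.lower()}"] = None
                row[f"y_{inst.lower()}"] = None
                continue
            final, y, clipped = generate_outcomes(
                latent_x, init, effects[inst], mean_dialogues=mean_nd,
                mean_recs_prev=mean_rprev, days_examined=window,
                therapist_effect=float(th_eff[tid]), noise_sd=config.noise_sd,
                rng=rng, instrument=inst, discretize=config.discretize_scores)
            clip_events[inst] += int(clipped)
            row[f"initial_{inst.lower()}"] = init
            row[f"final_{inst.lower()}"] = final
            row[f"y_{inst.lower()}"] = y
            for score, when in ((init, start), (final, start + timedelta(days=window))):
                assess_rows.append({"client_id": cid, "instrument": inst,
                                    "score": score, "date": when.isoformat()})
        client_rows.append(row)

    for inst, n in clip_events.items():
        if n:
            logger.info("%s: %d final scores clipped to the instrument range", inst, n)

    sessions = _render_sessions(planned_sessions, config, render_text)
    labels = pd.DataFrame(label_rows)
    clients = pd.DataFrame(client_rows)
    truth = GroundTruth(labels=labels, clients=clients, effects=effects,
                        planted_violations=planted_violations,
                        clip_events=clip_events)
    assessments = pd.DataFrame(assess_rows,
                               columns=["client_id", "instrument", "score", "date"])
    return SyntheticCorpus(config=config, sessions=sessions,
                           planned=planned_sessions, assessments=assessments,
                           truth=truth, rendered=render_text)


def _render_sessions(planned: list[PlannedSession], config: GeneratorConfig,
                     render_text: bool) -> list[Session]:
    sessions = []
    # Independent stream so structural draws above are unaffected by whether
    # text is rendered (the corpus structure is identical either way).
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    for ps in planned:
        utts: list[Utterance] = []
        if render_text:
            for d in ps.dialogues:
                utts.extend(render_dialogue(d.kind, rng, context=d.phrase,
                                            topic=d.topic))
        sessions.append(Session(
            session_id=ps.session_id, client_id=ps.client_id,
            therapist_id=ps.therapist_id, org_id=ps.org_id, date=ps.date,
            duration_min=ps.duration_min, utterances=utts))
    return sessions


# ---------------------------------------------------------------------------
# Ground-truth session metrics (oracle substitution for the text pipeline)

def truth_session_metrics(corpus: SyntheticCorpus) -> pd.DataFrame:
    """Per-session metrics computed from planted labels (not from text).

    One row per session from each client's second onward, matching the
    contract of the review-scoring stage: session_id, client_id, n_dialogues,
    n_recs, n_recs_prev, n_reviewing, review_percentage.
    """
    rows = []
    by_client: dict[str, list[PlannedSession]] = {}
    for ps in corpus.planned:
        by_client.setdefault(ps.client_id, []).append(ps)
    for cid, pss in by_client.items():
        pss = sorted(pss, key=lambda p: p.date)
        for prev, cur in zip(pss, pss[1:]):
            rows.append({
                "session_id": cur.session_id, "client_id": cid,
                "date": cur.date, "n_dialogues": cur.n_dialogues,
                "n_recs": cur.n_recs, "n_recs_prev": prev.n_recs,
                "n_reviewing": cur.n_reviews,
                "review_percentage": 100.0 * cur.n_reviews / cur.n_dialogues,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Persistence

def write_corpus(corpus: SyntheticCorpus, out_dir: str | Path) -> dict[str, Path]:
    from .transcript import write_transcripts_jsonl
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "transcripts": out / "transcripts.jsonl",
        "assessments": out / "assessments.csv",
        "truth_labels": out / "truth_labels.jsonl",
        "truth_clients": out / "truth_clients.csv",
        "truth_meta": out / "truth_meta.json",
    }
    write_transcripts_jsonl(corpus.sessions, paths["transcripts"])
    corpus.assessments.to_csv(paths["assessments"], index=False)
    with open(paths["truth_labels"], "w") as fh:
        for sid, grp in corpus.truth.labels.groupby("session_id", sort=False):
            rec = {"session_id": sid,
                   "labels": grp.drop(columns=["session_id"]).to_dict("records")}
            fh.write(json.dumps(rec, default=str) + "\n")
    corpus.truth.clients.to_csv(paths["truth_clients"], index=False)
    meta = {
        "effects": {k: vars(v) for k, v in corpus.truth.effects.items()},
        "planted_violations": corpus.truth.planted_violations,
        "clip_events": corpus.truth.clip_events,
        "config": corpus.config.to_dict(),
    }
    paths["truth_meta"].write_text(json.dumps(meta, indent=2, default=str))
    return paths
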