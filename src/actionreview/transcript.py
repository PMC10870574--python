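"""Session data model, micro-dialogue segmentation, and session exclusions.

A session transcript is an ordered list of speaker-tagged utterances. For
analysis it is divided into *micro-dialogues*: contiguous blocks of roughly
300 words treated as one topical unit. Segmentation is greedy on whole
utterances — a block closes at the first utterance boundary where the
cumulative word count reaches the target — with a trailing block shorter than
half the target merged into its predecessor. Words are whitespace-delimited
tokens.

Sessions with ten or fewer micro-dialogues or shorter than 15 minutes are
excluded together with the chronologically next session of the same client;
the cascade is evaluated in a single left-to-right pass over the original
order, and a session removed as a "subsequent" casualty still consumes its own
successor if it independently violates a rule.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import date as _date
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

THERAPIST = "therapist"
CLIENT = "client"
_SPEAKER_CODES = {"T": THERAPIST, "C": CLIENT,
                  THERAPIST: THERAPIST, CLIENT: CLIENT}


@dataclass(frozen=True)
class Utterance:
    speaker: str
    text: str

    def __post_init__(self) -> None:
        if self.speaker not in (THERAPIST, CLIENT):
            raise ValueError(f"speaker must be therapist|client, got {self.speaker!r}")

    @property
    def word_count(self) -> int:
        return len(self.text.split())


@dataclass
class MicroDialogue:
    session_id: str
    index: int
    utterances: list[Utterance]

    @property
    def word_count(self) -> int:
        return sum(u.word_count for u in self.utterances)

    @property
    def text(self) -> str:
        return " ".join(u.text for u in self.utterances)


@dataclass
class Session:
    session_id: str
    client_id: str
    therapist_id: str
    org_id: str
    date: _date
    duration_min: float
    utterances: list[Utterance] = field(default_factory=list)
    micro_dialogues: list[MicroDialogue] | None = None

    def __post_init__(self) -> None:
        if self.duration_min <= 0:
            raise ValueError("duration_min must be positive")

    @property
    def n_dialogues(self) -> int:
        if self.micro_dialogues is None:
            raise ValueError(f"session {self.session_id} is not segmented")
        return len(self.micro_dialogues)


def segment_session(utterances: Sequence[Utterance], target_words: int = 300,
                    session_id: str = "") -> list[MicroDialogue]:
    """Greedily partition ``utterances`` into ~``target_words`` blocks.

    The partition property holds exactly: every utterance appears in exactly
    one block, in order.
    """
    if not utterances:
        raise ValueError("cannot segment an empty utterance list")
    blocks: list[list[Utterance]] = []
    current: list[Utterance] = []
    cum = 0
    for utt in utterances:
        if utt.word_count > 2 * target_words and not current:
            logger.warning(
                "utterance of %d words exceeds twice the %d-word target; "
                "kept as its own block", utt.word_count, target_words)
        current.append(utt)
        cum += utt.word_count
        if cum >= target_words:
            blocks.append(current)
            current, cum = [], 0
    if current:
        if blocks and cum < target_words / 2:
            blocks[-1].extend(current)
        else:
            blocks.append(current)
    return [MicroDialogue(session_id=session_id, index=i, utterances=b)
            for i, b in enumerate(blocks)]


def segment_all(sessions: Iterable[Session], target_words: int = 300) -> list[Session]:
    for s in sessions:
        s.micro_dialogues = segment_session(s.utterances, target_words, s.session_id)
    return list(sessions)


def exclude_invalid_sessions(
    sessions: Sequence[Session],
    min_dialogues: int = 11,
    min_duration: float = 15.0,
) -> tuple[list[Session], pd.DataFrame]:
    """Apply the session exclusion cascade.

    ``sessions`` must be sorted by date within client. A session with fewer
    than ``min_dialogues`` micro-dialogues or shorter than ``min_duration``
    minutes is dropped together with the next session of the same client.
    Returns the retained sessions (order preserved) and a log with one row per
    dropped session (session_id, client_id, reason).
    """
    retained: list[Session] = []
    log_rows: list[dict] = []
    drop_next: dict[str, bool] = {}
    for s in sessions:
        reasons = []
        if s.n_dialogues < min_dialogues:
            reasons.append("few_dialogues")
        if s.duration_min < min_duration:
            reasons.append("short_duration")
        casualty = drop_next.pop(s.client_id, False)
        if reasons:
            # Own violation takes precedence in the log and always consumes
            # the client's next session, even if this session was already a
            # casualty of the previous one.
            log_rows.append({"session_id": s.session_id, "client_id": s.client_id,
                             "reason": "+".join(reasons)})
            drop_next[s.client_id] = True
        elif casualty:
            log_rows.append({"session_id": s.session_id, "client_id": s.client_id,
                             "reason": "subsequent"})
        else:
            retained.append(s)
    log = pd.DataFrame(log_rows, columns=["session_id", "client_id", "reason"])
    return retained, log


# ---------------------------------------------------------------------------
# JSONL / CSV interchange

def session_to_record(session: Session) -> dict:
    return {
        "session_id": session.session_id,
        "client_id": session.client_id,
        "therapist_id": session.therapist_id,
        "org_id": session.org_id,
        "date": session.date.isoformat(),
        "duration_min": session.duration_min,
        "utterances": [{"speaker": "T" if u.speaker == THERAPIST else "C",
                        "text": u.text} for u in session.utterances],
    }


def write_transcripts_jsonl(sessions: Iterable[Session], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sessions:
            fh.write(json.dumps(session_to_record(s)) + "\n")


def read_transcripts_jsonl(path: str | Path) -> list[Session]:
    sessions = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            utts = [Utterance(_SPEAKER_CODES[u["speaker"]], u["text"])
                    for u in rec["utterances"]]
            sessions.append(Session(
                session_id=rec["session_id"], client_id=rec["client_id"],
                therapist_id=rec["therapist_id"], org_id=rec["org_id"],
                date=_date.fromisoformat(rec["date"]),
                duration_min=rec["duration_min"], utterances=utts))
    return sessions


def write_segmented_jsonl(sessions: Iterable[Session], path: str | Path) -> None:
    """Persist segmentation as utterance counts per micro-dialogue."""
    with open(path, "w") as fh:
        for s in sessions:
            rec = session_to_record(s)
            rec["dialogue_utterance_counts"] = [
                len(d.utterances) for d in (s.micro_dialogues or [])]
            fh.write(json.dumps(rec) + "\n")


def read_segmented_jsonl(path: str | Path) -> list[Session]:
    sessions = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            utts = [Utterance(_SPEAKER_CODES[u["speaker"]], u["text"])
                    for u in rec["utterances"]]
            s = Session(
                session_id=rec["session_id"], client_id=rec["client_id"],
                therapist_id=rec["therapist_id"], org_id=rec["org_id"],
                date=_date.fromisoformat(rec["date"]),
                duration_min=rec["duration_min"], utterances=utts)
            counts = rec["dialogue_utterance_counts"]
            dialogues, pos = [], 0
            for i, c in enumerate(counts):
                dialogues.append(MicroDialogue(s.session_id, i, utts[pos:pos + c]))
                pos += c
            s.micro_dialogues = dialogues
            sessions.append(s)
    return sessions


def sessions_frame(sessions: Iterable[Session]) -> pd.DataFrame:
    """Session-level metadata table (one row per session)."""
    rows = []
    for s in sessions:
        rows.append({
            "session_id": s.session_id, "client_id": s.client_id,
            "therapist_id": s.therapist_id, "org_id": s.org_id,
            "date": s.date, "duration_min": s.duration_min,
            "n_dialogues": len(s.micro_dialogues) if s.micro_dialogues is not None else None,
        })
    return pd.DataFrame(rows)
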