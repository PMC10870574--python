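"""Cohort construction: inclusion criteria and per-client outcome quantities.

Inclusion, per instrument: a pair of assessments 50-70 days apart (earliest
qualifying pair), at least three retained sessions inside that window with
consecutive gaps of at least five days (sessions outside 15-90 minutes are
dropped before counting), and an initial score of at least 5 on either
instrument (client-level gate shared by both cohorts).

The change score is (initial - final) / initial * 100; positive values mean
symptom improvement. The standardized change (initial - final) /
(initial + final) * 100 maps to [-100, 100] and is used for visualization
only — it never enters a model fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

INSTRUMENT_MAX = {"PHQ9": 27, "GAD7": 21}

# Inclusive severity bounds by initial score.
SEVERITY_BOUNDS = {
    "PHQ9": [("mild", 5, 9), ("moderate", 10, 14),
             ("moderately_severe", 15, 19), ("severe", 20, 27)],
    "GAD7": [("mild", 5, 9), ("moderate", 10, 14), ("severe", 15, 21)],
}

SEVERITY_ORDER = ["mild", "moderate", "moderately_severe", "severe"]


@dataclass(frozen=True)
class SeverityCategory:
    instrument: str
    label: str
    lower: int
    upper: int


@dataclass
class ClientOutcome:
    client_id: str
    instrument: str
    initial_score: int
    final_score: int
    days_examined: int
    change_pct: float
    standardized_change_pct: float
    severity: str


def change_score(initial: float, final: float) -> float:
    """(initial - final) / initial * 100; e.g. 8 -> 4 gives 50.0."""
    if initial == 0:
        raise ValueError("change score undefined for initial score 0")
    return (initial - final) / initial * 100.0


def standardized_change(initial: float, final: float) -> float:
    """Symmetric change index in [-100, 100]; visualization only."""
    if initial + final == 0:
        raise ValueError("standardized change undefined when both scores are 0")
    return (initial - final) / (initial + final) * 100.0


def severity_of(instrument: str, initial_score: int) -> SeverityCategory:
    if instrument not in SEVERITY_BOUNDS:
        raise ValueError(f"unknown instrument {instrument!r}")
    if not (0 <= initial_score <= INSTRUMENT_MAX[instrument]):
        raise ValueError(
            f"{instrument} score {initial_score} outside [0, {INSTRUMENT_MAX[instrument]}]")
    if initial_score < 5:
        return SeverityCategory(instrument, "below_threshold", 0, 4)
    for label, lo, hi in SEVERITY_BOUNDS[instrument]:
        if lo <= initial_score <= hi:
            return SeverityCategory(instrument, label, lo, hi)
    raise AssertionError("unreachable")


def _earliest_qualifying_pair(records: list[tuple], lo: int, hi: int,
                              who: str = "") -> Optional[tuple]:
    """Earliest assessment pair (by first, then second date) spaced in [lo, hi].

    ``records``: (date, score) tuples. Returns ((date0, score0),
    (date1, score1), days) or None.
    """
    rows = sorted(records)
    dates = [r[0] for r in rows]
    if len(set(dates)) != len(dates):
        raise ValueError(f"duplicate same-day assessments for {who}")
    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            d = (rows[j][0] - rows[i][0]).days
            if lo <= d <= hi:
                return rows[i], rows[j], d
    return None


def select_cohort(
    sessions: pd.DataFrame,
    assessments: pd.DataFrame,
    window_days: tuple[int, int] = (50, 70),
    min_sessions: int = 3,
    min_gap_days: int = 5,
    duration_range: tuple[float, float] = (15.0, 90.0),
    min_initial_score: int = 5,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Apply inclusion criteria and compute per-client outcomes.

    ``sessions``: one row per retained session with columns session_id,
    client_id, date, duration_min (post transcript-level exclusion).
    ``assessments``: client_id, instrument, score, date.

    Returns ``(cohorts, exclusion_log)``. ``cohorts`` maps instrument to a
    one-row-per-client frame with the outcome quantities and the ordered list
    of retained in-window session ids. The log records the first failed
    criterion per excluded (client, instrument).
    """
    assessments = assessments.copy()
    assessments["date"] = pd.to_datetime(assessments["date"]).dt.date
    sessions = sessions.copy()
    sessions["date"] = pd.to_datetime(sessions["date"]).dt.date

    lo, hi = window_days
    dlo, dhi = duration_range
    cohort_rows: dict[str, list[dict]] = {"PHQ9": [], "GAD7": []}
    log_rows: list[dict] = []

    # Plain-python per-client structures (hot path for simulation studies).
    sess_by_client: dict[str, list[tuple]] = {}
    for cid, sid, d, dur in zip(sessions.client_id, sessions.session_id,
                                sessions.date, sessions.duration_min):
        sess_by_client.setdefault(cid, []).append((d, float(dur), sid))
    for v in sess_by_client.values():
        v.sort()

    records: dict[str, dict[str, list[tuple]]] = {}
    for cid, inst, score, d in zip(assessments.client_id, assessments.instrument,
                                   assessments.score, assessments.date):
        records.setdefault(cid, {}).setdefault(inst, []).append((d, float(score)))

    for cid in sorted(records):
        entry = {inst: _earliest_qualifying_pair(recs, lo, hi, f"{cid} ({inst})")
                 for inst, recs in records[cid].items()}
        initials = [pair[0][1] for pair in entry.values() if pair is not None]
        passes_gate = bool(initials) and max(initials) >= min_initial_score
        for inst, pair in entry.items():
            if pair is None:
                log_rows.append({"client_id": cid, "instrument": inst,
                                 "reason": "window"})
                continue
            (d0, score0), (d1, score1), days = pair
            if not passes_gate:
                log_rows.append({"client_id": cid, "instrument": inst,
                                 "reason": "score"})
                continue
            in_win = [(d, dur, sid) for d, dur, sid in sess_by_client.get(cid, [])
                      if dlo <= dur <= dhi and d0 <= d <= d1]
            if len(in_win) < min_sessions:
                log_rows.append({"client_id": cid, "instrument": inst,
                                 "reason": "insufficient_sessions"})
                continue
            kept_ids: list[str] = []
            last_date = None
            thinned = False
            for d, _, sid_ in in_win:
                if last_date is None or (d - last_date).days >= min_gap_days:
                    kept_ids.append(sid_)
                    last_date = d
                else:
                    thinned = True
            if len(kept_ids) < min_sessions:
                log_rows.append({"client_id": cid, "instrument": inst,
                                 "reason": "session_spacing" if thinned
                                 else "insufficient_sessions"})
                continue
            # Initial scores are integer by instrument design; final scores may
            # be continuous in simulation settings.
            init, fin = int(round(score0)), float(score1)
            chg = change_score(init, fin) if init > 0 else np.nan
            std = standardized_change(init, fin) if init + fin > 0 else np.nan
            cohort_rows[inst].append({
                "client_id": cid, "instrument": inst,
                "initial_score": init, "final_score": fin,
                "days_examined": days, "change_pct": chg,
                "standardized_change_pct": std,
                "severity": severity_of(inst, init).label,
                "window_start": d0, "window_end": d1,
                "retained_session_ids": kept_ids,
            })

    cohorts = {inst: pd.DataFrame(rows) for inst, rows in cohort_rows.items()}
    log = pd.DataFrame(log_rows, columns=["client_id", "instrument", "reason"])
    return cohorts, log


def build_analysis_table(cohort: pd.DataFrame,
                         session_metrics: pd.DataFrame,
                         sessions: pd.DataFrame) -> pd.DataFrame:
    """Assemble the session-level design table for the association model.

    One row per retained in-window session from each included client's second
    retained session onward, joining that session's review metrics with the
    client-level outcome. The cube-root/log1p transforms are applied by the
    model constructor, not here.
    """
    from .association import transform_change, transform_review

    pair_rows = [(crow.client_id, sid)
                 for crow in cohort.itertuples()
                 for sid in crow.retained_session_ids[1:]]
    pairs = pd.DataFrame(pair_rows, columns=["client_id", "session_id"])
    df = pairs.merge(
        session_metrics[["session_id", "review_percentage", "n_dialogues",
                         "n_recs_prev"]], on="session_id", how="inner")
    df = df.merge(sessions[["session_id", "therapist_id", "org_id"]],
                  on="session_id", how="left")
    client = cohort.set_index("client_id")
    df["initial_score"] = df.client_id.map(client.initial_score).astype(int)
    df["days_examined"] = df.client_id.map(client.days_examined).astype(int)
    df["severity"] = df.client_id.map(client.severity)
    df["change_pct"] = df.client_id.map(client.change_pct).astype(float)
    df["x_review"] = transform_review(df.review_percentage.to_numpy(dtype=float))
    df["y"] = transform_change(df.change_pct.to_numpy())
    cols = ["client_id", "therapist_id", "org_id", "session_id",
            "review_percentage", "x_review", "n_dialogues", "n_recs_prev",
            "initial_score", "days_examined", "severity", "change_pct", "y"]
    return df[cols]


def client_mean_review(analysis_table: pd.DataFrame) -> pd.DataFrame:
    """Per-client mean review percentage across analyzed sessions."""
    g = analysis_table.groupby("client_id")
    out = g.agg(mean_review_pct=("review_percentage", "mean"),
                severity=("severity", "first"),
                change_pct=("change_pct", "first"),
                initial_score=("initial_score", "first"),
                n_rows=("session_id", "size")).reset_index()
    return out
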