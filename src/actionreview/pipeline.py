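"""End-to-end orchestration: generate/ingest -> segment -> detect ->
summarize -> review-score -> cohort -> GEE -> report.

Each stage persists its outputs under the run directory and is re-runnable
from the persisted inputs: a stage executes only when one of its outputs is
missing (or ``force=True``), so deleting an intermediate regenerates exactly
that stage and nothing upstream. All randomness fans out from a single root
seed. A machine-readable manifest records the config hash, seeds, per-stage
timing and output digests.

In synthetic mode the annotation datasets that train the detection models are
sampled from the generator's ground truth — the synthetic counterpart of the
expert-labeled dialogue sets — and held-out evaluation against the remaining
latent labels is written under ``evaluation/``. The latent truth never feeds
the detection, scoring, cohort or association stages themselves.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .agreement import rate_agreement
from .association import fit_gee, fit_stratified
from .cohort import build_analysis_table, client_mean_review, select_cohort
from .config import GeneratorConfig
from .detect import (ExtractiveSummarizer, classify_cascade, evaluate_detection,
                     train_stage_classifier)
from .generate import generate_corpus, write_corpus
from .review import (TfidfEmbeddingSpace, calibrate_threshold,
                     compute_session_metrics, detect_reviews, metrics_frame)
from .transcript import (exclude_invalid_sessions, read_segmented_jsonl,
                         read_transcripts_jsonl, segment_all, sessions_frame,
                         write_segmented_jsonl)

N_STAGE1_LABELS = 1191   # annotated future-plan dialogues
N_STAGE2_LABELS = 311    # annotated action-recommendation dialogues
N_CALIBRATION_PAIRS = 90
TRAIN_FRACTION = 0.7     # 70/30 stratified split (paper reserved 15-30%)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class Stage:
    name: str
    outputs: list[str]
    run: Callable[["PipelineRun"], None]


class PipelineRun:
    """Stateful orchestrator for one run directory."""

    def __init__(self, config: GeneratorConfig, out_dir: str | Path,
                 bootstrap_reps: int = 1000,
                 threshold_override: Optional[float] = None,
                 instruments: Sequence[str] = ("PHQ9", "GAD7"),
                 make_plot: bool = False):
        self.config = config
        self.out = Path(out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        (self.out / "evaluation").mkdir(exist_ok=True)
        self.bootstrap_reps = bootstrap_reps
        self.threshold_override = threshold_override
        self.instruments = list(instruments)
        self.make_plot = make_plot
        self.timings: dict[str, float] = {}

    def path(self, name: str) -> Path:
        return self.out / name

    # -- stage bodies -------------------------------------------------------

    def stage_generate(self) -> None:
        corpus = generate_corpus(self.config, render_text=True)
        write_corpus(corpus, self.out)

    def stage_segment(self) -> None:
        sessions = read_transcripts_jsonl(self.path("transcripts.jsonl"))
        sessions.sort(key=lambda s: (s.client_id, s.date))
        segment_all(sessions)
        retained, log = exclude_invalid_sessions(sessions)
        write_segmented_jsonl(retained, self.path("segmented.jsonl"))
        log.to_csv(self.path("session_exclusions.csv"), index=False)
        sessions_frame(retained).to_csv(self.path("sessions.csv"), index=False)

    def _truth_labels(self) -> pd.DataFrame:
        rows = []
        with open(self.path("truth_labels.jsonl")) as fh:
            for line in fh:
                rec = json.loads(line)
                for lab in rec["labels"]:
                    lab["session_id"] = rec["session_id"]
                    rows.append(lab)
        return pd.DataFrame(rows)

    def stage_detect(self) -> None:
        sessions = read_segmented_jsonl(self.path("segmented.jsonl"))
        dialogues = [d for s in sessions for d in s.micro_dialogues]
        texts = [d.text for d in dialogues]
        truth = self._truth_labels().set_index(["session_id", "index"])
        keys = [(d.session_id, d.index) for d in dialogues]
        pos_of = {k: i for i, k in enumerate(keys)}
        known = [k in truth.index for k in keys]
        # Separate streams so re-running from persisted annotations yields
        # byte-identical predictions.
        rng = np.random.default_rng(np.random.SeedSequence([self.config.seed, 11]))
        rng_split = np.random.default_rng(
            np.random.SeedSequence([self.config.seed, 12]))
        rng_rater = np.random.default_rng(
            np.random.SeedSequence([self.config.seed, 14]))

        ann1, ann2 = (self.path("annotations_stage1.csv"),
                      self.path("annotations_stage2.csv"))
        idx_known = [i for i, k in enumerate(known) if k]
        if ann1.exists() and ann2.exists():
            # User-supplied (or previously persisted) annotation datasets.
            def _load(path):
                df = pd.read_csv(path)
                pos = [pos_of[(s, int(i))]
                       for s, i in zip(df.session_id, df.dialogue_index)
                       if (s, int(i)) in pos_of]
                lab = [bool(l) for (s, i), l in
                       zip(zip(df.session_id, df.dialogue_index), df.label)
                       if (s, int(i)) in pos_of]
                return np.asarray(pos), np.asarray(lab, dtype=bool)
            stage1_idx, is_plan = _load(ann1)
            stage2_idx, is_rec = _load(ann2)
        else:
            # Synthetic annotation datasets (stand-ins for expert labeling).
            n1 = min(N_STAGE1_LABELS, len(idx_known))
            stage1_idx = rng.choice(idx_known, size=n1, replace=False)
            is_plan = np.array([bool(truth.loc[keys[i], "is_plan"])
                                for i in stage1_idx])
            plan_pool = [i for i in idx_known
                         if bool(truth.loc[keys[i], "is_plan"])]
            n2 = min(N_STAGE2_LABELS, len(plan_pool))
            stage2_idx = rng.choice(plan_pool, size=n2, replace=False)
            is_rec = np.array([bool(truth.loc[keys[i], "is_action_recommendation"])
                               for i in stage2_idx])

        def _split(idx, y):
            order = rng_split.permutation(len(idx))
            n_train = int(round(TRAIN_FRACTION * len(idx)))
            tr, va = order[:n_train], order[n_train:]
            # stratification guard: both classes in the training part
            if y[tr].all() or not y[tr].any():
                order = np.concatenate([np.flatnonzero(y)[:1],
                                        np.flatnonzero(~y)[:1],
                                        order])
                tr = np.unique(order[:n_train + 2])[:n_train]
            return idx[tr], y[tr], idx[va], y[va]

        s1_tr, y1_tr, s1_va, y1_va = _split(np.asarray(stage1_idx), is_plan)
        s2_tr, y2_tr, s2_va, y2_va = _split(np.asarray(stage2_idx), is_rec)
        # Persist the (synthetic) annotation datasets behind the classifiers.
        for name, idx, y in (("stage1", stage1_idx, is_plan),
                             ("stage2", stage2_idx, is_rec)):
            pd.DataFrame({
                "session_id": [keys[i][0] for i in idx],
                "dialogue_index": [keys[i][1] for i in idx],
                "label": np.asarray(y, dtype=int),
            }).to_csv(self.path(f"annotations_{name}.csv"), index=False)
        clf_plans = train_stage_classifier([texts[i] for i in s1_tr], y1_tr,
                                           "plans", random_state=self.config.seed % 2**16)
        clf_recs = train_stage_classifier([texts[i] for i in s2_tr], y2_tr,
                                          "recommendations",
                                          random_state=self.config.seed % 2**16)
        labels = classify_cascade(clf_plans, clf_recs, dialogues)

        pred = pd.DataFrame([{
            "session_id": l.session_id, "index": l.index,
            "is_plan": l.is_plan, "is_action_recommendation": l.is_action_recommendation,
            "plan_score": l.plan_score, "rec_score": l.rec_score,
        } for l in labels])
        pred.to_csv(self.path("predictions.csv"), index=False)

        # Summaries: general for every dialogue, recommendation summaries for
        # predicted recommendations.
        summarizer = ExtractiveSummarizer().fit(texts)
        with open(self.path("summaries.jsonl"), "w") as fh:
            for d, l in zip(dialogues, labels):
                rec = {"session_id": d.session_id, "index": d.index,
                       "general": summarizer.summarize(d, "general")}
                if l.is_action_recommendation:
                    rec["recommendation"] = summarizer.summarize(d, "recommendation", l)
                fh.write(json.dumps(rec) + "\n")

        # Held-out evaluation of each stage and of the full cascade.
        train_used = set(s1_tr) | set(s2_tr)
        held = [i for i in idx_known if i not in train_used]
        truth_rec = np.array([bool(truth.loc[keys[i], "is_action_recommendation"])
                              for i in held])
        pred_rec = np.array([labels[i].is_action_recommendation for i in held])
        ev = {
            "stage1_holdout": evaluate_detection(
                clf_plans.predict([texts[i] for i in s1_va]), y1_va).to_dict(),
            "stage2_holdout": evaluate_detection(
                clf_recs.predict([texts[i] for i in s2_va]), y2_va).to_dict(),
            "cascade_held_out": evaluate_detection(pred_rec, truth_rec).to_dict(),
            "n_held_out": len(held),
        }
        # Inter-rater protocol on the synthetic annotation set: two simulated
        # raters re-label a 220-item subset with independent 5% error.
        sub = rng_rater.choice(idx_known, size=min(220, len(idx_known)),
                               replace=False)
        base = np.array([bool(truth.loc[keys[i], "is_action_recommendation"])
                         for i in sub])
        flip_a = rng_rater.random(base.size) < 0.05
        flip_b = rng_rater.random(base.size) < 0.05
        agr = rate_agreement(base ^ flip_a, base ^ flip_b)
        ev["simulated_inter_rater"] = agr.to_dict()
        (self.out / "evaluation" / "detection_eval.json").write_text(
            json.dumps(ev, indent=2))

    def stage_review(self) -> None:
        summaries = {}
        with open(self.path("summaries.jsonl")) as fh:
            for line in fh:
                rec = json.loads(line)
                summaries[(rec["session_id"], rec["index"])] = rec
        pred = pd.read_csv(self.path("predictions.csv"))
        sess = pd.read_csv(self.path("sessions.csv"))
        truth = self._truth_labels().set_index(["session_id", "index"])

        space = TfidfEmbeddingSpace().fit(
            [r["general"] for r in summaries.values()]
            + [r["recommendation"] for r in summaries.values() if "recommendation" in r])

        rng = np.random.default_rng(np.random.SeedSequence([self.config.seed, 13]))
        n_recs_by_session = pred.groupby("session_id")["is_action_recommendation"].sum()
        keys_by_session: dict[str, list[tuple[str, int]]] = {}
        for k in summaries:
            keys_by_session.setdefault(k[0], []).append(k)
        for ks in keys_by_session.values():
            ks.sort()
        rec_idx_by_session = {
            sid: list(grp[grp.is_action_recommendation]["index"])
            for sid, grp in pred.groupby("session_id", sort=False)}

        # Consecutive retained session pairs per client.
        sess = sess.sort_values(["client_id", "date"])
        pairs = []
        for _, grp in sess.groupby("client_id", sort=False):
            ids = list(grp.session_id)
            pairs += list(zip(ids, ids[1:]))

        # Pass 1: the detector's decision statistic — max similarity of each
        # session-t general summary against session t-1's recommendation
        # summaries — harvested for every judged dialogue.
        def _pair_io(prev_sid, cur_sid):
            rec_sums = [(prev_sid, int(i), summaries[(prev_sid, int(i))]["recommendation"])
                        for i in rec_idx_by_session.get(prev_sid, [])
                        if "recommendation" in summaries.get((prev_sid, int(i)), {})]
            gen_sums = [(sid, i, summaries[(sid, i)]["general"])
                        for (sid, i) in keys_by_session.get(cur_sid, [])]
            return gen_sums, rec_sums

        pos_pool, neg_pool = [], []
        for prev_sid, cur_sid in pairs:
            gen_sums, rec_sums = _pair_io(prev_sid, cur_sid)
            if not rec_sums:
                continue
            for j in detect_reviews(gen_sums, rec_sums, space, float("inf")):
                key = (j.session_id, j.index)
                if key not in truth.index:
                    continue
                if truth.loc[key, "kind"] == "review":
                    pos_pool.append(j.max_similarity)
                else:
                    neg_pool.append(j.max_similarity)

        # Calibration on a labeled sample of (similarity, label) pairs
        # (positives = dialogues genuinely reviewing a prior recommendation).
        n_pos = min(len(pos_pool), N_CALIBRATION_PAIRS // 3)
        n_neg = min(len(neg_pool), N_CALIBRATION_PAIRS - n_pos)
        sims = np.concatenate([
            rng.choice(pos_pool, size=n_pos, replace=False),
            rng.choice(neg_pool, size=n_neg, replace=False)])
        labels = np.array([True] * n_pos + [False] * n_neg)
        cal = calibrate_threshold(sims, labels)
        threshold = (self.threshold_override if self.threshold_override is not None
                     else cal.threshold)
        (self.out / "calibration.json").write_text(json.dumps({
            "threshold": threshold, "calibrated_threshold": cal.threshold,
            "precision": cal.precision, "recall": cal.recall,
            "f_score": cal.f_score, "n_pairs": int(labels.size),
            "n_positive": int(n_pos)}, indent=2))
        cal.grid.to_csv(self.out / "evaluation" / "calibration_grid.csv", index=False)

        # Pass 2: review judgments at the calibrated threshold; metrics from
        # the second session of each client onward.
        all_judgments, metrics = [], []
        truth_flags, pred_flags = [], []
        for prev_sid, cur_sid in pairs:
            gen_sums, rec_sums = _pair_io(prev_sid, cur_sid)
            judgments = detect_reviews(gen_sums, rec_sums, space, threshold)
            all_judgments += judgments
            n_recs_cur = int(n_recs_by_session.get(cur_sid, 0))
            n_recs_prev = int(n_recs_by_session.get(prev_sid, 0))
            m = compute_session_metrics(cur_sid, cur_sid.split("_s")[0], judgments,
                                        n_recs_cur, n_recs_prev)
            metrics.append(m)
            for j in judgments:
                key = (j.session_id, j.index)
                if key in truth.index:
                    truth_flags.append(truth.loc[key, "kind"] == "review")
                    pred_flags.append(j.is_review)

        pd.DataFrame([{
            "session_id": j.session_id, "index": j.index,
            "max_similarity": j.max_similarity, "is_review": j.is_review,
            "matched_session_id": j.matched_session_id,
            "matched_index": j.matched_index} for j in all_judgments]
        ).to_csv(self.path("review_judgments.csv"), index=False)
        metrics_frame(metrics).to_csv(self.path("session_metrics.csv"), index=False)
        ev = {"review_detector": evaluate_detection(pred_flags, truth_flags).to_dict(),
              "n_judged": len(pred_flags)}
        (self.out / "evaluation" / "review_eval.json").write_text(
            json.dumps(ev, indent=2))

    def stage_cohort(self) -> None:
        sessions = pd.read_csv(self.path("sessions.csv"))
        assessments = pd.read_csv(self.path("assessments.csv"))
        metrics = pd.read_csv(self.path("session_metrics.csv"))
        cohorts, log = select_cohort(sessions, assessments,
                                     window_days=self.config.window_days)
        log.to_csv(self.path("cohort_exclusions.csv"), index=False)
        for inst, cohort in cohorts.items():
            tag = inst.lower()
            if cohort.empty:
                continue
            cohort.drop(columns=["retained_session_ids"]).to_csv(
                self.path(f"cohort_{tag}.csv"), index=False)
            table = build_analysis_table(cohort, metrics, sessions)
            table.to_csv(self.path(f"analysis_{tag}.csv"), index=False)

    def stage_associate(self) -> None:
        out = {}
        for inst in self.instruments:
            tag = inst.lower()
            p = self.path(f"analysis_{tag}.csv")
            if not p.exists():
                continue
            table = pd.read_csv(p)
            if table.empty or table.client_id.nunique() < 2:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                main = fit_gee(table, interactions="none")
                inter_spec = ("review_x_initial+review_x_dialogues"
                              if inst == "PHQ9" else "review_x_initial")
                inter = fit_gee(table, interactions=inter_spec)
                strata, skipped = fit_stratified(table)
                boot = inter.bootstrap(B=self.bootstrap_reps,
                                       seed=self.config.seed + 17)
            entry = {
                "formula_main": main.model.formula,
                "formula_interaction": inter.model.formula,
                "main": json.loads(main.term_table().to_json(orient="index")),
                "interaction": json.loads(inter.term_table().to_json(orient="index")),
                "interaction_spec": inter_spec,
                "stratified": {lab: json.loads(r.term_table().to_json(orient="index"))
                               for lab, r in strata.items()},
                "stratified_skipped": skipped,
                "bootstrap": {
                    "B": boot.n_samples, "n_failed": boot.n_failed,
                    "conf_int": json.loads(boot.conf_int.to_json(orient="index")),
                    "verified": boot.verified,
                },
                "n_clusters": main.n_clusters, "n_rows": main.nobs,
                "note": "stratified post-hoc models are exploratory and carry "
                        "no multiple-comparisons correction",
            }
            out[inst] = entry
            main.term_table(focal_only=False).to_csv(
                self.path(f"gee_main_{tag}.csv"))
            inter.term_table(focal_only=False).to_csv(
                self.path(f"gee_interaction_{tag}.csv"))
        self.path("gee_results.json").write_text(json.dumps(out, indent=2))

    def stage_report(self) -> None:
        path = self.path("analysis_phq9.csv")
        rows = []
        if path.exists():
            table = pd.read_csv(path)
            mild = client_mean_review(table)
            mild = mild[mild.severity == "mild"]
            if not mild.empty:
                # standardized change recomputed from the cohort file
                cohort = pd.read_csv(self.path("cohort_phq9.csv")).set_index("client_id")
                mild = mild.join(cohort["standardized_change_pct"], on="client_id")
                groups, summary = fig2_grouping(mild)
                groups.to_csv(self.path("fig2_groups.csv"), index=False)
                summary.to_csv(self.path("fig2_summary.csv"), index=False)
                rows = summary.to_dict("records")
                if self.make_plot:
                    _plot_fig2(mild, groups, self.path("fig2_boxplot.png"))
        manifest = {
            "config_hash": hashlib.sha256(
                json.dumps(self.config.to_dict(), sort_keys=True, default=str)
                .encode()).hexdigest(),
            "seed": self.config.seed,
            "bootstrap_reps": self.bootstrap_reps,
            "timings_s": {k: round(v, 2) for k, v in self.timings.items()},
            "fig2_summary": rows,
            "outputs": {p.name: _sha256(p) for p in sorted(self.out.glob("*"))
                        if p.is_file() and p.name != "manifest.json"},
        }
        self.path("manifest.json").write_text(json.dumps(manifest, indent=2))

    # -- orchestration ------------------------------------------------------

    def stages(self) -> list[Stage]:
        return [
            Stage("generate", ["transcripts.jsonl", "assessments.csv",
                               "truth_labels.jsonl", "truth_clients.csv"],
                  PipelineRun.stage_generate),
            Stage("segment", ["segmented.jsonl", "session_exclusions.csv",
                              "sessions.csv"], PipelineRun.stage_segment),
            Stage("detect", ["predictions.csv", "summaries.jsonl"],
                  PipelineRun.stage_detect),
            Stage("review", ["calibration.json", "session_metrics.csv",
                             "review_judgments.csv"], PipelineRun.stage_review),
            Stage("cohort", ["cohort_exclusions.csv", "analysis_phq9.csv"],
                  PipelineRun.stage_cohort),
            Stage("associate", ["gee_results.json"], PipelineRun.stage_associate),
            Stage("report", ["manifest.json"], PipelineRun.stage_report),
        ]

    def run(self, only: Optional[Sequence[str]] = None,
            force: bool = False) -> dict:
        for stage in self.stages():
            if only is not None and stage.name not in only:
                continue
            missing = [o for o in stage.outputs if not self.path(o).exists()]
            if not force and not missing:
                continue
            t0 = time.perf_counter()
            stage.run(self)
            self.timings[stage.name] = time.perf_counter() - t0
        if self.path("manifest.json").exists():
            return json.loads(self.path("manifest.json").read_text())
        return {}


def run_pipeline(config: GeneratorConfig, out_dir: str | Path,
                 bootstrap_reps: int = 1000,
                 threshold_override: Optional[float] = None,
                 only: Optional[Sequence[str]] = None,
                 force: bool = False, make_plot: bool = False) -> dict:
    """Execute the pipeline end to end (or the named stages); returns the manifest."""
    run = PipelineRun(config, out_dir, bootstrap_reps=bootstrap_reps,
                      threshold_override=threshold_override,
                      make_plot=make_plot)
    return run.run(only=only, force=force)


def _plot_fig2(clients: pd.DataFrame, groups: pd.DataFrame, path: Path) -> None:
    """Box plot of standardized change by review-percentage group."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    merged = clients.merge(groups[["client_id", "group"]], on="client_id")
    data = [merged[merged.group == g].standardized_change_pct.to_numpy()
            for g in sorted(merged.group.unique())]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.boxplot(data, tick_labels=[f"group {g}" for g in sorted(merged.group.unique())])
    ax.set_ylabel("standardized change in score (%)")
    ax.set_xlabel("mean review-percentage group (low to high)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def fig2_grouping(clients: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Three-way grouping of clients by mean review percentage.

    Group 1: clients whose mean review percentage is exactly zero. The
    remaining clients are split at the median of their means, the lower half
    taking the tie. Returns (per-client group assignment, per-group
    five-number summary of standardized change).
    """
    df = clients.copy()
    zero = df[df.mean_review_pct == 0]
    nonzero = df[df.mean_review_pct > 0]
    assignments = []
    for _, r in zero.iterrows():
        assignments.append({"client_id": r.client_id, "group": 1,
                            "mean_review_pct": r.mean_review_pct})
    if nonzero.empty:
        warnings.warn("no clients with nonzero mean review percentage; "
                      "only the zero group is emitted")
        parts = {1: zero}
    else:
        med = float(nonzero.mean_review_pct.median())
        low = nonzero[nonzero.mean_review_pct <= med]
        high = nonzero[nonzero.mean_review_pct > med]
        for g, part in ((2, low), (3, high)):
            for _, r in part.iterrows():
                assignments.append({"client_id": r.client_id, "group": g,
                                    "mean_review_pct": r.mean_review_pct})
        parts = {1: zero, 2: low, 3: high}
    rows = []
    for g, part in parts.items():
        if part.empty:
            continue
        v = part["standardized_change_pct"].astype(float)
        rows.append({
            "group": g, "n": int(len(part)),
            "review_pct_min": float(part.mean_review_pct.min()),
            "review_pct_max": float(part.mean_review_pct.max()),
            "min": float(v.min()), "q1": float(v.quantile(0.25)),
            "median": float(v.median()), "q3": float(v.quantile(0.75)),
            "max": float(v.max()),
        })
    groups = pd.DataFrame(assignments)
    summary = pd.DataFrame(rows)
    return groups, summary
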