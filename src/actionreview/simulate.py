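"""Simulation studies: parameter recovery, type-I error, stratified patterns.

These drivers run the numeric path of the pipeline — corpus structure,
latent session metrics, cohort selection and GEE fitting — without rendering
transcript text, so replicate studies at hundreds of clients stay cheap. The
latent session metrics equal what the text pipeline recovers when detection
is perfect (the oracle-substitution property checked in the test suite), so
what these studies isolate is the statistical estimator, not detector error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .association import fit_gee, fit_stratified
from .cohort import build_analysis_table, select_cohort
from .config import GeneratorConfig, recovery_config
from .generate import SyntheticCorpus, generate_corpus, truth_session_metrics
from .transcript import sessions_frame


def analysis_table_from_truth(corpus: SyntheticCorpus,
                              instrument: str = "PHQ9") -> pd.DataFrame:
    """Cohort-selected session-level analysis table built from latent metrics."""
    sessions = sessions_frame(corpus.sessions)
    metrics = truth_session_metrics(corpus)
    cohorts, _ = select_cohort(sessions, corpus.assessments,
                               window_days=corpus.config.window_days)
    cohort = cohorts[instrument]
    if cohort.empty:
        return pd.DataFrame()
    return build_analysis_table(cohort, metrics, sessions)


@dataclass
class RecoveryReplicate:
    seed: int
    estimate_review: float
    se_review: float
    p_review: float
    ci_review: tuple[float, float]
    estimate_interaction: float
    ci_interaction: tuple[float, float]
    n_clusters: int
    converged: bool


def run_recovery_replicate(seed: int, beta_review: float = 0.61,
                           beta_interaction: float = -0.02,
                           interactions: str = "review_x_initial",
                           n_clients: int = 400,
                           **config_overrides) -> RecoveryReplicate:
    """One replicate: generate a numeric corpus with planted coefficients,
    run cohort selection and the interaction GEE, return the focal estimates.
    """
    cfg = recovery_config(seed=seed, beta_review=beta_review,
                          beta_interaction=beta_interaction,
                          n_clients=n_clients, **config_overrides)
    corpus = generate_corpus(cfg, render_text=False)
    table = analysis_table_from_truth(corpus, "PHQ9")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = fit_gee(table, interactions=interactions)
    ci = res.conf_int()
    has_inter = interactions != "none"
    return RecoveryReplicate(
        seed=seed,
        estimate_review=float(res.params["log_review_pct"]),
        se_review=float(res.bse["log_review_pct"]),
        p_review=float(res.pvalues["log_review_pct"]),
        ci_review=(float(ci.lower["log_review_pct"]),
                   float(ci.upper["log_review_pct"])),
        estimate_interaction=(float(res.params["log_review_pct:initial_score"])
                              if has_inter else float("nan")),
        ci_interaction=((float(ci.lower["log_review_pct:initial_score"]),
                         float(ci.upper["log_review_pct:initial_score"]))
                        if has_inter else (float("nan"), float("nan"))),
        n_clusters=res.n_clusters, converged=res.converged)


def recovery_study(n_reps: int, base_seed: int, beta_review: float = 0.61,
                   beta_interaction: float = -0.02,
                   interactions: str = "review_x_initial",
                   n_clients: int = 400, **config_overrides) -> pd.DataFrame:
    """Replicate recovery study; one row per replicate."""
    rows = []
    for r in range(n_reps):
        rep = run_recovery_replicate(
            seed=int((base_seed + 1) * 10_000 + r) % (2**31 - 1),
            beta_review=beta_review, beta_interaction=beta_interaction,
            interactions=interactions, n_clients=n_clients, **config_overrides)
        rows.append({
            "seed": rep.seed,
            "estimate_review": rep.estimate_review,
            "se_review": rep.se_review,
            "p_review": rep.p_review,
            "ci_lo_review": rep.ci_review[0], "ci_hi_review": rep.ci_review[1],
            "covered_review": rep.ci_review[0] <= beta_review <= rep.ci_review[1],
            "estimate_interaction": rep.estimate_interaction,
            "covered_interaction": (rep.ci_interaction[0] <= beta_interaction
                                    <= rep.ci_interaction[1]),
            "rejected_review": rep.p_review < 0.05,
            "converged": rep.converged,
        })
    return pd.DataFrame(rows)


def stratified_pattern_study(n_reps: int, base_seed: int,
                             mild_beta: float = 0.8,
                             n_clients: int = 400,
                             n_therapists: int = 10,
                             n_organizations: int = 3) -> pd.DataFrame:
    """Plant a review effect only in the mild stratum; fit stratified GEEs.

    Returns one row per (replicate, stratum) with the review estimate and
    Wald decision, for checking that the effect surfaces where planted and
    false-positive rates stay near nominal elsewhere. The hierarchy is kept
    shallow (default 10 therapists) so each stratum retains many clusters per
    fixed-effect dummy; deep hierarchies overfit small strata and inflate
    robust-Wald rejection.
    """
    from dataclasses import replace

    rows = []
    for r in range(n_reps):
        seed = int((base_seed + 1) * 20_000 + r) % (2**31 - 1)
        cfg = recovery_config(
            seed=seed, beta_review=0.0, beta_interaction=0.0,
            n_clients=n_clients, n_therapists=n_therapists,
            n_organizations=n_organizations)
        cfg = GeneratorConfig.from_dict({
            **cfg.to_dict(),
            "effects_phq9": replace(
                cfg.effects_phq9,
                beta_review_by_severity={"mild": mild_beta}).__dict__,
        })
        corpus = generate_corpus(cfg, render_text=False)
        table = analysis_table_from_truth(corpus, "PHQ9")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            strata, _ = fit_stratified(table)
        for label, res in strata.items():
            rows.append({
                "replicate": r, "stratum": label,
                "estimate_review": float(res.params["log_review_pct"]),
                "p_review": float(res.pvalues["log_review_pct"]),
                "rejected": bool(res.pvalues["log_review_pct"] < 0.05),
                "n_clusters": res.n_clusters,
            })
    return pd.DataFrame(rows)
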