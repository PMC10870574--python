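"""Marginal association between review percentage and symptom change.

The estimand is population-average: the change score (cube-root transformed)
is regressed on the log1p-transformed session review percentage with
generalized estimating equations — Gaussian family, identity link, clients as
clusters, exchangeable working correlation and robust (sandwich) standard
errors — controlling for dialogues per session, the previous session's
recommendation count, the initial symptom score, the assessment window in
days, and therapist/organization fixed effects (dummy coded, first-observed
level as reference). Covariates enter uncentered; interactions are built on
the transformed review variable. Severity-stratified fits drop the
interaction terms, and a client-level cluster bootstrap provides
nonparametric confidence intervals.

Organized statsmodels-style: :class:`ReviewOutcomeModel` is built from the
session-level analysis table and its ``fit()`` returns a
:class:`ReviewOutcomeResults` carrying estimates, robust uncertainties,
diagnostics, ``summary()`` and ``bootstrap()``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.genmod import cov_struct as _cov_struct

INTERACTION_SPECS = ("none", "review_x_initial", "review_x_initial+review_x_dialogues")

CORE_TERMS = ["log_review_pct", "n_dialogues", "n_recs_prev",
              "initial_score", "days_examined"]


# ---------------------------------------------------------------------------
# Variable transforms

def transform_change(change_pct: float | np.ndarray) -> float | np.ndarray:
    """Signed cube root, sign(x) * |x|^(1/3); handles negative, zero, positive."""
    x = np.asarray(change_pct, dtype=float)
    out = np.sign(x) * np.abs(x) ** (1.0 / 3.0)
    return float(out) if out.ndim == 0 else out

def transform_review(review_pct: float | np.ndarray) -> float | np.ndarray:
    """ln(1 + x); zero maps to zero, negatives are rejected."""
    x = np.asarray(review_pct, dtype=float)
    if np.any(x < 0):
        raise ValueError("review percentages cannot be negative")
    out = np.log1p(x)
    return float(out) if out.ndim == 0 else out


class ClampedExchangeable(_cov_struct.Exchangeable):
    """Exchangeable working correlation with the dependence parameter capped.

    When the outcome is (nearly) constant within cluster the moment estimate
    of the within-cluster correlation approaches 1 and the working
    correlation matrix becomes singular; capping keeps the weighting defined.
    Point estimates for cluster-constant designs are invariant to the cap.
    """

    def __init__(self, max_alpha: float = 0.99):
        super().__init__()
        self.max_alpha = max_alpha

    def update(self, params) -> None:
        super().update(params)
        if self.dep_params > self.max_alpha:
            self.dep_params = self.max_alpha


# ---------------------------------------------------------------------------
# Design construction

def _dummies_first_observed(values: pd.Series, prefix: str) -> pd.DataFrame:
    levels = list(dict.fromkeys(values))
    cat = pd.Categorical(values, categories=levels)
    d = pd.get_dummies(cat, prefix=prefix, dtype=float)
    return d.iloc[:, 1:]  # first-observed level is the reference


def build_design(table: pd.DataFrame, interactions: str = "none",
                 fixed_effects: bool = True
                 ) -> tuple[pd.Series, pd.DataFrame, pd.Series, list[str]]:
    """Build (y, X, groups, dropped_columns) from the analysis table.

    Aliased fixed-effect dummies (e.g. organization indicators spanned by
    therapist indicators when therapists are nested in organizations) are
    detected by QR and dropped with a warning; an aliased core covariate is
    an error.
    """
    if interactions not in INTERACTION_SPECS:
        raise ValueError(f"interactions must be one of {INTERACTION_SPECS}")
    X = pd.DataFrame({"const": np.ones(len(table))}, index=table.index)
    X["log_review_pct"] = table["x_review"].astype(float)
    X["n_dialogues"] = table["n_dialogues"].astype(float)
    X["n_recs_prev"] = table["n_recs_prev"].astype(float)
    X["initial_score"] = table["initial_score"].astype(float)
    X["days_examined"] = table["days_examined"].astype(float)
    if interactions != "none":
        X["log_review_pct:initial_score"] = X.log_review_pct * X.initial_score
    if interactions == "review_x_initial+review_x_dialogues":
        X["log_review_pct:n_dialogues"] = X.log_review_pct * X.n_dialogues
    n_protected = X.shape[1]
    if fixed_effects:
        X = pd.concat([X, _dummies_first_observed(table.therapist_id, "th"),
                       _dummies_first_observed(table.org_id, "org")], axis=1)

    # Rank audit: non-pivoted QR flags each column dependent on its
    # predecessors (protected core columns come first).
    A = X.to_numpy(dtype=float)
    R = np.linalg.qr(A, mode="r")
    diag = np.abs(np.diag(R))
    colnorm = np.linalg.norm(A, axis=0)
    dependent = np.ones(A.shape[1], dtype=bool)  # cols beyond row rank
    k = diag.size
    dependent[:k] = diag <= 1e-8 * np.maximum(colnorm[:k], 1.0)
    dropped = [c for c, d in zip(X.columns, dependent) if d]
    core_dropped = [c for i, c in enumerate(X.columns[:n_protected]) if dependent[i]]
    if core_dropped:
        raise ValueError(f"design is rank deficient in core terms: {core_dropped}")
    if dropped:
        warnings.warn(f"dropping aliased fixed-effect columns: {dropped}",
                      stacklevel=2)
        X = X.drop(columns=dropped)

    y = table["y"].astype(float)
    groups = table["client_id"]
    return y, X, groups, dropped


# ---------------------------------------------------------------------------
# Model / Results

class ReviewOutcomeModel:
    """GEE model of transformed symptom change on transformed review percentage.

    Parameters
    ----------
    table : DataFrame
        Session-level analysis table with columns client_id, therapist_id,
        org_id, x_review, n_dialogues, n_recs_prev, initial_score,
        days_examined, y (one row per analyzed session).
    interactions : str
        "none", "review_x_initial", or
        "review_x_initial+review_x_dialogues".
    cov_struct : str
        "exchangeable" (default) or "independence" working correlation.
    fixed_effects : bool
        Include therapist and organization dummy indicators.
    """

    def __init__(self, table: pd.DataFrame, interactions: str = "none",
                 cov_struct: str = "exchangeable", fixed_effects: bool = True):
        if table["client_id"].nunique() < 2:
            raise ValueError("GEE requires at least two clusters")
        self.table = table.reset_index(drop=True)
        self.interactions = interactions
        self.cov_struct_name = cov_struct
        self.fixed_effects = fixed_effects
        self.endog, self.exog, self.groups, self.dropped_columns = build_design(
            self.table, interactions, fixed_effects)

    @classmethod
    def from_analysis_table(cls, table: pd.DataFrame, **kwargs) -> "ReviewOutcomeModel":
        return cls(table, **kwargs)

    # statsmodels-flavoured alias
    from_dataframe = from_analysis_table

    @property
    def formula(self) -> str:
        """Model formula with transform provenance."""
        terms = ["log1p(review_pct)", "n_dialogues", "n_recs_prev",
                 "initial_score", "days_examined"]
        if self.interactions != "none":
            terms.append("log1p(review_pct):initial_score")
        if self.interactions == "review_x_initial+review_x_dialogues":
            terms.append("log1p(review_pct):n_dialogues")
        if self.fixed_effects:
            terms += ["C(therapist_id)", "C(org_id)"]
        return "cbrt(change_pct) ~ " + " + ".join(terms)

    def _make_cov_struct(self):
        if self.cov_struct_name == "exchangeable":
            return ClampedExchangeable()
        if self.cov_struct_name == "independence":
            return _cov_struct.Independence()
        raise ValueError("cov_struct must be 'exchangeable' or 'independence'")

    def fit(self, maxiter: int = 100,
            cov_type: str = "robust") -> "ReviewOutcomeResults":
        """Fit by GEE. ``cov_type``: "robust" (sandwich, default) or
        "bias_reduced" (Mancl-DeRouen small-sample correction, appropriate
        when the cluster count per parameter is low, e.g. severity strata).
        """
        cov = self._make_cov_struct()
        model = sm.GEE(self.endog, self.exog, groups=self.groups,
                       family=sm.families.Gaussian(), cov_struct=cov)
        converged = True
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            res = model.fit(maxiter=maxiter, cov_type=cov_type)
        for w in caught:
            if "onvergence" in str(w.message) or "iteration limit" in str(w.message).lower():
                converged = False
        dep = getattr(cov, "dep_params", None)
        dep = 0.0 if dep is None else float(np.atleast_1d(dep)[0])
        return ReviewOutcomeResults(self, res, converged=converged,
                                    dep_params=dep)


@dataclass
class BootstrapValidation:
    """Client-level cluster-bootstrap percentile intervals for focal terms."""
    n_samples: int
    n_failed: int
    conf_int: pd.DataFrame      # index: term; columns: lower, upper
    draws: pd.DataFrame = field(repr=False)
    verified: dict = field(default_factory=dict)  # term -> bootstrap/Wald agree


class ReviewOutcomeResults:
    """Fitted GEE results: estimates, robust SEs, CIs, diagnostics, bootstrap."""

    def __init__(self, model: ReviewOutcomeModel, res, converged: bool,
                 dep_params: float):
        self.model = model
        self._res = res
        self.converged = converged
        self.dep_params = dep_params
        self.params: pd.Series = res.params
        self.bse: pd.Series = res.bse
        self.pvalues: pd.Series = res.pvalues
        self.n_clusters = int(model.table["client_id"].nunique())
        self.nobs = int(len(model.table))
        self.focal_terms = [t for t in model.exog.columns
                            if not t.startswith(("th_", "org_")) and t != "const"]

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        ci = self._res.conf_int(alpha=alpha)
        ci.columns = ["lower", "upper"]
        return ci

    def term_table(self, focal_only: bool = True) -> pd.DataFrame:
        ci = self.conf_int()
        terms = (["const"] + self.focal_terms) if focal_only else list(self.params.index)
        return pd.DataFrame({
            "coefficient": self.params[terms],
            "robust_se": self.bse[terms],
            "p_value": self.pvalues[terms],
            "ci_lower": ci.lower[terms],
            "ci_upper": ci.upper[terms],
        })

    def summary(self) -> str:
        head = (
            f"Review-outcome GEE (Gaussian, identity link)\n"
            f"  {self.model.formula}\n"
            f"  interactions: {self.model.interactions}; working correlation: "
            f"{self.model.cov_struct_name} (dep={self.dep_params:.3f})\n"
            f"  clusters (clients): {self.n_clusters}; sessions: {self.nobs}; "
            f"converged: {self.converged}\n"
            f"  outcome: cube-root change score; review: log1p(review %)\n"
            f"  dropped aliased columns: {len(self.model.dropped_columns)}\n")
        return head + self.term_table().to_string(float_format=lambda v: f"{v: .4f}")

    def bootstrap(self, B: int = 1000, seed: int = 0,
                  focal_terms: Optional[Sequence[str]] = None) -> BootstrapValidation:
        return bootstrap_validate(self, B=B, seed=seed, focal_terms=focal_terms)


# ---------------------------------------------------------------------------
# Convenience operations

def fit_gee(table: pd.DataFrame, interactions: str = "none",
            cov_struct: str = "exchangeable",
            fixed_effects: bool = True,
            cov_type: str = "robust") -> ReviewOutcomeResults:
    return ReviewOutcomeModel(table, interactions=interactions,
                              cov_struct=cov_struct,
                              fixed_effects=fixed_effects).fit(cov_type=cov_type)


def fit_stratified(table: pd.DataFrame, cov_struct: str = "exchangeable",
                   fixed_effects: bool = True, min_clusters: int = 2,
                   cov_type: str = "bias_reduced"
                   ) -> tuple[dict[str, ReviewOutcomeResults], list[str]]:
    """Severity-stratified fits without interaction terms.

    Strata with fewer than ``min_clusters`` clients are skipped (reported in
    the returned skip list), not errored. Inference defaults to the
    Mancl-DeRouen bias-reduced sandwich: strata carry far fewer clusters than
    the pooled model, where the uncorrected sandwich is anti-conservative.
    """
    results: dict[str, ReviewOutcomeResults] = {}
    skipped: list[str] = []
    for label, sub in table.groupby("severity", sort=False):
        if sub["client_id"].nunique() < min_clusters:
            skipped.append(str(label))
            continue
        try:
            results[str(label)] = fit_gee(sub, interactions="none",
                                          cov_struct=cov_struct,
                                          fixed_effects=fixed_effects,
                                          cov_type=cov_type)
        except (ValueError, np.linalg.LinAlgError) as exc:
            # e.g. a covariate constant within a very small stratum
            warnings.warn(f"stratum {label!r} skipped: {exc}")
            skipped.append(str(label))
    return results, skipped


def bootstrap_validate(results: ReviewOutcomeResults, B: int = 1000,
                       seed: int = 0,
                       focal_terms: Optional[Sequence[str]] = None,
                       max_failure_rate: float = 0.10) -> BootstrapValidation:
    """Nonparametric cluster bootstrap: resample clients with replacement,
    refit, and take percentile 95% intervals per focal coefficient.

    A coefficient is "verified" when the bootstrap interval's exclusion of
    zero agrees with the Wald test's alpha=0.05 decision. Non-convergent or
    failing replicates are dropped and counted; more than
    ``max_failure_rate`` failures is an error.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    model = results.model
    focal = list(focal_terms) if focal_terms else list(results.focal_terms)
    rng = np.random.default_rng(seed)
    table = model.table
    by_client = dict(tuple(table.groupby("client_id", sort=False)))
    client_ids = list(by_client)

    draws: list[dict] = []
    n_failed = 0
    for b in range(B):
        chosen = rng.choice(client_ids, size=len(client_ids), replace=True)
        parts = []
        for k, cid in enumerate(chosen):
            part = by_client[cid].copy()
            part["client_id"] = f"{cid}#{k}"
            parts.append(part)
        boot = pd.concat(parts, ignore_index=True)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                r = ReviewOutcomeModel(
                    boot, interactions=model.interactions,
                    cov_struct=model.cov_struct_name,
                    fixed_effects=model.fixed_effects).fit()
            if not r.converged:
                n_failed += 1
                continue
            draws.append({t: r.params.get(t, np.nan) for t in focal})
        except (ValueError, np.linalg.LinAlgError):
            n_failed += 1
    if n_failed > max_failure_rate * B:
        raise RuntimeError(
            f"{n_failed}/{B} bootstrap replicates failed to converge")
    draws_df = pd.DataFrame(draws)
    ci = pd.DataFrame({
        "lower": draws_df.quantile(0.025),
        "upper": draws_df.quantile(0.975),
    })
    wald_sig = results.pvalues[focal] < 0.05
    boot_sig = (ci.lower > 0) | (ci.upper < 0)
    verified = {t: bool(wald_sig[t] == boot_sig[t]) for t in focal}
    return BootstrapValidation(n_samples=B, n_failed=n_failed, conf_int=ci,
                               draws=draws_df, verified=verified)
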