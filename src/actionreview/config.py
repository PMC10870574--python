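"""Generator configuration.

Defaults encode the study conditions the synthetic corpus emulates: the
hierarchy sizes (14 behavioral-health organizations, 126 therapists, 450
clients), the per-session count distributions (sessions per client 5.2 (2.1),
micro-dialogues per session 31.5 (7.7), action recommendations per session
4.7 (3.2) truncated to [1, 8]), a 50-70 day assessment window with sessions at
least 5 days apart, and outcome effects on the cube-root change scale with a
log1p(review%) main effect of 0.61 and a review-by-initial-score interaction
of -0.02 for the depression instrument (0.23 / -0.02 for anxiety).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import yaml

VIOLATION_RULES = ("duration", "dialogues", "window", "score", "spacing")


@dataclass(frozen=True)
class OutcomeEffects:
    """Planted coefficients of the outcome model on the cube-root change scale.

    ``change^(1/3) = intercept + beta_review * log1p(review%) +
    beta_initial * initial + beta_interaction * log1p(review%) * initial +
    beta_dialogues * dialogues/session + beta_recs * recs/previous session +
    beta_days * days examined + therapist effect + noise``.
    """

    intercept: float = -1.93
    beta_review: float = 0.61
    beta_interaction: float = -0.02
    beta_initial: float = 0.09
    beta_dialogues: float = 0.04
    beta_recs: float = 0.01
    beta_days: float = 0.02
    # Optional per-severity override of beta_review (labels: mild, moderate,
    # moderately_severe, severe). Used for stratified-effect simulations.
    beta_review_by_severity: Optional[dict] = None


GAD7_DEFAULT_EFFECTS = OutcomeEffects(
    intercept=-2.07,
    beta_review=0.23,
    beta_interaction=-0.02,
    beta_initial=0.16,
    beta_dialogues=0.01,
    beta_recs=0.03,
    beta_days=0.02,
)


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int
    n_organizations: int = 14
    n_therapists: int = 126
    n_clients: int = 450
    sessions_per_client: tuple[float, float] = (5.2, 2.1)
    dialogues_per_session: tuple[float, float] = (31.5, 7.7)
    recs_per_session: tuple[float, float] = (4.7, 3.2)
    review_probability: float = 0.14
    window_days: tuple[int, int] = (50, 70)
    min_intersession_days: int = 5
    effect_beta_review: float = 0.61
    effect_beta_interaction: float = -0.02
    noise_sd: float = 1.0
    therapist_sd: float = 0.4
    org_sd: float = 0.2
    # Full planted outcome models; ``effect_beta_review``/``effect_beta_interaction``
    # above override the primary-instrument (PHQ-9) block for spec-level access.
    effects_phq9: OutcomeEffects = field(default_factory=OutcomeEffects)
    effects_gad7: OutcomeEffects = field(default_factory=lambda: GAD7_DEFAULT_EFFECTS)
    # Fraction of clients planted to violate each inclusion rule, keys from
    # VIOLATION_RULES. Violating clients are disjoint across rules so exclusion
    # counts are exactly auditable.
    violation_fractions: dict = field(default_factory=dict)
    # Hold dialogue/recommendation/review counts constant within client so the
    # session-level regressor is cluster-constant and the marginal-regression
    # estimand equals the planted coefficient exactly (see docs/methods.md).
    constant_session_structure: bool = False
    # Round final scores to the integer instrument scale (realistic). Disabled
    # for sharp parameter recovery: coarse rounding (granularity 100/initial
    # on the change scale) through the concave cube root attenuates slopes.
    discretize_scores: bool = True
    # Probabilities that a client has each instrument on file (joint: both with
    # probability p_both; remaining mass split to single-instrument clients).
    p_both_instruments: float = 0.80
    p_phq9: float = 0.884
    p_gad7: float = 0.916

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("n_organizations", "n_therapists", "n_clients"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 <= self.review_probability <= 1.0):
            raise ValueError("review_probability must lie in [0, 1]")
        lo, hi = self.window_days
        if lo > hi:
            raise ValueError("window_days min must be <= max")
        mean, sd = self.sessions_per_client
        if mean < 3 and sd == 0:
            raise ValueError(
                "sessions_per_client mean < 3 with zero sd cannot satisfy the "
                "minimum of three sessions per client"
            )
        for rule in self.violation_fractions:
            if rule not in VIOLATION_RULES:
                raise ValueError(f"unknown violation rule {rule!r}")
        if sum(self.violation_fractions.values()) > 0.5:
            raise ValueError("planted violation fractions must sum to <= 0.5")

    @property
    def phq9_effects(self) -> OutcomeEffects:
        """PHQ-9 outcome block with the flat spec-level overrides applied."""
        base = self.effects_phq9
        if (base.beta_review == self.effect_beta_review
                and base.beta_interaction == self.effect_beta_interaction):
            return base
        return OutcomeEffects(
            intercept=base.intercept,
            beta_review=self.effect_beta_review,
            beta_interaction=self.effect_beta_interaction,
            beta_initial=base.beta_initial,
            beta_dialogues=base.beta_dialogues,
            beta_recs=base.beta_recs,
            beta_days=base.beta_days,
            beta_review_by_severity=base.beta_review_by_severity,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        for key in ("sessions_per_client", "dialogues_per_session",
                    "recs_per_session", "window_days"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        for key in ("effects_phq9", "effects_gad7"):
            if key in d and isinstance(d[key], dict):
                d[key] = OutcomeEffects(**d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "seed" not in d:
            raise ValueError("config YAML must set a seed")
        return cls.from_dict(d)


def reference_corpus_config(seed: int = 2024, n_clients: int = 60,
                            **overrides) -> GeneratorConfig:
    """Configuration of the seeded reference corpus used for text-pipeline
    evaluation: small enough to render full transcripts quickly, large enough
    for held-out classifier evaluation (~300 sessions, ~9,000 micro-dialogues).
    """
    defaults = dict(
        seed=seed,
        n_organizations=6,
        n_therapists=24,
        n_clients=n_clients,
    )
    defaults.update(overrides)
    return GeneratorConfig(**defaults)


def recovery_config(seed: int, beta_review: float = 0.61,
                    beta_interaction: float = -0.02,
                    **overrides) -> GeneratorConfig:
    """Configuration for parameter-recovery simulations: 400 clients, a
    compact 40-therapist / 5-organization hierarchy, numeric corpus only,
    constant within-client session structure so the GEE estimand equals the
    planted coefficients exactly.
    """
    effects = OutcomeEffects(beta_review=beta_review,
                             beta_interaction=beta_interaction)
    defaults = dict(
        seed=seed,
        n_organizations=5,
        n_therapists=40,
        n_clients=400,
        effect_beta_review=beta_review,
        effect_beta_interaction=beta_interaction,
        effects_phq9=effects,
        constant_session_structure=True,
        discretize_scores=False,
    )
    defaults.update(overrides)
    return GeneratorConfig(**defaults)
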