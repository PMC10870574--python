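"""Inter-rater agreement statistics (percent agreement and Cohen's kappa).

Annotation tasks here are binary, so unweighted kappa applies. Multi-rater
panels are summarized as all pairwise statistics plus their mean.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np


@dataclass(frozen=True)
class AgreementResult:
    percent_agreement: float
    kappa: Optional[float]
    p_observed: float
    p_expected: float
    n_items: int
    note: str = ""

    def to_dict(self) -> dict:
        return {"percent_agreement": self.percent_agreement, "kappa": self.kappa,
                "p_observed": self.p_observed, "p_expected": self.p_expected,
                "n_items": self.n_items, "note": self.note}


def _check(a: Sequence, b: Sequence) -> tuple[np.ndarray, np.ndarray]:
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("label vectors must be 1-D and of equal length")
    if a.size == 0:
        raise ValueError("label vectors must be non-empty")
    return a, b


def percent_agreement(labels_a: Sequence, labels_b: Sequence) -> float:
    a, b = _check(labels_a, labels_b)
    return 100.0 * float(np.mean(a == b))


def _expected_agreement(a: np.ndarray, b: np.ndarray) -> float:
    labels = np.union1d(a, b)
    pe = 0.0
    for lab in labels:
        pe += float(np.mean(a == lab)) * float(np.mean(b == lab))
    return pe


def cohens_kappa(labels_a: Sequence, labels_b: Sequence) -> float:
    """Two-rater Cohen's kappa, (p_o - p_e) / (1 - p_e).

    Returns NaN (with a warning) when both raters used a single identical
    label, where chance agreement equals 1 and kappa is undefined.
    """
    a, b = _check(labels_a, labels_b)
    p_o = float(np.mean(a == b))
    p_e = _expected_agreement(a, b)
    if p_e >= 1.0:
        warnings.warn("kappa undefined: both raters constant and identical "
                      "(perfect agreement, chance agreement = 1)")
        return math.nan
    return (p_o - p_e) / (1.0 - p_e)


def rate_agreement(labels_a: Sequence, labels_b: Sequence) -> AgreementResult:
    a, b = _check(labels_a, labels_b)
    p_o = float(np.mean(a == b))
    p_e = _expected_agreement(a, b)
    if p_e >= 1.0:
        return AgreementResult(100.0 * p_o, None, p_o, p_e, int(a.size),
                               note="kappa undefined: perfect agreement between "
                                    "constant raters")
    return AgreementResult(100.0 * p_o, (p_o - p_e) / (1.0 - p_e), p_o, p_e,
                           int(a.size))


def rate_agreement_csv(path, column_a: int = 0, column_b: int = 1) -> AgreementResult:
    """Agreement statistics from a two-column label CSV (with header)."""
    import pandas as pd
    df = pd.read_csv(path)
    return rate_agreement(df.iloc[:, column_a].to_numpy(),
                          df.iloc[:, column_b].to_numpy())


def pairwise_agreement(ratings: dict[str, Sequence]) -> dict:
    """All pairwise agreement statistics for a panel of raters, plus means."""
    pairs = {}
    for (ra, la), (rb, lb) in combinations(ratings.items(), 2):
        pairs[f"{ra}|{rb}"] = rate_agreement(la, lb)
    kappas = [r.kappa for r in pairs.values() if r.kappa is not None]
    pcts = [r.percent_agreement for r in pairs.values()]
    return {
        "pairs": pairs,
        "mean_percent_agreement": float(np.mean(pcts)) if pcts else math.nan,
        "mean_kappa": float(np.mean(kappas)) if kappas else math.nan,
    }
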