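"""Risk-group stratification from patient scores.

The trained score is turned into high/low risk groups by running the
maximally selected rank statistic once more with the score itself as the
covariate; the resulting cutoff maximizes the survival separation on the
training cohort. A validation cohort can reuse the transferred cutoff or
refit its own (default: refit).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DataValidationError
from .expression import RAW_COUNTS, ExpressionMatrix, normalize_pipeline
from .maxstat import MaxstatConfig, maxstat_test
from .signature import RiskScores, SignatureModel, compute_risk_score
from .survival import KMCurve, SurvivalData, TestResult, km_estimate, logrank_test

__all__ = [
    "StratificationResult",
    "find_score_cutoff",
    "stratify_cohort",
    "validate_on_cohort",
]


@dataclass
class StratificationResult:
    """High/low risk split with per-group survival curves and log-rank test."""

    cutoff: float
    sample_ids: list
    score: np.ndarray
    group: np.ndarray  # "high" / "low" per sample
    frac_high: float
    km_high: KMCurve | None
    km_low: KMCurve | None
    logrank: TestResult | None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_ids, "score": self.score, "group": self.group}
        )

    def km_dataframe(self) -> pd.DataFrame:
        frames = []
        for label, km in (("high", self.km_high), ("low", self.km_low)):
            if km is not None:
                df = km.to_dataframe()
                df.insert(0, "group", label)
                frames.append(df)
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def find_score_cutoff(
    scores: RiskScores, s: SurvivalData, cfg: MaxstatConfig | None = None
) -> float:
    """Maxstat cutoff on the score axis (maximum overall-survival separation)."""
    s = s.reorder(scores.sample_ids)
    return float(maxstat_test(scores.score, s, cfg).cutpoint)


def stratify_cohort(scores: RiskScores, s: SurvivalData, cutoff: float) -> StratificationResult:
    """Split a cohort at ``cutoff`` (high = score > cutoff) and compare survival."""
    if len(scores) == 0:
        raise DataValidationError("empty cohort")
    s = s.reorder(scores.sample_ids)
    high = scores.score > cutoff
    group = np.where(high, "high", "low")
    km_high = km_low = None
    logrank = None
    if high.all() or not high.any():
        warnings.warn(
            "cutoff outside the score range: single risk group, log-rank skipped",
            stacklevel=2,
        )
        km = km_estimate(s)
        if high.any():
            km_high = km
        else:
            km_low = km
    else:
        km_high = km_estimate(
            SurvivalData(
                [i for i, h in zip(s.sample_ids, high) if h], s.time[high], s.event[high]
            )
        )
        km_low = km_estimate(
            SurvivalData(
                [i for i, h in zip(s.sample_ids, high) if not h], s.time[~high], s.event[~high]
            )
        )
        logrank = logrank_test(s, high.astype(int))
    return StratificationResult(
        cutoff=float(cutoff),
        sample_ids=list(scores.sample_ids),
        score=scores.score.copy(),
        group=group,
        frac_high=float(high.mean()),
        km_high=km_high,
        km_low=km_low,
        logrank=logrank,
    )


def validate_on_cohort(
    model: SignatureModel,
    m: ExpressionMatrix,
    s: SurvivalData,
    cutoff_policy: str = "refit",
    cfg: MaxstatConfig | None = None,
    max_missing_frac: float = 0.1,
) -> StratificationResult:
    """Apply a trained signature to an independent cohort.

    Raw counts are normalized with the cohort's own size factors into the
    model's training space. ``cutoff_policy="transfer"`` reuses the training
    score cutoff (honest external validation); ``"refit"`` (default) re-runs
    maxstat on the validation scores, accommodating cross-cohort score-scale
    shifts at the price of an optimistic log-rank p-value.
    """
    if cutoff_policy not in ("transfer", "refit"):
        raise DataValidationError(f"unknown cutoff policy {cutoff_policy!r}")
    if m.space == RAW_COUNTS:
        log = model.metadata.get("space", "log_normalized") == "log_normalized"
        m = normalize_pipeline(m, log_transform=log, min_expressed_frac=None)
    scores = compute_risk_score(model, m, max_missing_frac=max_missing_frac)
    if cutoff_policy == "transfer":
        if model.score_cutoff is None:
            raise DataValidationError("transfer policy requires a trained score cutoff")
        cutoff = model.score_cutoff
    else:
        cutoff = find_score_cutoff(scores, s, cfg)
    return stratify_cohort(scores, s, cutoff)
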