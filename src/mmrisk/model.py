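"""Statsmodels-style front end: fit the risk signature to a cohort.

``RiskScoreModel`` holds the training data (raw counts + survival) and the
fitting configuration; ``fit()`` runs normalization, gene screening,
signature construction, patient scoring and risk stratification, returning a
``RiskScoreResults`` carrying the estimates, diagnostics, a ``summary()``
table, prediction/validation for new cohorts, and Kaplan-Meier plotting.

Example
-------
>>> from mmrisk import SimulationConfig, simulate_cohort, RiskScoreModel
>>> counts, surv, truth = simulate_cohort(SimulationConfig(seed=7))
>>> res = RiskScoreModel(counts, surv).fit()
>>> print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .exceptions import DataValidationError
from .expression import (
    RAW_COUNTS,
    ExpressionMatrix,
    filter_low_expression,
    normalize,
    size_factors,
)
from .maxstat import MaxstatConfig
from .signature import (
    GeneScreen,
    RiskScores,
    SignatureModel,
    build_signature,
    compute_risk_score,
    screen_genes,
)
from .stratify import (
    StratificationResult,
    find_score_cutoff,
    stratify_cohort,
    validate_on_cohort,
)
from .survival import SurvivalData


class RiskScoreModel:
    """Prognostic gene-signature model for a counts + survival cohort.

    Parameters
    ----------
    counts
        Raw count ``ExpressionMatrix`` (genes x samples). Already-normalized
        matrices are accepted and used as-is.
    survival
        Overall-survival follow-up for the same samples.
    maxstat_config
        Cutpoint window and selection-adjusted p-value method.
    alpha
        BH-adjusted selection threshold (default 0.05).
    min_expressed_frac
        Genes with zero counts in at least ``1 - min_expressed_frac`` of
        samples are dropped before screening.
    log_transform
        Screen and score on log2(normalized + 1) values (default).
    """

    def __init__(
        self,
        counts: ExpressionMatrix,
        survival: SurvivalData,
        maxstat_config: MaxstatConfig | None = None,
        alpha: float = 0.05,
        min_expressed_frac: float = 0.2,
        log_transform: bool = True,
    ):
        if set(counts.sample_ids) != set(survival.sample_ids):
            raise DataValidationError("counts and survival cover different samples")
        self.counts = counts
        self.survival = survival.reorder(counts.sample_ids)
        self.maxstat_config = maxstat_config or MaxstatConfig()
        self.alpha = alpha
        self.min_expressed_frac = min_expressed_frac
        self.log_transform = log_transform

    @classmethod
    def from_dataframes(
        cls, counts_df: pd.DataFrame, survival_df: pd.DataFrame, **kwargs
    ) -> "RiskScoreModel":
        """Build from a genes x samples count DataFrame and a survival table
        with columns sample_id / os_time / os_event."""
        return cls(
            ExpressionMatrix.from_dataframe(counts_df, RAW_COUNTS),
            SurvivalData.from_dataframe(survival_df),
            **kwargs,
        )

    def fit(self) -> "RiskScoreResults":
        counts = self.counts
        if counts.space == RAW_COUNTS:
            filtered = filter_low_expression(counts, self.min_expressed_frac)
            sf = size_factors(filtered)
            expr = normalize(filtered, sf, log_transform=self.log_transform)
        else:
            expr = counts

        screen = screen_genes(expr, self.survival, self.maxstat_config)
        signature = build_signature(
            screen,
            alpha=self.alpha,
            metadata={
                "space": expr.space,
                "n_samples": expr.n_samples,
                "n_genes_screened": len(screen.results),
                "alpha": self.alpha,
                "minprop": self.maxstat_config.minprop,
                "maxprop": self.maxstat_config.maxprop,
                "pmethod": self.maxstat_config.pmethod,
                "package_version": _pkg_version,
            },
        )
        scores = stratification = None
        if signature.genes:
            scores = compute_risk_score(signature, expr)
            cutoff = find_score_cutoff(scores, self.survival, self.maxstat_config)
            signature.score_cutoff = cutoff
            stratification = stratify_cohort(scores, self.survival, cutoff)
        return RiskScoreResults(
            model=self,
            expression=expr,
            screen=screen,
            signature=signature,
            scores=scores,
            stratification=stratification,
        )


@dataclass
class RiskScoreResults:
    """Fitted signature with training-cohort scores and stratification."""

    model: RiskScoreModel
    expression: ExpressionMatrix
    screen: GeneScreen
    signature: SignatureModel
    scores: RiskScores | None = None
    stratification: StratificationResult | None = None
    _screen_frame: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def screen_table(self) -> pd.DataFrame:
        if self._screen_frame is None:
            self._screen_frame = self.screen.to_dataframe()
        return self._screen_frame

    def predict(self, counts: ExpressionMatrix, max_missing_frac: float = 0.1) -> RiskScores:
        """Risk scores for a new cohort (raw counts are normalized with the
        cohort's own size factors into the training space)."""
        if counts.space == RAW_COUNTS:
            counts = normalize(
                counts, size_factors(counts), log_transform=self.model.log_transform
            )
        return compute_risk_score(self.signature, counts, max_missing_frac=max_missing_frac)

    def validate(
        self,
        counts: ExpressionMatrix,
        survival: SurvivalData,
        cutoff_policy: str = "refit",
    ) -> StratificationResult:
        """Stratify an independent cohort with the trained signature."""
        return validate_on_cohort(
            self.signature, counts, survival,
            cutoff_policy=cutoff_policy, cfg=self.model.maxstat_config,
        )

    def plot_km(self, stratification: StratificationResult | None = None, ax=None):
        """Kaplan-Meier curves of the high- and low-risk groups."""
        from .plotting import plot_km

        strat = stratification if stratification is not None else self.stratification
        if strat is None:
            raise DataValidationError("no stratification available (empty signature?)")
        return plot_km(strat, ax=ax)

    def summary(self) -> str:
        sig = self.signature
        lines = [
            "RNA-seq risk signature",
            "=" * 58,
            f"Samples:                 {self.expression.n_samples}",
            f"Events:                  {self.model.survival.n_events}",
            f"Genes screened:          {len(self.screen.results)}"
            f" (skipped {len(self.screen.skipped)})",
            f"Genes selected (q<{sig.alpha:g}): {len(sig.genes)}"
            f"  [{sig.n_poor} adverse-high / {sig.n_good} protective-high]",
        ]
        if self.stratification is not None:
            st = self.stratification
            p = st.logrank.p_value if st.logrank is not None else float("nan")
            lines += [
                f"Score cutoff (maxstat):  {st.cutoff:.4f}",
                f"High-risk fraction:      {st.frac_high:.3f}",
                f"Log-rank p (high vs low): {p:.3g}",
            ]
        lines.append("=" * 58)
        if sig.genes:
            top = sig.to_dataframe().sort_values("p_adj").head(10)
            lines.append("Top signature genes (by adjusted p):")
            lines.append(
                top.to_string(
                    index=False,
                    formatters={
                        "cutpoint": "{:.3f}".format,
                        "beta": "{:+.3f}".format,
                        "p_adj": "{:.2e}".format,
                    },
                )
            )
        return "\n".join(lines)
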