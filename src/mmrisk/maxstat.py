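"""Maximally selected rank statistics for a right-censored outcome.

For a continuous covariate x (here: a gene's expression, or a patient risk
score) the procedure evaluates, at every admissible cutpoint mu, the
standardized linear rank statistic of the split ``{x <= mu}`` versus
``{x > mu}`` built from log-rank scores, and reports the cutpoint that
maximizes the absolute standardized statistic M. Because the cutpoint is
chosen to maximize the separation, the naive normal p-value is optimistic;
a selection-adjusted p-value (Lausen-Schumacher improved Bonferroni
approximation, or a plain Bonferroni fallback) is attached.

The log-rank score of subject i is ``event_i - H(t_i)`` where H is the
Nelson-Aalen cumulative hazard estimate; these are the standard rank scores
for censored outcomes and sum to zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats

from .exceptions import DataValidationError, DegenerateCovariateError
from .survival import SurvivalData, _event_table

__all__ = ["MaxstatConfig", "MaxstatResult", "logrank_scores", "maxstat_test", "pvalue_adjusted"]

HIGH_IS_ADVERSE = "high_is_adverse"
LOW_IS_ADVERSE = "low_is_adverse"


@dataclass(frozen=True)
class MaxstatConfig:
    """Admissible cutpoint window and p-value approximation.

    minprop/maxprop bound the fraction of subjects in the low group; the
    defaults (0.1, 0.9) mirror the usual choice for expression cutpoints.
    ``pmethod``: ``lau92`` (improved Bonferroni approximation for the
    maximally selected statistic) or ``none_bonferroni`` (plain Bonferroni
    over the candidate cutpoints, conservative).
    """

    minprop: float = 0.1
    maxprop: float = 0.9
    pmethod: str = "lau92"

    def __post_init__(self):
        if not (0.0 < self.minprop < 0.5):
            raise DataValidationError("minprop must lie in (0, 0.5)")
        if not (0.5 < self.maxprop < 1.0):
            raise DataValidationError("maxprop must lie in (0.5, 1)")
        if self.pmethod not in ("lau92", "none_bonferroni"):
            raise DataValidationError(f"unknown pmethod {self.pmethod!r}")


@dataclass
class MaxstatResult:
    """Best cutpoint with its standardized statistic and adjusted p-value.

    ``cutpoint`` is the largest covariate value assigned to the low group
    (membership rule: low group = ``x <= cutpoint``). ``direction`` states
    which side of the cutpoint has the worse survival.
    """

    cutpoint: float
    statistic: float
    p_adjusted: float
    n_candidates: int
    direction: str
    z_at_cutpoint: float = 0.0


def logrank_scores(s: SurvivalData) -> np.ndarray:
    """Per-subject log-rank scores ``a_i = event_i - H(t_i)``.

    H is the Nelson-Aalen estimator, evaluated at each subject's own
    (event or censoring) time. The scores sum to zero.
    """
    if len(s) == 0:
        raise DataValidationError("empty survival data")
    times, d, n_at_risk = _event_table(s.time, s.event)
    if times.size == 0:
        return np.zeros(len(s))
    cumhaz = np.cumsum(d / n_at_risk)
    idx = np.searchsorted(times, s.time, side="right")
    H = np.concatenate(([0.0], cumhaz))[idx]
    return s.event - H


def pvalue_adjusted(M: float, n_candidates: int, cfg: MaxstatConfig) -> float:
    """Selection-adjusted p-value for the maximally selected statistic.

    ``lau92`` uses the improved Bonferroni approximation

        p ~= 4 phi(b)/b + phi(b) (b - 1/b) log[ t2(1-t1) / ((1-t2) t1) ]

    with (t1, t2) the quantile window. The formula is asymptotic and
    non-monotone for small b (where it is vacuous); what is returned is its
    monotone non-increasing envelope, floored at the single-split two-sided
    normal p-value 2*Phi(-M) (the selection penalty can only make a split
    look less significant) and clipped to [0, 1]. In the significance range
    (b > ~1.5) the envelope coincides with the raw formula.
    ``none_bonferroni`` returns min(1, n_candidates * 2*Phi(-M)).
    """
    if M < 0:
        raise DataValidationError("statistic must be non-negative")
    if M == 0:
        return 1.0
    single = 2.0 * stats.norm.sf(M)
    if cfg.pmethod == "none_bonferroni":
        return float(min(1.0, n_candidates * single))
    own = _lau92_raw(M, cfg.minprop, cfg.maxprop)
    grid, vals = _lau92_grid(cfg.minprop, cfg.maxprop)
    right = vals[np.searchsorted(grid, M):]
    envelope = max(own, right.max()) if right.size else own
    return float(np.clip(max(envelope, single), 0.0, 1.0))


def _lau92_raw(b: float, t1: float, t2: float) -> float:
    db = stats.norm.pdf(b)
    return float(
        4.0 * db / b + db * (b - 1.0 / b) * np.log((t2 * (1 - t1)) / ((1 - t2) * t1))
    )


@lru_cache(maxsize=8)
def _lau92_grid(t1: float, t2: float):
    """Fixed evaluation grid so the returned envelope nests monotonically."""
    grid = np.linspace(1e-3, 8.0, 4001)
    db = stats.norm.pdf(grid)
    vals = np.maximum(
        4.0 * db / grid + db * (grid - 1.0 / grid) * np.log((t2 * (1 - t1)) / ((1 - t2) * t1)),
        2.0 * stats.norm.sf(grid),
    )
    return grid, vals


def maxstat_test(
    x, s: SurvivalData, cfg: MaxstatConfig | None = None, scores: np.ndarray | None = None
) -> MaxstatResult:
    """Find the covariate cutpoint maximizing the standardized rank statistic.

    For each distinct covariate value mu with an admissible low-group
    fraction, the statistic of the low group is standardized under the
    permutation null:

        S = sum of scores with x <= mu,  E = m * mean(a),
        V = m (N-m) / (N (N-1)) * sum (a_i - mean(a))^2,
        Z = (S - E) / sqrt(V).

    M = max |Z|; ties are broken toward the smallest cutpoint. ``direction``
    is ``low_is_adverse`` when the low group carries the excess of events
    (Z > 0 at the maximum), else ``high_is_adverse``.

    ``scores`` may carry precomputed log-rank scores for ``s`` (they depend
    only on the outcome, so a gene screen computes them once).
    """
    if cfg is None:
        cfg = MaxstatConfig()
    x = np.asarray(x, dtype=float)
    if x.shape != (len(s),):
        raise DataValidationError("covariate length must match survival data")
    if not np.all(np.isfinite(x)):
        raise DataValidationError("covariate must be finite")

    a = logrank_scores(s) if scores is None else np.asarray(scores, dtype=float)
    N = len(s)
    abar = a.mean()
    ssq = float(((a - abar) ** 2).sum())
    if ssq == 0.0:
        raise DegenerateCovariateError("all rank scores identical (no events)")

    order = np.argsort(x, kind="stable")
    xs = x[order]
    csum = np.cumsum(a[order])
    # candidate cutpoints: last occurrence of each distinct value, excluding the max
    last = np.nonzero(np.diff(xs) > 0)[0]  # index i -> cutpoint xs[i], m = i + 1
    if last.size == 0:
        raise DegenerateCovariateError("degenerate covariate: constant values")
    m = last + 1
    frac = m / N
    admissible = (frac >= cfg.minprop) & (frac <= cfg.maxprop)
    if not admissible.any():
        raise DegenerateCovariateError(
            "degenerate covariate: no cutpoint within the admissible quantile window"
        )
    last = last[admissible]
    m = m[admissible]
    S = csum[last]
    E = m * abar
    V = m * (N - m) / (N * (N - 1.0)) * ssq
    Z = (S - E) / np.sqrt(V)
    best = int(np.argmax(np.abs(Z)))  # first max -> smallest cutpoint
    M = float(abs(Z[best]))
    return MaxstatResult(
        cutpoint=float(xs[last[best]]),
        statistic=M,
        p_adjusted=pvalue_adjusted(M, int(m.size), cfg),
        n_candidates=int(m.size),
        direction=LOW_IS_ADVERSE if Z[best] > 0 else HIGH_IS_ADVERSE,
        z_at_cutpoint=float(Z[best]),
    )
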