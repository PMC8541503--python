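"""Kaplan-Meier plotting for stratification results."""

from __future__ import annotations

import numpy as np

from .stratify import StratificationResult
from .survival import KMCurve


def _steps(km: KMCurve):
    # step function starting at (0, 1)
    t = np.concatenate(([0.0], km.event_times))
    s = np.concatenate(([1.0], km.survival))
    return t, s


def plot_km(strat: StratificationResult, ax=None):
    """Plot the high/low risk-group survival curves; returns the Axes."""
    import matplotlib

    if ax is None:
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        _, ax = plt.subplots(figsize=(5, 4))
    for label, km, color in (
        ("high risk", strat.km_high, "#c0392b"),
        ("low risk", strat.km_low, "#2471a3"),
    ):
        if km is None:
            continue
        t, s = _steps(km)
        ax.step(t, s, where="post", label=label, color=color)
    if strat.logrank is not None:
        ax.set_title(f"log-rank p = {strat.logrank.p_value:.2e}")
    ax.set_xlabel("time (days)")
    ax.set_ylabel("overall survival")
    ax.set_ylim(0, 1.02)
    ax.legend(loc="lower left", frameon=False)
    return ax
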