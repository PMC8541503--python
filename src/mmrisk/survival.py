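"""Survival primitives: Kaplan-Meier, log-rank, Cox PH, BH adjustment.

These are the building blocks for the cutpoint screen and all downstream
survival analyses. The Cox model is fit by Newton-Raphson maximization of
the partial likelihood with Breslow (default) or Efron handling of tied
event times; the score test at beta = 0 for a binary covariate reproduces
the two-group log-rank statistic on untied data, which serves as an internal
consistency check between the two code paths.

Conventions: times are positive (days); event = 1 means death observed,
0 means right-censored; when an event and a censoring share a time the event
is counted first (the censored subject remains in the risk set at that time).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import DataValidationError

__all__ = [
    "SurvivalData",
    "KMCurve",
    "CoxFit",
    "TestResult",
    "read_survival",
    "write_survival",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "cox_score_test",
    "bh_adjust",
]


@dataclass
class SurvivalData:
    """Right-censored follow-up: per-sample time (days) and event flag."""

    sample_ids: list
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self):
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DataValidationError("duplicate sample ids in survival data")
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event)
        if self.time.shape != (len(self.sample_ids),) or self.event.shape != self.time.shape:
            raise DataValidationError("sample ids, time and event lengths differ")
        if not np.all(np.isfinite(self.time)) or np.any(self.time <= 0):
            raise DataValidationError("survival times must be positive and finite")
        if not np.isin(self.event, (0, 1)).all():
            raise DataValidationError("event flags must be 0 or 1")
        self.event = self.event.astype(int)

    def __len__(self) -> int:
        return len(self.sample_ids)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "SurvivalData":
        required = {"sample_id", "os_time", "os_event"}
        if not required.issubset(df.columns):
            raise DataValidationError(
                f"survival table needs columns {sorted(required)}, got {list(df.columns)}"
            )
        return cls(list(df["sample_id"]), df["os_time"].to_numpy(), df["os_event"].to_numpy())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_ids, "os_time": self.time, "os_event": self.event}
        )

    def reorder(self, sample_ids) -> "SurvivalData":
        """Return a copy aligned to ``sample_ids`` (must be a subset)."""
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in idx]
        if missing:
            raise DataValidationError(
                f"samples missing from survival data: {', '.join(map(str, missing[:5]))}"
            )
        rows = [idx[s] for s in sample_ids]
        return SurvivalData(list(sample_ids), self.time[rows], self.event[rows])


def read_survival(path) -> SurvivalData:
    return SurvivalData.from_dataframe(pd.read_csv(path, sep="\t"))


def write_survival(s: SurvivalData, path) -> None:
    s.to_dataframe().to_csv(path, sep="\t", index=False)


@dataclass
class KMCurve:
    """Product-limit estimate evaluated at the distinct event times."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "survival": self.survival,
                "at_risk": self.at_risk,
                "n_events": self.n_events,
            }
        )

    def survival_at(self, t: float) -> float:
        """Step-function value S(t); S = 1 before the first event time."""
        i = np.searchsorted(self.event_times, t, side="right")
        return 1.0 if i == 0 else float(self.survival[i - 1])


def _event_table(time: np.ndarray, event: np.ndarray):
    """Distinct event times with event counts and risk-set sizes."""
    t = np.sort(time)
    times, d = np.unique(time[event == 1], return_counts=True)
    # at risk at u = number with time >= u (censoring at u stays at risk)
    at_risk = len(t) - np.searchsorted(t, times, side="left")
    return times, d, at_risk


def km_estimate(s: SurvivalData) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    Steps occur only at times with at least one observed event; with no
    events the curve is identically 1.
    """
    if len(s) == 0:
        raise DataValidationError("empty survival data")
    times, d, n = _event_table(s.time, s.event)
    surv = np.cumprod(1.0 - d / n)
    return KMCurve(times, surv, n, d)


@dataclass
class TestResult:
    """A test statistic with its p-value and bookkeeping fields."""

    statistic: float
    p_value: float
    df: int | None = None
    n: int | None = None
    estimate: float | None = None
    note: str = ""

    def __post_init__(self):
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise DataValidationError("p-value outside [0, 1]")


def logrank_test(s: SurvivalData, group) -> TestResult:
    """Two-group log-rank test (1 df chi-square).

    ``group`` is a binary label per sample; at each distinct event time the
    observed events in group 1 are compared with their hypergeometric
    expectation given the risk sets, and (O - E)^2 / V is referred to
    chi-square(1).
    """
    group = np.asarray(group)
    if group.shape != s.time.shape:
        raise DataValidationError("group labels must match survival data length")
    if not np.isin(group, (0, 1)).all():
        raise DataValidationError("group labels must be binary 0/1")
    g = group.astype(bool)
    if g.all() or not g.any():
        raise DataValidationError("both groups must be non-empty")
    if s.n_events == 0:
        return TestResult(np.nan, 1.0, df=1, n=len(s), note="no events: statistic undefined")

    times, d, n_risk = _event_table(s.time, s.event)
    t1 = np.sort(s.time[g])
    n1_risk = len(t1) - np.searchsorted(t1, times, side="left")
    ev1_times = s.time[g & (s.event == 1)]
    d1 = np.zeros(len(times))
    if len(ev1_times):
        u, c = np.unique(ev1_times, return_counts=True)
        d1[np.searchsorted(times, u)] = c
    obs = float(d1.sum())
    exp = float((d * n1_risk / n_risk).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        vterms = d * (n1_risk / n_risk) * (1 - n1_risk / n_risk) * (n_risk - d) / (n_risk - 1)
    var = float(np.where(n_risk > 1, vterms, 0.0).sum())
    if var == 0:
        return TestResult(np.nan, 1.0, df=1, n=len(s), note="zero variance")
    stat = (obs - exp) ** 2 / var
    return TestResult(float(stat), float(stats.chi2.sf(stat, 1)), df=1, n=len(s))


@dataclass
class CoxFit:
    """Cox proportional-hazards fit: log hazard ratios with Wald inference."""

    covariate_names: list
    beta: np.ndarray
    se: np.ndarray
    loglik: float
    converged: bool
    n: int
    n_events: int
    ties: str
    note: str = ""
    loglik_null: float = field(default=np.nan)

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.beta)

    @property
    def wald_p(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            z2 = (self.beta / self.se) ** 2
        return stats.chi2.sf(z2, 1)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "covariate": self.covariate_names,
                "beta": self.beta,
                "hr": self.hr,
                "se": self.se,
                "p": self.wald_p,
            }
        )


def _prepare_cox(x, s: SurvivalData):
    X = np.asarray(x, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != len(s):
        raise DataValidationError("covariate rows must match survival data length")
    if not np.all(np.isfinite(X)):
        raise DataValidationError("covariates must be finite")
    const = np.ptp(X, axis=0) == 0
    if const.any():
        raise DataValidationError(f"constant covariate at column(s) {np.where(const)[0].tolist()}")
    if X.shape[0] <= X.shape[1]:
        raise DataValidationError("need more subjects than covariates")
    order = np.argsort(s.time, kind="stable")
    return X[order], s.time[order], s.event[order].astype(bool)


def _cox_loglik(beta, X, t, e, ties):
    """Partial log-likelihood with gradient and observed information.

    ``t`` ascending. Risk-set sums are suffix cumulative sums evaluated at
    the unique event times (fully vectorized); Efron corrections replace the
    Breslow terms only at times with tied events.
    """
    n, p = X.shape
    eta = X @ beta
    eta = eta - eta.max()  # guard exp overflow; the shift cancels exactly
    w = np.exp(eta)
    wX = w[:, None] * X
    wXXf = wX[:, :, None] * X[:, None, :]

    S0r = np.cumsum(w[::-1])[::-1]
    S1r = np.cumsum(wX[::-1], axis=0)[::-1]
    S2r = np.cumsum(wXXf[::-1], axis=0)[::-1]

    ev_times, first = np.unique(t[e], return_index=True)
    # d events per unique event time; risk set starts at the first subject
    # with time >= u (ties: events and censorings at u are all at risk)
    d = np.diff(np.concatenate([first, [int(e.sum())]]))
    risk_start = np.searchsorted(t, ev_times, side="left")
    S0 = S0r[risk_start]
    S1 = S1r[risk_start]
    S2 = S2r[risk_start]

    ll = float(eta[e].sum())
    U = X[e].sum(axis=0)
    if ties == "breslow":
        ll -= float(d @ np.log(S0))
        U -= (d[:, None] * S1 / S0[:, None]).sum(axis=0)
        Info = (
            d[:, None, None] * (S2 / S0[:, None, None]
                                - S1[:, :, None] * S1[:, None, :] / S0[:, None, None] ** 2)
        ).sum(axis=0)
    else:  # efron
        Info = np.zeros((p, p))
        te = t[e]
        Xe = X[e]
        we = w[e]
        wXe = wX[e]
        wXXe = wXXf[e]
        for k, u in enumerate(ev_times):
            dk = d[k]
            if dk == 1:
                R0, R1, R2 = S0[k], S1[k], S2[k]
                ll -= np.log(R0)
                U -= R1 / R0
                Info += R2 / R0 - np.outer(R1, R1) / R0**2
            else:
                sel = slice(first[k], first[k] + dk)
                D0 = we[sel].sum()
                D1 = wXe[sel].sum(axis=0)
                D2 = wXXe[sel].sum(axis=0)
                for l in range(dk):
                    f = l / dk
                    R0 = S0[k] - f * D0
                    R1 = S1[k] - f * D1
                    R2 = S2[k] - f * D2
                    ll -= np.log(R0)
                    U -= R1 / R0
                    Info += R2 / R0 - np.outer(R1, R1) / R0**2
    return ll, U, Info


def cox_fit(
    x,
    s: SurvivalData,
    ties: str = "breslow",
    covariate_names=None,
    max_iter: int = 50,
    tol: float = 1e-9,
) -> CoxFit:
    """Fit a Cox proportional-hazards model by Newton-Raphson.

    Convergence is declared when the score vector's max absolute entry falls
    below ``tol`` or the relative log-likelihood change does. A monotone
    likelihood (perfect separation) is reported via ``converged=False`` with
    a diagnostic note rather than an exception.
    """
    if ties not in ("breslow", "efron"):
        raise DataValidationError(f"unknown ties method {ties!r}")
    X, t, e = _prepare_cox(x, s)
    n, p = X.shape
    if covariate_names is None:
        covariate_names = [f"x{j}" for j in range(p)]
    if not e.any():
        raise DataValidationError("no events: Cox model undefined")

    beta = np.zeros(p)
    ll, U, Info = _cox_loglik(beta, X, t, e, ties)
    ll0 = ll
    converged = False
    note = ""
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(Info, U)
        except np.linalg.LinAlgError:
            note = "singular information matrix"
            break
        new_beta = beta + step
        new_ll, new_U, new_Info = _cox_loglik(new_beta, X, t, e, ties)
        # step-halving keeps the likelihood climbing
        halvings = 0
        while (not np.isfinite(new_ll) or new_ll < ll) and halvings < 20:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_U, new_Info = _cox_loglik(new_beta, X, t, e, ties)
            halvings += 1
        rel_change = abs(new_ll - ll) / max(abs(ll), 1.0)
        beta, ll, U, Info = new_beta, new_ll, new_U, new_Info
        if np.max(np.abs(U)) < tol or rel_change < tol:
            converged = True
            break
    if np.max(np.abs(beta)) > 15:
        converged = False
        note = "monotone likelihood (possible perfect separation): estimates diverge"
    elif not converged and not note:
        note = f"not converged in {max_iter} iterations"

    try:
        cov = np.linalg.inv(Info)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    return CoxFit(
        list(covariate_names), beta, se, float(ll), converged,
        n=n, n_events=int(e.sum()), ties=ties, note=note, loglik_null=float(ll0),
    )


def cox_score_test(x, s: SurvivalData, ties: str = "breslow") -> TestResult:
    """Cox partial-likelihood score test at beta = 0.

    For a single binary covariate with untied event times this equals the
    two-group log-rank chi-square statistic.
    """
    X, t, e = _prepare_cox(x, s)
    if not e.any():
        raise DataValidationError("no events: score test undefined")
    _, U, Info = _cox_loglik(np.zeros(X.shape[1]), X, t, e, ties)
    stat = float(U @ np.linalg.solve(Info, U))
    return TestResult(stat, float(stats.chi2.sf(stat, X.shape[1])), df=X.shape[1], n=X.shape[0])


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if not np.all(np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise DataValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
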