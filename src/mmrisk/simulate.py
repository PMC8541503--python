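"""Synthetic myeloma-like cohorts with planted prognostic genes.

The generator emulates the statistical structure the pipeline assumes:

* a latent log-normal expression level per gene and sample, observed through
  negative-binomial counts with per-sample library sizes (so normalization
  and cutpoint selection act on RNA-seq-like data);
* a minority of prognostic genes with *threshold* effects on the hazard —
  a patient's hazard is multiplied by ``exp(+/- effect_log_hr)`` according to
  whether the latent expression exceeds the planted cutpoint quantile,
  mirroring the dichotomized construction of the risk score (a linear-effect
  mode is available for robustness checks);
* a per-patient latent *risk axis* on which all prognostic genes load
  (adverse genes positively, protective genes negatively), reproducing the
  co-expression structure of real prognostic signatures, whose genes tag a
  shared biology rather than thirty independent mechanisms;
* an exponential (or Weibull) baseline with uniform-entry administrative
  censoring calibrated to a target censoring fraction;
* optional binary annotations enriched in the true high-risk group and drug
  responses rank-correlated with the score.

Ground truth (planted genes, directions, cutpoints, per-sample linear
predictor and risk group) is returned for recovery tests.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DataValidationError
from .expression import RAW_COUNTS, ExpressionMatrix
from .signature import RiskScores
from .survival import SurvivalData

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_cohort",
    "simulate_validation_cohort",
    "simulate_annotations",
    "simulate_drug_response",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults: 300 patients, 1000 genes of which 30 are prognostic split
    20 adverse / 10 protective (echoing the 2:1 poor/good partition of real
    signatures), per-gene effect of 0.9 on the log hazard at the median
    latent cutpoint, exponential baseline with 2190-day median survival, and
    a 0.35 censoring fraction.
    """

    n_samples: int = 300
    n_genes: int = 1000
    n_prognostic: int = 30
    effect_log_hr: float = 0.9
    planted_cutpoint_quantile: float = 0.5
    baseline_hazard: float = math.log(2) / 2190.0  # per day; median OS ~6 years
    weibull_shape: float = 1.0
    censoring_fraction: float = 0.35
    axis_loading: float = 0.6  # correlation of planted latent expression with the risk axis
    latent_sd: float = 1.0
    dispersion: float = 0.15
    libsize_sigma: float = 0.25
    base_logmean_range: tuple = (math.log(5.0), math.log(500.0))
    prognostic_logmean_range: tuple = (math.log(30.0), math.log(300.0))
    linear_effects: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_prognostic > self.n_genes:
            raise DataValidationError("n_prognostic cannot exceed n_genes")
        if not np.isfinite(self.effect_log_hr):
            raise DataValidationError("effect size must be finite")
        if not (0.0 <= self.censoring_fraction < 1.0):
            raise DataValidationError("infeasible censoring target (need 0 <= f < 1)")
        if not (0.0 < self.planted_cutpoint_quantile < 1.0):
            raise DataValidationError("planted cutpoint quantile must lie in (0, 1)")
        if not (0.0 <= self.axis_loading < 1.0):
            raise DataValidationError("axis_loading must lie in [0, 1)")

    @property
    def n_poor(self) -> int:
        """Adverse genes (high expression raises the hazard); 2:1 split."""
        return int(round(self.n_prognostic * 2 / 3))

    @property
    def n_good(self) -> int:
        return self.n_prognostic - self.n_poor


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated cohort, sufficient to regenerate new
    samples from the same generative law."""

    config: SimulationConfig
    gene_ids: list
    gene_logmeans: np.ndarray
    prognostic_idx: np.ndarray
    effect_sign: np.ndarray  # +1 adverse-when-high, -1 protective-when-high
    latent_cutpoints: np.ndarray  # per prognostic gene, latent scale
    sample_ids: list = field(default_factory=list)
    eta: np.ndarray = None  # per-sample linear predictor (centered)
    risk_axis: np.ndarray = None  # latent factor all planted genes load on
    true_high_risk: np.ndarray = None

    @property
    def prognostic_gene_ids(self) -> list:
        return [self.gene_ids[i] for i in self.prognostic_idx]

    @property
    def directions(self) -> list:
        """Screening-convention direction label per prognostic gene."""
        return ["poor_when_high" if s > 0 else "poor_when_low" for s in self.effect_sign]

    def to_json(self) -> str:
        return json.dumps(
            {
                "prognostic_genes": [
                    {
                        "gene_id": g,
                        "direction": d,
                        "effect_log_hr": float(self.config.effect_log_hr * s),
                        "cutpoint_quantile": self.config.planted_cutpoint_quantile,
                        "latent_cutpoint": float(c),
                    }
                    for g, d, s, c in zip(
                        self.prognostic_gene_ids, self.directions,
                        self.effect_sign, self.latent_cutpoints,
                    )
                ],
                "samples": [
                    {"sample_id": sid, "eta": float(e), "true_high_risk": bool(h)}
                    for sid, e, h in zip(self.sample_ids, self.eta, self.true_high_risk)
                ],
                "seed": self.config.seed,
            },
            indent=2,
        )


def _calibrate_admin_time(t_event: np.ndarray, target: float) -> float:
    """Administrative horizon tau such that uniform entry over [0, tau]
    yields the target expected censoring fraction."""
    if target == 0.0:
        return math.inf

    def frac(tau):
        return float(np.mean(np.minimum(t_event / tau, 1.0)))

    lo, hi = 1e-6, float(np.max(t_event)) * 2 + 1.0
    while frac(hi) > target:
        hi *= 2.0
        if hi > 1e12:
            raise DataValidationError("infeasible censoring target")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if frac(mid) > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _draw_latent(rng, cfg: SimulationConfig, truth: "SyntheticTruth", u: np.ndarray):
    """Latent log-expression; planted genes load on the risk axis u with
    correlation ``axis_loading`` (signed by direction), marginal sd unchanged."""
    logmeans = truth.gene_logmeans
    eps = rng.normal(size=(len(logmeans), len(u)))
    z = logmeans[:, None] + cfg.latent_sd * eps
    rho = cfg.axis_loading
    if truth.prognostic_idx.size and rho > 0:
        pidx = truth.prognostic_idx
        load = rho * truth.effect_sign[:, None] * u[None, :]
        z[pidx] = logmeans[pidx][:, None] + cfg.latent_sd * (
            load + math.sqrt(1.0 - rho**2) * eps[pidx]
        )
    return z


def _counts_from_latent(rng, z, libsizes, dispersion):
    mu = libsizes[None, :] * np.exp(z)
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mu)).astype(float)


def _survival_from_eta(rng, cfg: SimulationConfig, eta: np.ndarray, sample_ids):
    n = len(eta)
    u = rng.uniform(size=n)
    # inverse Weibull hazard transform; shape 1 = exponential
    t_event = (-np.log(u) / (cfg.baseline_hazard * np.exp(eta))) ** (1.0 / cfg.weibull_shape)
    tau = _calibrate_admin_time(t_event, cfg.censoring_fraction)
    if math.isinf(tau):
        time, event = t_event, np.ones(n, dtype=int)
    else:
        c = tau * rng.uniform(size=n)
        time = np.minimum(t_event, c)
        event = (t_event <= c).astype(int)
    time = np.maximum(time, 1e-3)  # survival times must stay positive
    return SurvivalData(sample_ids, time, event)


def _eta_from_latent(cfg: SimulationConfig, truth: SyntheticTruth, z: np.ndarray) -> np.ndarray:
    q = cfg.planted_cutpoint_quantile
    eta = np.zeros(z.shape[1])
    for k, i in enumerate(truth.prognostic_idx):
        beta = truth.effect_sign[k] * cfg.effect_log_hr
        if cfg.linear_effects:
            eta += beta * (z[i] - truth.gene_logmeans[i]) / cfg.latent_sd * 0.5
        else:
            ind = (z[i] > truth.latent_cutpoints[k]).astype(float)
            eta += beta * (ind - (1.0 - q))  # centered: E[1(z>c)] = 1-q
    return eta


def simulate_cohort(cfg: SimulationConfig):
    """Draw a training cohort.

    Returns ``(ExpressionMatrix[raw_counts], SurvivalData, SyntheticTruth)``;
    the same seed reproduces the outputs exactly.
    """
    rng = np.random.default_rng(cfg.seed)
    gene_ids = [f"G{i + 1:04d}" for i in range(cfg.n_genes)]
    sample_ids = [f"S{j + 1:04d}" for j in range(cfg.n_samples)]

    logmeans = rng.uniform(*cfg.base_logmean_range, size=cfg.n_genes)
    prognostic_idx = np.sort(rng.choice(cfg.n_genes, size=cfg.n_prognostic, replace=False))
    logmeans[prognostic_idx] = rng.uniform(
        *cfg.prognostic_logmean_range, size=cfg.n_prognostic
    )
    effect_sign = np.concatenate(
        [np.ones(cfg.n_poor), -np.ones(cfg.n_good)]
    )
    cuts = logmeans[prognostic_idx] + cfg.latent_sd * stats.norm.ppf(
        cfg.planted_cutpoint_quantile
    )
    truth = SyntheticTruth(
        config=cfg,
        gene_ids=gene_ids,
        gene_logmeans=logmeans,
        prognostic_idx=prognostic_idx,
        effect_sign=effect_sign,
        latent_cutpoints=cuts,
    )

    u = rng.normal(size=cfg.n_samples)
    libsizes = np.exp(rng.normal(0.0, cfg.libsize_sigma, size=cfg.n_samples))
    z = _draw_latent(rng, cfg, truth, u)
    counts = _counts_from_latent(rng, z, libsizes, cfg.dispersion)
    eta = _eta_from_latent(cfg, truth, z)
    surv = _survival_from_eta(rng, cfg, eta, sample_ids)

    truth.sample_ids = sample_ids
    truth.eta = eta
    truth.risk_axis = u
    truth.true_high_risk = u > 0

    expr = ExpressionMatrix(gene_ids, sample_ids, counts, RAW_COUNTS)
    return expr, surv, truth


def simulate_validation_cohort(
    cfg: SimulationConfig,
    truth: SyntheticTruth,
    shift: float = 0.0,
    n_samples: int | None = None,
    seed: int | None = None,
):
    """Draw an independent cohort from the same generative law.

    ``shift`` perturbs the mean log library size (sequencing-depth shift
    between cohorts); planted genes, cutpoints and effects are preserved.
    """
    if seed is None:
        seed = (cfg.seed + 1) % (2**31)
    if n_samples is None:
        n_samples = cfg.n_samples
    rng = np.random.default_rng(seed)
    sample_ids = [f"V{j + 1:04d}" for j in range(n_samples)]

    u = rng.normal(size=n_samples)
    libsizes = np.exp(rng.normal(shift, cfg.libsize_sigma, size=n_samples))
    z = _draw_latent(rng, cfg, truth, u)
    counts = _counts_from_latent(rng, z, libsizes, cfg.dispersion)
    eta = _eta_from_latent(cfg, truth, z)
    surv = _survival_from_eta(rng, cfg, eta, sample_ids)
    expr = ExpressionMatrix(truth.gene_ids, sample_ids, counts, RAW_COUNTS)
    return expr, surv


def simulate_annotations(
    truth: SyntheticTruth,
    n_null: int = 10,
    n_linked: int = 5,
    link_odds: float = 4.0,
    baseline_prev: float = 0.15,
    seed: int | None = None,
) -> pd.DataFrame:
    """Binary annotations; linked ones have their carrier odds multiplied by
    ``link_odds`` in the true high-risk group."""
    if seed is None:
        seed = (truth.config.seed + 2) % (2**31)
    rng = np.random.default_rng(seed)
    odds0 = baseline_prev / (1.0 - baseline_prev)
    p_linked_high = (link_odds * odds0) / (1.0 + link_odds * odds0)
    high = np.asarray(truth.true_high_risk)

    cols = {}
    for k in range(n_linked):
        p = np.where(high, p_linked_high, baseline_prev)
        cols[f"linked_{k + 1}"] = (rng.uniform(size=len(high)) < p).astype(int)
    for k in range(n_null):
        cols[f"null_{k + 1}"] = (rng.uniform(size=len(high)) < baseline_prev).astype(int)
    return pd.DataFrame(cols, index=pd.Index(truth.sample_ids, name="sample_id"))


def simulate_drug_response(
    scores: RiskScores,
    rho_target: float,
    seed: int = 0,
    drug_name: str = "drug_1",
) -> pd.DataFrame:
    """Drug responses whose expected Spearman correlation with the score is
    ``rho_target``.

    Log-response is a linear function of the standardized score plus Gaussian
    noise; the slope is set from the Pearson-Spearman relation for bivariate
    normals, ``rho_p = 2 sin(pi rho_s / 6)``.
    """
    if not (-1.0 <= rho_target <= 1.0):
        raise DataValidationError("rho_target must lie in [-1, 1]")
    rho_s = float(np.clip(rho_target, -0.99, 0.99))
    rho_p = 2.0 * math.sin(math.pi * rho_s / 6.0)
    slope = rho_p / math.sqrt(1.0 - rho_p**2)

    rng = np.random.default_rng(seed)
    x = np.asarray(scores.score, dtype=float)
    sd = x.std()
    xstd = (x - x.mean()) / (sd if sd > 0 else 1.0)
    y = slope * xstd + rng.normal(size=len(x))
    return pd.DataFrame(
        {"line_id": scores.sample_ids, "drug": drug_name, "response": np.exp(y)}
    )
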