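"""Gene screening and the signed-sum-of-Cox-betas risk score.

Every gene is screened with the maximally selected rank statistic; genes
surviving a Benjamini-Hochberg cut (adjusted p < alpha across the screened
family) form the signature. Each selected gene carries its expression
cutpoint and the Cox log hazard ratio (beta) of the dichotomized
above-cutpoint indicator. A patient's risk score is

    score = sum_i  w_i * beta_i,   w_i = +1 if expression_i > cutpoint_i else -1,

so genes whose high expression is adverse (beta > 0) push the score up when
high, and protective genes (beta < 0) push it down; higher score = higher
risk by construction.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DataValidationError, DegenerateCovariateError, MMRiskError
from .expression import RAW_COUNTS, ExpressionMatrix
from .maxstat import MaxstatConfig, maxstat_test
from .survival import SurvivalData, bh_adjust, cox_fit

__all__ = [
    "GeneScreenResult",
    "GeneScreen",
    "SignatureModel",
    "RiskScores",
    "screen_genes",
    "build_signature",
    "compute_risk_score",
]

POOR_WHEN_HIGH = "poor_when_high"
POOR_WHEN_LOW = "poor_when_low"


@dataclass
class GeneScreenResult:
    """Per-gene screening outcome: cutpoint, maxstat p, dichotomized Cox beta."""

    gene_id: str
    cutpoint: float
    maxstat_statistic: float
    p_raw: float
    beta: float
    direction: str
    p_adj: float = np.nan
    cox_converged: bool = True


@dataclass
class GeneScreen:
    """Screening of one gene family: results plus skipped genes with reasons."""

    results: list
    skipped: dict = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(r) for r in self.results])


def screen_genes(
    m: ExpressionMatrix, s: SurvivalData, cfg: MaxstatConfig | None = None
) -> GeneScreen:
    """Screen every gene for a prognostic expression cutpoint.

    Per gene: maxstat gives the cutpoint and a selection-adjusted p; BH across
    all successfully tested genes gives ``p_adj``; a univariate Cox fit of the
    above-cutpoint indicator gives ``beta``. Genes whose covariate is
    degenerate (constant, or constant within the admissible window) are
    recorded in ``skipped`` and excluded from the BH family.

    Expression must be normalized (the model is trained and applied in one
    expression space; the default pipeline uses log2(normalized + 1)).
    """
    if cfg is None:
        cfg = MaxstatConfig()
    if m.space == RAW_COUNTS:
        raise DataValidationError("screen_genes expects normalized expression, not raw counts")
    if set(m.sample_ids) != set(s.sample_ids):
        raise DataValidationError("expression and survival cover different samples")
    s = s.reorder(m.sample_ids)

    from .maxstat import logrank_scores

    scores = logrank_scores(s)
    results: list[GeneScreenResult] = []
    skipped: dict[str, str] = {}
    for i, gene in enumerate(m.gene_ids):
        x = m.values[i]
        try:
            ms = maxstat_test(x, s, cfg, scores=scores)
        except DegenerateCovariateError as err:
            skipped[gene] = str(err)
            continue
        indicator = (x > ms.cutpoint).astype(float)
        fit = cox_fit(indicator, s, covariate_names=[gene])
        beta = float(fit.beta[0])
        results.append(
            GeneScreenResult(
                gene_id=gene,
                cutpoint=float(ms.cutpoint),
                maxstat_statistic=ms.statistic,
                p_raw=ms.p_adjusted,
                beta=beta,
                direction=POOR_WHEN_HIGH if beta > 0 else POOR_WHEN_LOW,
                cox_converged=fit.converged,
            )
        )
    if results:
        adj = bh_adjust([r.p_raw for r in results])
        for r, q in zip(results, adj):
            r.p_adj = float(q)
    return GeneScreen(results, skipped)


@dataclass
class SignatureGene:
    """A selected gene as carried by the trained signature."""

    gene_id: str
    cutpoint: float
    beta: float
    direction: str
    p_adj: float


@dataclass
class SignatureModel:
    """The trained risk signature: selected genes, betas, and score cutoff."""

    genes: list
    alpha: float = 0.05
    score_cutoff: float | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def gene_ids(self) -> list:
        return [g.gene_id for g in self.genes]

    @property
    def n_poor(self) -> int:
        """Genes whose high expression is adverse (beta > 0)."""
        return sum(g.direction == POOR_WHEN_HIGH for g in self.genes)

    @property
    def n_good(self) -> int:
        """Genes whose high expression is protective (beta < 0)."""
        return sum(g.direction == POOR_WHEN_LOW for g in self.genes)

    @property
    def max_score(self) -> float:
        return float(sum(abs(g.beta) for g in self.genes))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(g) for g in self.genes])

    def to_json(self) -> str:
        payload = {
            "alpha": self.alpha,
            "genes": [
                {
                    "gene_id": g.gene_id,
                    "cutpoint": g.cutpoint,
                    "beta": g.beta,
                    "direction": g.direction,
                    "p_adj": g.p_adj,
                }
                for g in self.genes
            ],
            "score_cutoff": self.score_cutoff,
            "metadata": self.metadata,
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SignatureModel":
        payload = json.loads(text)
        genes = [SignatureGene(**g) for g in payload["genes"]]
        return cls(
            genes=genes,
            alpha=payload["alpha"],
            score_cutoff=payload["score_cutoff"],
            metadata=payload.get("metadata", {}),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "SignatureModel":
        with open(path) as fh:
            return cls.from_json(fh.read())


def build_signature(
    screen: GeneScreen, alpha: float = 0.05, metadata: dict | None = None
) -> SignatureModel:
    """Retain genes with BH-adjusted p < alpha as the signature."""
    selected = [r for r in screen.results if np.isfinite(r.p_adj) and r.p_adj < alpha]
    if not selected:
        warnings.warn("no gene passed the selection threshold: empty signature", stacklevel=2)
    genes = [
        SignatureGene(r.gene_id, r.cutpoint, r.beta, r.direction, r.p_adj) for r in selected
    ]
    return SignatureModel(genes=genes, alpha=alpha, metadata=metadata or {})


@dataclass
class RiskScores:
    """Per-patient risk score values."""

    sample_ids: list
    score: np.ndarray

    def __post_init__(self):
        self.score = np.asarray(self.score, dtype=float)
        if self.score.shape != (len(self.sample_ids),):
            raise DataValidationError("one score per sample required")

    def __len__(self) -> int:
        return len(self.sample_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"sample_id": self.sample_ids, "score": self.score})


def compute_risk_score(
    model: SignatureModel, m: ExpressionMatrix, max_missing_frac: float = 0.1
) -> RiskScores:
    """Score each sample: signed sum of betas across the signature genes.

    Expression must be in the space the model was trained in (recorded in
    ``model.metadata["space"]`` when trained through the pipeline). Model
    genes absent from the matrix contribute 0, up to ``max_missing_frac`` of
    the signature; beyond that the cohorts are deemed incomparable.
    """
    if not model.genes:
        raise MMRiskError("signature is empty: no genes to score")
    trained_space = model.metadata.get("space")
    if trained_space is not None and trained_space != m.space:
        raise DataValidationError(
            f"expression space {m.space!r} differs from training space {trained_space!r}"
        )
    idx = {g: i for i, g in enumerate(m.gene_ids)}
    missing = [g.gene_id for g in model.genes if g.gene_id not in idx]
    if len(missing) > max_missing_frac * len(model.genes):
        raise DataValidationError(
            f"{len(missing)}/{len(model.genes)} signature genes absent from the matrix "
            f"(tolerated fraction {max_missing_frac})"
        )
    if missing:
        warnings.warn(
            f"{len(missing)} signature gene(s) absent; they contribute 0 to the score",
            stacklevel=2,
        )
    score = np.zeros(m.n_samples)
    for g in model.genes:
        if g.gene_id in idx:
            w = np.where(m.values[idx[g.gene_id]] > g.cutpoint, 1.0, -1.0)
            score += w * g.beta
    return RiskScores(list(m.sample_ids), score)
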