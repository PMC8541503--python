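"""Score-versus-covariate association analyses.

Three families of analyses link the risk score to external patient or
cell-line features: Wilcoxon rank-sum comparisons of score values across
binary annotations (cytogenetic abnormalities, somatic mutations),
rank correlations between score and drug response (IC50 or inhibition
ratio), and Cox models of survival on the score plus clinical covariates.

Annotation tables are wide 0/1 DataFrames indexed by sample id; drug
response tables are long DataFrames with columns line_id, drug, response.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DataValidationError
from .signature import RiskScores
from .survival import SurvivalData, TestResult, bh_adjust, cox_fit

__all__ = [
    "wilcoxon_rank_sum",
    "spearman",
    "pearson",
    "score_association_report",
    "cox_table",
    "read_annotations",
    "read_drug_response",
]


def read_annotations(path) -> pd.DataFrame:
    """Read a TSV of binary annotations (sample_id + one 0/1 column each)."""
    df = pd.read_csv(path, sep="\t").set_index("sample_id")
    values = df.to_numpy()
    if not np.isin(values, (0, 1)).all():
        raise DataValidationError("annotation values must be 0/1")
    return df


def read_drug_response(path) -> pd.DataFrame:
    """Read a long TSV of drug responses (line_id, drug, response > 0)."""
    df = pd.read_csv(path, sep="\t")
    required = {"line_id", "drug", "response"}
    if not required.issubset(df.columns):
        raise DataValidationError(f"drug table needs columns {sorted(required)}")
    if (df["response"] <= 0).any():
        raise DataValidationError("drug responses must be positive")
    return df


def wilcoxon_rank_sum(x, label) -> TestResult:
    """Two-sided Mann-Whitney / Wilcoxon rank-sum test.

    Exact enumeration when both groups have <= 12 observations and the data
    are untied; otherwise the tie-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    label = np.asarray(label)
    if x.shape != label.shape:
        raise DataValidationError("values and labels must have equal length")
    if not np.isin(label, (0, 1)).all():
        raise DataValidationError("labels must be binary 0/1")
    g = label.astype(bool)
    x1, x0 = x[g], x[~g]
    if len(x1) == 0 or len(x0) == 0:
        raise DataValidationError("both label groups must be non-empty")
    untied = len(np.unique(x)) == len(x)
    method = "exact" if (len(x1) <= 12 and len(x0) <= 12 and untied) else "asymptotic"
    res = stats.mannwhitneyu(
        x1, x0, alternative="two-sided", method=method, use_continuity=False
    )
    return TestResult(
        float(res.statistic), float(res.pvalue), n=len(x), note=method
    )


def spearman(x, y) -> TestResult:
    """Spearman rank correlation with two-sided t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataValidationError("x and y must be equal-length vectors")
    if len(x) < 4:
        raise DataValidationError("need at least 4 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DataValidationError("constant vector: correlation undefined")
    rho, p = stats.spearmanr(x, y)
    return TestResult(float(rho), float(p), n=len(x), estimate=float(rho))


def pearson(x, y) -> TestResult:
    """Pearson correlation (provided alongside Spearman for linear reporting)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataValidationError("x and y must be equal-length vectors")
    if len(x) < 4:
        raise DataValidationError("need at least 4 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DataValidationError("constant vector: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return TestResult(float(r), float(p), n=len(x), estimate=float(r))


def score_association_report(
    scores: RiskScores,
    annotations: pd.DataFrame,
    min_group_size: int = 5,
    bh: bool = True,
) -> pd.DataFrame:
    """Wilcoxon comparison of score values for each binary annotation.

    Annotations with fewer than ``min_group_size`` samples in either arm are
    reported as skipped with a reason. With ``bh=True`` a BH-adjusted p
    column is added across the tested annotations.
    """
    common = [sid for sid in scores.sample_ids if sid in annotations.index]
    if not common:
        warnings.warn("no overlap between scores and annotations", stacklevel=2)
        return pd.DataFrame()
    score_map = dict(zip(scores.sample_ids, scores.score))
    sc = np.array([score_map[sid] for sid in common])
    ann = annotations.loc[common]

    rows = []
    for name in ann.columns:
        lab = ann[name].to_numpy().astype(int)
        n1, n0 = int(lab.sum()), int(len(lab) - lab.sum())
        row = {"annotation": name, "n_with": n1, "n_without": n0}
        if min(n1, n0) < min_group_size:
            row.update(
                median_with=np.nan, median_without=np.nan, U=np.nan, p=np.nan,
                skipped=f"group smaller than {min_group_size}",
            )
        else:
            res = wilcoxon_rank_sum(sc, lab)
            row.update(
                median_with=float(np.median(sc[lab == 1])),
                median_without=float(np.median(sc[lab == 0])),
                U=res.statistic, p=res.p_value, skipped="",
            )
        rows.append(row)
    report = pd.DataFrame(rows)
    if report.empty or report["p"].notna().sum() == 0:
        warnings.warn("no annotation was testable", stacklevel=2)
        return report
    if bh:
        tested = report["p"].notna()
        adj = pd.Series(np.nan, index=report.index)
        adj[tested] = bh_adjust(report.loc[tested, "p"].to_numpy())
        report["p_adj"] = adj
    return report


def cox_table(
    scores: RiskScores,
    s: SurvivalData,
    covariates: pd.DataFrame | None = None,
    mode: str = "univariate",
    score_cutoff: float | None = None,
    score_as: str = "binary",
    ties: str = "breslow",
) -> pd.DataFrame:
    """Cox analyses of overall survival on the risk score plus covariates.

    The score enters as the binary high/low indicator at ``score_cutoff``
    by default (``score_as="continuous"`` uses the raw score). Univariate
    mode fits one model per variable; multivariate fits them jointly.
    Returns a table of HR, beta, se and Wald p per variable.
    """
    if mode not in ("univariate", "multivariate"):
        raise DataValidationError(f"unknown mode {mode!r}")
    if score_as not in ("binary", "continuous"):
        raise DataValidationError(f"unknown score_as {score_as!r}")
    s = s.reorder(scores.sample_ids)
    if score_as == "binary":
        if score_cutoff is None:
            raise DataValidationError("binary score mode requires score_cutoff")
        score_col = (scores.score > score_cutoff).astype(float)
        score_name = "risk_score_high"
    else:
        score_col = scores.score.astype(float)
        score_name = "risk_score"
    design = pd.DataFrame({score_name: score_col}, index=scores.sample_ids)
    if covariates is not None:
        cov = covariates.loc[scores.sample_ids].astype(float)
        design = pd.concat([design, cov], axis=1)

    rows = []
    if mode == "univariate":
        for name in design.columns:
            fit = cox_fit(design[name].to_numpy(), s, ties=ties, covariate_names=[name])
            rows.append(_cox_row(fit, 0, mode))
    else:
        fit = cox_fit(design.to_numpy(), s, ties=ties, covariate_names=list(design.columns))
        rows = [_cox_row(fit, j, mode) for j in range(len(design.columns))]
    return pd.DataFrame(rows)


def _cox_row(fit, j, mode):
    return {
        "variable": fit.covariate_names[j],
        "mode": mode,
        "beta": float(fit.beta[j]),
        "hr": float(fit.hr[j]),
        "se": float(fit.se[j]),
        "p": float(fit.wald_p[j]),
        "converged": bool(fit.converged),
    }
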