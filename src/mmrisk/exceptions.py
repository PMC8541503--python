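"""Exception hierarchy for mmrisk.

All package-specific errors derive from :class:`MMRiskError`, so callers
(and the command-line wrapper) can distinguish data problems from genuine
bugs with a single ``except`` clause.
"""


class MMRiskError(Exception):
    """Base class for all mmrisk errors."""


class DataValidationError(MMRiskError):
    """Input data violates a documented precondition (bad file, mismatched
    ids, values out of range, constant covariate, ...)."""


class DegenerateCovariateError(MMRiskError):
    """A covariate admits no valid cutpoint: constant within the admissible
    quantile window, or the outcome carries no events so all rank scores
    vanish."""


class ConvergenceError(MMRiskError):
    """An iterative fit failed to converge and no usable estimate exists."""
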