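"""Regression of classifier prediction probability on MMSE score.

For external test cohorts, the AD-class probability of each subject is
regressed on the subject's MMSE score by ordinary least squares, and the fit
is summarized by R-squared and the overall F-test (which, with a single
predictor, is equivalent to the two-sided t-test on the slope). Two preset
cohort filters mirror the screening analysis: all test cohorts, and the
community cohorts with the young group excluded to remove the age contrast.
Probabilities are used untransformed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .errors import ValidationError
from .mlharness import SubjectPrediction

__all__ = ["RegressionResult", "fit_probability_mmse", "probability_mmse_presets"]


@dataclass
class RegressionResult:
    n: int
    slope: float
    intercept: float
    r_squared: float
    f_statistic: float
    p_value: float
    cohorts_included: list[str]

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "f_statistic": self.f_statistic,
            "p_value": self.p_value,
            "cohorts_included": self.cohorts_included,
        }


def fit_probability_mmse(
    preds: list[SubjectPrediction], include: list[str] | None = None
) -> RegressionResult:
    """OLS of probability_ad on MMSE over the selected cohorts.

    ``include`` limits the fit to the named cohorts (default: all). Requires
    at least three subjects and non-constant MMSE.
    """
    if include is not None:
        include = list(include)
        preds = [p for p in preds if p.cohort in include]
    cohorts = sorted({p.cohort for p in preds})
    n = len(preds)
    if n < 3:
        raise ValidationError(f"need >= 3 predictions, got {n}")
    mmse = np.array([p.mmse for p in preds], dtype=float)
    prob = np.array([p.probability_ad for p in preds], dtype=float)
    if np.ptp(mmse) == 0:
        raise ValidationError("MMSE values are all identical; regression is degenerate")

    fit = sm.OLS(prob, sm.add_constant(mmse)).fit()
    p_value = float(fit.f_pvalue)
    if np.isnan(p_value) and fit.rsquared > 1 - 1e-12:
        p_value = 0.0  # exact fit: infinite F
    return RegressionResult(
        n=n,
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared),
        f_statistic=float(fit.fvalue),
        p_value=p_value,
        cohorts_included=cohorts,
    )


def probability_mmse_presets(
    preds: list[SubjectPrediction], young_label: str = "Young"
) -> dict[str, RegressionResult]:
    """The two standard regressions: all test cohorts, and community-only
    (young group excluded)."""
    cohorts = sorted({p.cohort for p in preds})
    community = [c for c in cohorts if c != young_label]
    return {
        "all_test": fit_probability_mmse(preds, include=cohorts),
        "community_only": fit_probability_mmse(preds, include=community),
    }
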