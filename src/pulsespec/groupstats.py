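"""Per-index two-group comparisons with two significance bands.

Each of the 40 spectral indices is compared between two groups with an
unpaired two-tailed test (Student's t by default; Welch's t and
Mann-Whitney U selectable) and assigned to one of the reporting bands
``p<0.05``, ``0.05<p<0.1`` or ``ns``. No multiple-testing correction is
applied by default, matching the per-index reporting style of the target
analysis; Bonferroni or Benjamini-Hochberg adjustment can be switched on.

Missing index values (e.g. CVs of degenerate spectra) are excluded pairwise
per index. An index with fewer than three values in either group, or with an
undefined test statistic, is marked ``untestable`` rather than failing the
pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .spectral import FEATURE_NAMES

__all__ = ["ComparisonResult", "compare_groups", "comparisons_to_frame"]

_METHODS = ("t", "welch", "mannwhitney")


@dataclass
class ComparisonResult:
    index_name: str
    group_a: str
    group_b: str
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    p_value: float
    band: str


def assign_band(p_value: float) -> str:
    """Map a p-value to the two-band reporting convention."""
    if np.isnan(p_value):
        return "untestable"
    if p_value < 0.05:
        return "p<0.05"
    if p_value < 0.1:
        return "0.05<p<0.1"
    return "ns"


def _test(a: np.ndarray, b: np.ndarray, method: str) -> float:
    # two identical constant samples: no variance, no difference -> p = 1
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        return 1.0
    if method == "t":
        return float(stats.ttest_ind(a, b, equal_var=True).pvalue)
    if method == "welch":
        return float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    if method == "mannwhitney":
        return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    raise ValidationError(f"unknown method {method!r}; choose from {_METHODS}")


def compare_groups(
    features: pd.DataFrame,
    group_a: str,
    group_b: str,
    method: str = "t",
    *,
    feature_names: list[str] | None = None,
    min_per_group: int = 3,
    correction: str | None = None,
) -> list[ComparisonResult]:
    """Compare every index between two groups of a feature table.

    ``features`` must carry a ``group`` column alongside the index columns
    (see :func:`pulsespec.spectral.attach_metadata`). ``correction`` may be
    ``"bonferroni"`` or ``"fdr_bh"``; bands are then assigned from adjusted
    p-values.
    """
    if method not in _METHODS:
        raise ValidationError(f"unknown method {method!r}; choose from {_METHODS}")
    if "group" not in features.columns:
        raise ValidationError("features table must have a 'group' column")
    names = feature_names if feature_names is not None else FEATURE_NAMES
    sub_a = features[features["group"] == group_a]
    sub_b = features[features["group"] == group_b]

    results = []
    for name in names:
        a = sub_a[name].dropna().to_numpy(dtype=float)
        b = sub_b[name].dropna().to_numpy(dtype=float)
        stats_ab = [
            float(np.mean(v)) if len(v) else np.nan for v in (a, b)
        ]
        sds = [float(np.std(v, ddof=1)) if len(v) > 1 else np.nan for v in (a, b)]
        if len(a) < min_per_group or len(b) < min_per_group:
            p = np.nan
        else:
            p = _test(a, b, method)
            if np.isnan(p):
                p = np.nan
        results.append(
            ComparisonResult(
                index_name=name,
                group_a=group_a,
                group_b=group_b,
                mean_a=stats_ab[0],
                sd_a=sds[0],
                mean_b=stats_ab[1],
                sd_b=sds[1],
                p_value=p,
                band=assign_band(p),
            )
        )

    if correction is not None:
        testable = [r for r in results if not np.isnan(r.p_value)]
        if testable:
            adjusted = multipletests(
                [r.p_value for r in testable], method=correction
            )[1]
            for r, p_adj in zip(testable, adjusted):
                r.p_value = float(p_adj)
                r.band = assign_band(r.p_value)
    return results


def comparisons_to_frame(results: list[ComparisonResult]) -> pd.DataFrame:
    """Tabulate comparison results, one row per index."""
    return pd.DataFrame(
        [
            dict(
                index_name=r.index_name,
                group_a=r.group_a,
                group_b=r.group_b,
                mean_a=r.mean_a,
                sd_a=r.sd_a,
                mean_b=r.mean_b,
                sd_b=r.sd_b,
                p_value=r.p_value,
                band=r.band,
            )
            for r in results
        ]
    ).set_index("index_name")
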