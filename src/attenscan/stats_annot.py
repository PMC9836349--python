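"""Group comparisons with unequal-variance tests and significance stars.

Two groups are compared with Welch's two-sample t-test (two-sided,
Welch–Satterthwaite degrees of freedom); three or more with Welch's ANOVA.
P-values are annotated with the conventional star ladder
(* ≤0.05, ** ≤0.01, *** ≤0.001, **** ≤0.0001, ns otherwise). No
multiple-testing correction is applied; comparisons must be named explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats


class StatsError(ValueError):
    pass


STAR_THRESHOLDS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (0.05, "*"))


def star_label(p: float) -> str:
    """Significance stars for a p-value; the most extreme threshold wins."""
    if not 0.0 <= p <= 1.0:
        raise StatsError(f"p-value must lie in [0, 1], got {p}")
    for threshold, stars in STAR_THRESHOLDS:
        if p <= threshold:
            return stars
    return "ns"


def welch_test(groups: Sequence[Sequence[float]]) -> float:
    """Two-sided p-value comparing group means under unequal variances.

    Two groups: Welch's t-test. More: Welch's ANOVA. Each group needs at
    least two finite replicate values. If every group is exactly constant
    (zero within-group variance) the test statistic is undefined; the
    contract is p = 1 for identical means and p = 0 otherwise.
    """
    arrays = [np.asarray(g, dtype=np.float64) for g in groups]
    if len(arrays) < 2:
        raise StatsError("need at least two groups")
    for idx, arr in enumerate(arrays):
        if arr.ndim != 1 or len(arr) < 2:
            raise StatsError(f"group {idx} needs at least 2 replicate values")
        if not np.all(np.isfinite(arr)):
            raise StatsError(f"group {idx} contains non-finite values")
    if all(float(a.var(ddof=1)) == 0.0 for a in arrays):
        means = [float(a.mean()) for a in arrays]
        return 1.0 if len(set(means)) == 1 else 0.0
    if len(arrays) == 2:
        result = stats.ttest_ind(arrays[0], arrays[1], equal_var=False)
        return float(result.pvalue)
    return _welch_anova(arrays)


def _welch_anova(arrays: list[np.ndarray]) -> float:
    import pandas as pd
    import pingouin

    frame = pd.DataFrame({
        "value": np.concatenate(arrays),
        "group": np.concatenate([
            np.full(len(a), i) for i, a in enumerate(arrays)
        ]),
    })
    table = pingouin.welch_anova(data=frame, dv="value", between="group")
    return float(table["p_unc"].iloc[0])


@dataclass(frozen=True)
class GroupComparison:
    """A named comparison between replicate groups, with its verdict."""

    labels: tuple[str, ...]
    test: str           # "welch_t" or "welch_anova"
    p_value: float
    stars: str


def compare_groups(groups: Mapping[str, Sequence[float]]) -> GroupComparison:
    """Run the appropriate Welch test on labeled replicate groups."""
    labels = tuple(groups)
    p = welch_test([groups[lbl] for lbl in labels])
    test = "welch_t" if len(labels) == 2 else "welch_anova"
    return GroupComparison(labels=labels, test=test, p_value=p,
                           stars=star_label(p))
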