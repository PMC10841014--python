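"""Shared replicate statistics: Welch t-test with the three-star convention."""

from __future__ import annotations

from typing import Sequence, Tuple

import numpy as np
from scipy import stats

STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def stars_for_p(p: float) -> str:
    for threshold, stars in STAR_THRESHOLDS:
        if p < threshold:
            return stars
    return ""


def welch_stars(group_a: Sequence[float], group_b: Sequence[float]) -> Tuple[float, str]:
    """Two-sided Welch t-test plus significance stars.

    Degenerate input (both groups constant and identical) yields p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if a.std() == 0 and b.std() == 0:
        p = 1.0 if a.mean() == b.mean() else 0.0
    else:
        p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        if np.isnan(p):
            p = 1.0
    return p, stars_for_p(p)
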