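"""Group descriptive statistics and two-sample comparisons.

Covers the two statistical forms used at the group level: descriptive
summaries (n, mean, median, SD, SEM, min, max) of a raw value list — e.g.
hemisphere surface areas of the cortical foveal confluence — and two-sample
t-tests with Cohen's d computed from summary statistics (n, mean, SD) per
group, as used to compare carrier and control resolution thresholds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class GroupSummary:
    n: int
    mean: float
    median: float
    sd: float | None
    sem: float | None
    min: float
    max: float
    units: str = ""

    def rounded(self, ndigits: int = 0) -> dict:
        """Summary rounded for comparison against printed tables (half-up)."""

        def r(v):
            if v is None:
                return None
            return round_half_up(v, ndigits)

        return {
            "n": self.n,
            "mean": r(self.mean),
            "median": r(self.median),
            "sd": r(self.sd),
            "sem": r(self.sem),
            "min": r(self.min),
            "max": r(self.max),
        }


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (the convention of printed tables)."""
    factor = 10.0**ndigits
    return math.floor(abs(value) * factor + 0.5) / factor * math.copysign(1.0, value)


def summarize(values: Sequence[float], units: str = "") -> GroupSummary:
    """Descriptive summary of a raw value list.

    SD is the sample standard deviation (n-1 denominator); SEM = SD/sqrt(n).
    A single value has undefined SD/SEM, reported as None.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty value list")
    if arr.size == 1:
        v = float(arr[0])
        return GroupSummary(1, v, v, None, None, v, v, units)
    sd = float(np.std(arr, ddof=1))
    return GroupSummary(
        n=int(arr.size),
        mean=float(np.mean(arr)),
        median=float(np.median(arr)),
        sd=sd,
        sem=sd / math.sqrt(arr.size),
        min=float(np.min(arr)),
        max=float(np.max(arr)),
        units=units,
    )


def two_sample_t(
    g1: tuple[int, float, float],
    g2: tuple[int, float, float],
    variant: str = "pooled",
) -> tuple[float, float, float, float]:
    """Two-sample t-test and Cohen's d from per-group (n, mean, sd).

    Parameters
    ----------
    g1, g2 : (n, mean, sd)
        Group summary statistics; sd is the sample SD.
    variant : {"pooled", "welch"}
        Pooled-variance Student's t (default) or Welch's unequal-variance t.

    Returns
    -------
    (t, df, p, cohen_d)
        Two-sided p-value; Cohen's d = |mean difference| / pooled SD
        (pooled SD is used for d under both variants).
    """
    n1, m1, s1 = g1
    n2, m2, s2 = g2
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown variant {variant!r}")
    pooled_var = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)
    if pooled_var == 0:
        raise ValueError("zero pooled variance: groups are degenerate")
    pooled_sd = math.sqrt(pooled_var)
    diff = m1 - m2
    if variant == "pooled":
        se = pooled_sd * math.sqrt(1.0 / n1 + 1.0 / n2)
        df = float(n1 + n2 - 2)
    else:
        v1, v2 = s1**2 / n1, s2**2 / n2
        se = math.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    t = diff / se
    p = 2.0 * float(stats.t.sf(abs(t), df))
    d = abs(diff) / pooled_sd
    return t, df, p, d
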