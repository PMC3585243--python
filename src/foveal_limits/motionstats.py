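"""Fixational eye-motion traces and fixation-stability statistics.

The position of the stimulus on the retina, extracted frame by frame from
AOSLO videos, is a direct measure of fixational spread.  Stability at a test
location is summarized as the standard deviation of stimulus position,
averaged over the horizontal and vertical directions.  Individual eyes are
classified against a normal cohort by a linear regression of fixation SD on
eccentricity with a 95% prediction band.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm_api


@dataclass(frozen=True)
class MotionTrace:
    """Per-frame retinal displacement of the stimulus/frame, in arcmin.

    ``x`` and ``y`` are positions relative to an arbitrary reference (the
    statistics used downstream are translation-invariant).
    """

    x: np.ndarray
    y: np.ndarray
    frame_rate: float = 30.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")

    def __len__(self) -> int:
        return self.x.size

    @property
    def positions(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    def shifted(self, dx: float, dy: float) -> "MotionTrace":
        return MotionTrace(self.x + dx, self.y + dy, self.frame_rate)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"frame": np.arange(len(self)), "dx_arcmin": self.x, "dy_arcmin": self.y}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, frame_rate: float = 30.0) -> "MotionTrace":
        df = pd.read_csv(path)
        return cls(df["dx_arcmin"].to_numpy(), df["dy_arcmin"].to_numpy(), frame_rate)


@dataclass(frozen=True)
class FixationSummary:
    """Fixation stability at one test location."""

    sd_x: float
    sd_y: float
    eccentricity: float = 0.0
    condition: str = "looking-at-stimulus"
    subject: str = ""

    def __post_init__(self) -> None:
        if self.sd_x < 0 or self.sd_y < 0:
            raise ValueError("standard deviations must be nonnegative")

    @property
    def sd_mean(self) -> float:
        return 0.5 * (self.sd_x + self.sd_y)


def fixation_sd(
    trace: MotionTrace,
    eccentricity: float = 0.0,
    condition: str = "looking-at-stimulus",
    subject: str = "",
) -> FixationSummary:
    """Positional SD of a trace (sample SD per axis; a constant trace gives 0)."""
    if len(trace) < 10:
        raise ValueError(f"trace has {len(trace)} frames; need >= 10")
    return FixationSummary(
        sd_x=float(np.std(trace.x, ddof=1)),
        sd_y=float(np.std(trace.y, ddof=1)),
        eccentricity=eccentricity,
        condition=condition,
        subject=subject,
    )


@dataclass(frozen=True)
class NormalEnvelope:
    """OLS fit of fixation SD vs eccentricity with a 95% prediction band."""

    slope: float
    intercept: float
    _results: object = field(repr=False, default=None)

    def line(self, ecc) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(ecc, dtype=float)

    def band(self, ecc) -> tuple[np.ndarray, np.ndarray]:
        """(lower, upper) 95% prediction band at the given eccentricities."""
        ecc = np.atleast_1d(np.asarray(ecc, dtype=float))
        exog = sm_api.add_constant(ecc, has_constant="add")
        pred = self._results.get_prediction(exog)
        frame = pred.summary_frame(alpha=0.05)
        return frame["obs_ci_lower"].to_numpy(), frame["obs_ci_upper"].to_numpy()

    def outside(self, ecc, sd) -> np.ndarray:
        """True where a point lies above the upper or below the lower band."""
        lower, upper = self.band(ecc)
        sd = np.atleast_1d(np.asarray(sd, dtype=float))
        return (sd > upper) | (sd < lower)


def normal_envelope(points: Sequence[tuple[float, float]]) -> NormalEnvelope:
    """Fit the normal-cohort envelope from (eccentricity, sd) pairs.

    A prediction-style band is used (rather than a mean-response band)
    because the envelope classifies individual eyes, not cohort means.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 (ecc, sd) points")
    ecc, sd = pts[:, 0], pts[:, 1]
    if np.unique(ecc).size < 3:
        raise ValueError("need at least 3 distinct eccentricities")
    exog = sm_api.add_constant(ecc, has_constant="add")
    results = sm_api.OLS(sd, exog).fit()
    return NormalEnvelope(
        slope=float(results.params[1]),
        intercept=float(results.params[0]),
        _results=results,
    )


def condition_compare(summaries: Sequence[FixationSummary]) -> pd.DataFrame:
    """Group x condition mean ± SEM of fixation SD.

    Groups are inferred from the ``subject`` prefix before the first ``:`` if
    present, otherwise each summary's ``subject`` string is its group.
    """
    if not summaries:
        raise ValueError("no summaries given")
    rows = [
        {
            "group": s.subject.split(":")[0] if s.subject else "all",
            "condition": s.condition,
            "sd_mean": s.sd_mean,
        }
        for s in summaries
    ]
    df = pd.DataFrame(rows)
    conditions = df["condition"].unique()
    if len(conditions) < 2:
        raise ValueError("both conditions must be present")
    out = (
        df.groupby(["group", "condition"])["sd_mean"]
        .agg(n="count", mean="mean", sem="sem")
        .reset_index()
    )
    if (out["n"] == 0).any():
        raise ValueError("empty group/condition cell")
    return out
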