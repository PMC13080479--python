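"""Germination-time calling from single-spore phase-contrast traces.

A dormant spore is phase-bright; on germination it rehydrates and turns
phase-dark within a few frames.  Germination time is called per spore as
the first frame whose intensity falls strictly below the midpoint between
the pre-germination and post-germination plateau levels.  Cohort-level
kinetics are summarised by the cumulative distribution of germination
times, and the population's maximum germination rate is the largest slope
of a line fitted to 3 consecutive CDF points, reported in h^-1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "IntensityTrace",
    "GerminationCall",
    "GerminationCDF",
    "RateEstimate",
    "CallConfig",
    "call_germination",
    "call_cohort",
    "germination_cdf",
    "max_germination_rate",
    "traces_from_frame",
]


@dataclass
class IntensityTrace:
    """Per-spore phase-contrast intensity versus time (minutes)."""

    spore_id: Union[int, str]
    times: np.ndarray  # min
    intensity: np.ndarray  # arbitrary units

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.times.size != self.intensity.size:
            raise ValidationError("times and intensity must have equal length")
        if self.times.size < 6:
            raise ValidationError("trace needs >= 6 frames to estimate both plateaus")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("times must be strictly increasing")


@dataclass
class GerminationCall:
    spore_id: Union[int, str]
    germinated: bool
    t_germ: Optional[float]  # min; None if never germinated
    pre_level: float
    post_level: float
    midpoint: float


@dataclass(frozen=True)
class CallConfig:
    """Tunables of the calling rule.

    fraction_drop: a spore counts as germinated only if its post plateau
    fell below this fraction of the pre plateau (default 0.5, the 50%
    phase-intensity drop criterion).  plateau_frames: frames averaged at
    each end of the trace to estimate the plateaus.
    """

    fraction_drop: float = 0.5
    plateau_frames: int = 3


def call_germination(trace: IntensityTrace, config: CallConfig = CallConfig()) -> GerminationCall:
    """Call germination status and time for one trace.

    pre/post plateau = mean of the first/last ``plateau_frames`` frames;
    germinated iff post < fraction_drop * pre and the trace crosses the
    midpoint; t_germ = earliest frame time with intensity strictly below
    the midpoint (frame resolution, no interpolation).
    """
    k = config.plateau_frames
    pre = float(trace.intensity[:k].mean())
    post = float(trace.intensity[-k:].mean())
    midpoint = 0.5 * (pre + post)
    below = trace.intensity < midpoint
    germinated = bool(post < config.fraction_drop * pre and below.any())
    t_germ = float(trace.times[int(np.argmax(below))]) if germinated else None
    return GerminationCall(
        spore_id=trace.spore_id,
        germinated=germinated,
        t_germ=t_germ,
        pre_level=pre,
        post_level=post,
        midpoint=midpoint,
    )


def call_cohort(
    traces: Sequence[IntensityTrace], config: CallConfig = CallConfig()
) -> list[GerminationCall]:
    return [call_germination(t, config) for t in traces]


@dataclass
class GerminationCDF:
    """Cumulative fraction of the cohort germinated by each frame time.

    Never-germinating spores stay in the denominator, so the plateau equals
    the germinated fraction at movie end, not 1.
    """

    times: np.ndarray  # min
    cum_fraction: np.ndarray
    n_total: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_min": self.times, "cum_fraction": self.cum_fraction})

    def to_csv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, index=False)


def germination_cdf(
    calls: Sequence[GerminationCall], frame_times: Sequence[float]
) -> GerminationCDF:
    """Empirical CDF of called germination times over the full cohort."""
    if len(calls) == 0:
        raise ValidationError("cohort is empty")
    frame_times = np.asarray(frame_times, dtype=float)
    t_germs = np.array([c.t_germ for c in calls if c.germinated], dtype=float)
    if t_germs.size and t_germs.max() > frame_times.max() + 1e-9:
        raise ValidationError("frame_times does not cover all called germination times")
    counts = (t_germs[None, :] <= frame_times[:, None] + 1e-9).sum(axis=1)
    return GerminationCDF(
        times=frame_times,
        cum_fraction=counts / len(calls),
        n_total=len(calls),
    )


@dataclass
class RateEstimate:
    max_rate: float  # h^-1
    window_start_index: int
    slope_points: int = 3


def max_germination_rate(cdf: GerminationCDF) -> RateEstimate:
    """Maximum 3-point least-squares slope of the CDF, in h^-1.

    The slope is computed over every window of 3 consecutive CDF points
    (for equispaced times this equals (y3 - y1)/(t3 - t1)); the maximum
    wins, ties going to the earliest window.
    """
    t = cdf.times
    y = cdf.cum_fraction
    if t.size < 3:
        raise ValidationError("CDF needs >= 3 points for a 3-point slope")
    n_win = t.size - 2
    slopes = np.empty(n_win)
    for i in range(n_win):
        tw, yw = t[i : i + 3], y[i : i + 3]
        tc = tw - tw.mean()
        slopes[i] = float(tc @ (yw - yw.mean()) / (tc @ tc))  # per minute
    best = int(np.argmax(slopes))  # argmax returns the earliest tie
    return RateEstimate(max_rate=max(slopes[best], 0.0) * 60.0, window_start_index=best)


def traces_from_frame(df: pd.DataFrame) -> list[IntensityTrace]:
    """Read traces from a long table with columns spore_id, time_min, intensity."""
    out = []
    for sid, grp in df.groupby("spore_id", sort=True):
        grp = grp.sort_values("time_min")
        out.append(
            IntensityTrace(
                spore_id=sid,
                times=grp["time_min"].to_numpy(),
                intensity=grp["intensity"].to_numpy(),
            )
        )
    return out
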