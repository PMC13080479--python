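"""Viable-count estimation and the co-culture yield-ratio statistic.

In the competition assay, *B. subtilis* spores are co-incubated with a
partner species either untreated ("native" arm) or with exogenous
L-alanine added to force germination ("forced" arm).  Viable *B. subtilis*
is measured per arm by serial-dilution plating; the yield ratio
N_nat / N_germ compares the arms — values above 1 mean the spores were
better off staying dormant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "DilutionCount",
    "CfuEstimate",
    "YieldRatioResult",
    "cfu_from_dilution_series",
    "estimates_from_table",
    "yield_ratio",
]

DEFAULT_WINDOW = (30, 300)  # countable colonies per plate


@dataclass(frozen=True)
class DilutionCount:
    """One plate of a serial dilution series."""

    species: str
    arm: str  # 'native' | 'forced'
    replicate_id: Union[int, str]
    dilution_factor: float  # e.g. 1e-4
    plated_volume: float  # mL
    colonies: int

    def __post_init__(self) -> None:
        if self.arm not in ("native", "forced"):
            raise ValidationError(f"arm must be 'native' or 'forced', got {self.arm!r}")
        if not (0 < self.dilution_factor <= 1):
            raise ValidationError("dilution_factor must be in (0, 1]")
        if self.plated_volume <= 0:
            raise ValidationError("plated_volume must be > 0")
        if self.colonies < 0 or self.colonies != int(self.colonies):
            raise ValidationError("colonies must be a non-negative integer")


@dataclass
class CfuEstimate:
    species: str
    arm: str
    replicate_id: Union[int, str]
    cfu_per_ml: float
    n_countable_plates: int
    flag: Optional[str] = None  # 'no_countable_plate' | 'all_zero'


def cfu_from_dilution_series(
    counts: Sequence[DilutionCount],
    window: tuple = DEFAULT_WINDOW,
) -> CfuEstimate:
    """Pooled viable-count estimate from one replicate's dilution series.

    Plates whose colony count lies inside the countable window contribute;
    the estimate pools them as sum(colonies) / sum(dilution * volume),
    i.e. each plate's rate weighted by its plated dilution-volume (the
    Poisson maximum-likelihood combination).  If no plate is countable the
    plate closest to the window is used alone and the estimate is flagged;
    all-zero counts give a flagged 0 (a legitimate kill result).
    """
    if not counts:
        raise ValidationError("need at least one plate")
    keys = {(c.species, c.arm, c.replicate_id) for c in counts}
    if len(keys) > 1:
        raise ValidationError("plates mix species/arm/replicate identities")
    species, arm, rep = next(iter(keys))

    lo, hi = window
    countable = [c for c in counts if lo <= c.colonies <= hi]
    flag = None
    if not countable:
        if all(c.colonies == 0 for c in counts):
            return CfuEstimate(species, arm, rep, 0.0, 0, flag="all_zero")
        # fall back to the plate nearest the window (most colonies on a tie)
        def dist(c: DilutionCount) -> tuple:
            d = lo - c.colonies if c.colonies < lo else c.colonies - hi
            return (max(d, 0), -c.colonies)

        countable = [min(counts, key=dist)]
        flag = "no_countable_plate"
    total = sum(c.colonies for c in countable)
    denom = sum(c.dilution_factor * c.plated_volume for c in countable)
    return CfuEstimate(
        species,
        arm,
        rep,
        cfu_per_ml=total / denom,
        n_countable_plates=len(countable) if flag is None else 0,
        flag=flag,
    )


def estimates_from_table(
    df: pd.DataFrame, window: tuple = DEFAULT_WINDOW
) -> list[CfuEstimate]:
    """Per-replicate estimates from a tidy table of DilutionCount columns."""
    out = []
    for (_, _, _), grp in df.groupby(["species", "arm", "replicate_id"], sort=True):
        plates = [
            DilutionCount(
                species=r.species,
                arm=r.arm,
                replicate_id=r.replicate_id,
                dilution_factor=float(r.dilution_factor),
                plated_volume=float(r.plated_volume),
                colonies=int(r.colonies),
            )
            for r in grp.itertuples()
        ]
        out.append(cfu_from_dilution_series(plates, window=window))
    return out


@dataclass
class YieldRatioResult:
    """N_nat / N_germ with delta-method SEM and the dormancy verdict."""

    species: str
    ratio: float
    sem: float
    n_native: int
    n_forced: int
    verdict: str  # 'dormancy_advantage' | 'germination_advantage' | 'indeterminate'
    flag: Optional[str] = None


def _arm_stats(estimates: Sequence[CfuEstimate]) -> tuple:
    vals = np.array([e.cfu_per_ml for e in estimates], dtype=float)
    mean = float(vals.mean())
    sem = float(vals.std(ddof=1) / math.sqrt(vals.size)) if vals.size > 1 else 0.0
    return mean, sem, vals.size


def yield_ratio(
    native: Sequence[CfuEstimate], forced: Sequence[CfuEstimate]
) -> YieldRatioResult:
    """Ratio of arm means with first-order (delta-method) SEM propagation.

    verdict is 'indeterminate' when ratio +/- sem spans 1; a zero forced
    mean yields an infinite ratio, flagged, with verdict dormancy_advantage.
    """
    if not native or not forced:
        raise ValidationError("both arms need at least one estimate")
    species = native[0].species
    m_nat, s_nat, n_nat = _arm_stats(native)
    m_for, s_for, n_for = _arm_stats(forced)
    if m_for == 0.0:
        return YieldRatioResult(
            species, math.inf, math.nan, n_nat, n_for,
            verdict="dormancy_advantage", flag="zero_forced_mean",
        )
    ratio = m_nat / m_for
    rel = 0.0
    if m_nat > 0:
        rel = math.sqrt((s_nat / m_nat) ** 2 + (s_for / m_for) ** 2)
    sem = ratio * rel
    if ratio - sem <= 1.0 <= ratio + sem:
        verdict = "indeterminate"
    elif ratio > 1.0:
        verdict = "dormancy_advantage"
    else:
        verdict = "germination_advantage"
    return YieldRatioResult(species, ratio, sem, n_nat, n_for, verdict)
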