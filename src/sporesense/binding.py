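"""Competitive enantiomer binding and the germination rate law.

A dormant *B. subtilis* spore carries a germinant receptor to which
L-alanine (the germinant) and D-alanine (a competitive inhibitor) both
bind.  With dissociation constants ``k_l`` and ``k_d`` and total receptor
normalised to one, the equilibrium fraction of receptor in the active
L-bound state is

    [LG]/G_T = (L/k_l) / (1 + L/k_l + D/k_d)

and the germination rate is proportional to it,

    rate(L, D) = alpha * L / (k_l + L + g * D),      g = k_l / k_d.

``alpha`` is the maximal germination rate (events per hour per spore, the
slope of the germination-time CDF at saturating L and no D).  Because the
denominator is dominated by ``g * D`` whenever D-alanine is appreciable,
the response depends mainly on the L/D ratio rather than on absolute
concentrations — the ratiometric behaviour this package quantifies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError

ArrayLike = Union[float, np.ndarray]

__all__ = [
    "BindingParams",
    "RateMap",
    "RegionMask",
    "germination_rate",
    "bound_fraction",
    "response_map",
    "germination_region",
    "region_boundary_L",
    "classify_concentration",
    "log_grid",
]


@dataclass(frozen=True)
class BindingParams:
    """Parameters of the competitive-binding rate law.

    Parameters
    ----------
    alpha : float
        Maximal germination rate, h^-1 (CDF-slope units).
    k_l : float
        Dissociation constant of L-alanine, mM.
    k_d : float
        Dissociation constant of D-alanine, mM.
    """

    alpha: float
    k_l: float
    k_d: float

    def __post_init__(self) -> None:
        for name in ("alpha", "k_l", "k_d"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ValidationError(f"{name} must be finite and > 0, got {value!r}")

    @property
    def g(self) -> float:
        """Ratio of dissociation constants k_l / k_d (always recomputed)."""
        return self.k_l / self.k_d

    def to_dict(self) -> dict:
        return {"alpha": self.alpha, "k_l": self.k_l, "k_d": self.k_d}

    @classmethod
    def from_dict(cls, d: dict) -> "BindingParams":
        return cls(alpha=float(d["alpha"]), k_l=float(d["k_l"]), k_d=float(d["k_d"]))

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "BindingParams":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _check_concentrations(L: ArrayLike, D: ArrayLike) -> tuple[np.ndarray, np.ndarray]:
    L = np.asarray(L, dtype=float)
    D = np.asarray(D, dtype=float)
    if np.any(~np.isfinite(L)) or np.any(L < 0):
        raise ValidationError("L must be finite and >= 0")
    if np.any(~np.isfinite(D)) or np.any(D < 0):
        raise ValidationError("D must be finite and >= 0")
    return L, D


def germination_rate(L: ArrayLike, D: ArrayLike, params: BindingParams) -> ArrayLike:
    """Germination rate alpha * L / (k_l + L + g*D) in h^-1.

    Accepts scalars or broadcastable arrays of concentrations (mM).
    """
    L, D = _check_concentrations(L, D)
    out = params.alpha * L / (params.k_l + L + params.g * D)
    return out if out.ndim else float(out)


def bound_fraction(L: ArrayLike, D: ArrayLike, params: BindingParams) -> ArrayLike:
    """Equilibrium active-receptor fraction (L/k_l)/(1 + L/k_l + D/k_d).

    Algebraically identical to ``germination_rate`` with ``alpha = 1``;
    kept as an independent code path so the two can be cross-checked.
    """
    L, D = _check_concentrations(L, D)
    x = L / params.k_l
    y = D / params.k_d
    out = x / (1.0 + x + y)
    return out if out.ndim else float(out)


def _check_grid(grid: ArrayLike, name: str) -> np.ndarray:
    grid = np.atleast_1d(np.asarray(grid, dtype=float))
    if grid.size == 0:
        raise ValidationError(f"{name} must be non-empty")
    if np.any(grid < 0) or np.any(~np.isfinite(grid)):
        raise ValidationError(f"{name} must be finite and >= 0")
    if grid.size > 1 and np.any(np.diff(grid) <= 0):
        raise ValidationError(f"{name} must be strictly increasing")
    return grid


@dataclass
class RateMap:
    """Maximum germination rate over a grid of (L, D) concentration pairs.

    ``rate`` has shape (len(D_grid), len(L_grid)): rows index D, columns L.
    """

    L_grid: np.ndarray
    D_grid: np.ndarray
    rate: np.ndarray

    def __post_init__(self) -> None:
        self.L_grid = _check_grid(self.L_grid, "L_grid")
        self.D_grid = _check_grid(self.D_grid, "D_grid")
        self.rate = np.asarray(self.rate, dtype=float)
        if self.rate.shape != (self.D_grid.size, self.L_grid.size):
            raise ValidationError(
                f"rate has shape {self.rate.shape}, expected "
                f"{(self.D_grid.size, self.L_grid.size)}"
            )
        if np.any(self.rate < 0) or np.any(~np.isfinite(self.rate)):
            raise ValidationError("rate must be finite and >= 0")

    @property
    def LL(self) -> np.ndarray:
        return np.meshgrid(self.L_grid, self.D_grid)[0]

    @property
    def DD(self) -> np.ndarray:
        return np.meshgrid(self.L_grid, self.D_grid)[1]

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format view with columns L_mM, D_mM, rate_per_h."""
        return pd.DataFrame(
            {
                "L_mM": self.LL.ravel(),
                "D_mM": self.DD.ravel(),
                "rate_per_h": self.rate.ravel(),
            }
        )

    def to_csv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RateMap":
        L_grid = np.sort(df["L_mM"].unique())
        D_grid = np.sort(df["D_mM"].unique())
        wide = df.pivot_table(index="D_mM", columns="L_mM", values="rate_per_h")
        wide = wide.reindex(index=D_grid, columns=L_grid)
        if wide.isna().any().any():
            raise ValidationError("rate map table does not cover the full L x D grid")
        return cls(L_grid=L_grid, D_grid=D_grid, rate=wide.to_numpy())

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "RateMap":
        return cls.from_frame(pd.read_csv(path))


@dataclass
class RegionMask:
    """Boolean germination region over an (L, D) grid at a rate cutoff."""

    L_grid: np.ndarray
    D_grid: np.ndarray
    inside: np.ndarray
    threshold: float

    def to_frame(self) -> pd.DataFrame:
        LL, DD = np.meshgrid(self.L_grid, self.D_grid)
        return pd.DataFrame(
            {
                "L_mM": LL.ravel(),
                "D_mM": DD.ravel(),
                "inside": self.inside.ravel().astype(int),
            }
        )

    def to_csv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, index=False)


def response_map(L_grid: ArrayLike, D_grid: ArrayLike, params: BindingParams) -> RateMap:
    """Evaluate the rate law over the cartesian grid L_grid x D_grid."""
    L_grid = _check_grid(L_grid, "L_grid")
    D_grid = _check_grid(D_grid, "D_grid")
    LL, DD = np.meshgrid(L_grid, D_grid)
    return RateMap(L_grid=L_grid, D_grid=D_grid, rate=germination_rate(LL, DD, params))


def _check_threshold(threshold: float, params: BindingParams) -> float:
    threshold = float(threshold)
    if not (0.0 < threshold < params.alpha):
        raise ValidationError(
            f"threshold must lie in (0, alpha={params.alpha}), got {threshold}"
        )
    return threshold


def germination_region(
    L_grid: ArrayLike,
    D_grid: ArrayLike,
    params: BindingParams,
    threshold: float,
) -> RegionMask:
    """Grid cells whose predicted rate reaches ``threshold`` (h^-1).

    In the high-D regime the region boundary approaches a constant L/D
    ratio, i.e. a unit-slope line in log-log concentration space.
    """
    threshold = _check_threshold(threshold, params)
    rm = response_map(L_grid, D_grid, params)
    return RegionMask(
        L_grid=rm.L_grid,
        D_grid=rm.D_grid,
        inside=rm.rate >= threshold,
        threshold=threshold,
    )


def region_boundary_L(D: ArrayLike, params: BindingParams, threshold: float) -> ArrayLike:
    """L concentration on the region boundary at given D: rate(L, D) == threshold.

    Solves alpha*L/(k_l + L + g*D) = threshold for L; for D >> k_l/g this
    tends to g*D*t/(1-t) with t = threshold/alpha, the constant-ratio line.
    """
    threshold = _check_threshold(threshold, params)
    D = np.asarray(D, dtype=float)
    t = threshold / params.alpha
    out = t * (params.k_l + params.g * D) / (1.0 - t)
    return out if out.ndim else float(out)


def classify_concentration(
    L: ArrayLike,
    D: ArrayLike,
    params: BindingParams,
    threshold: float,
) -> ArrayLike:
    """Classify concentration pairs as 'germinate' or 'dormant' at a rate cutoff."""
    threshold = _check_threshold(threshold, params)
    rate = germination_rate(L, D, params)
    out = np.where(np.asarray(rate) >= threshold, "germinate", "dormant")
    return out if out.ndim else str(out)


def log_grid(
    lo: float = 1e-3,
    hi: float = 10.0,
    num: int = 8,
    include_zero: bool = False,
) -> np.ndarray:
    """Log-spaced concentration grid (mM), optionally prepended with 0."""
    if lo <= 0 or hi <= lo:
        raise ValidationError("log_grid requires 0 < lo < hi")
    grid = np.geomspace(lo, hi, num)
    if include_zero:
        grid = np.concatenate([[0.0], grid])
    return grid
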