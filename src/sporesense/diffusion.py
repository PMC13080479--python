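"""Explicit 1D diffusion of opposing L-/D-alanine gradients on an agarose pad.

The experiment this emulates: a 2 cm agarose pad carrying immobilised
spores, with thin source strips of agarose containing L-alanine (left) or
D-alanine (right) appended to the pad edges at t = 0.  Each enantiomer then
diffuses across the pad, so a spore at position x experiences a
time-varying concentration pair (L(x,t), D(x,t)).

The solver is forward-time centred-space (FTCS) on the extended domain
pad + source strips, with zero-flux boundaries at both outer ends (a sealed
dish: mass cannot leave) and the source strips as depleting initial
conditions.  FTCS is stable iff D*dt/dx^2 <= 1/2; with the default
D = 1e-5 cm^2/s, dx = 0.005 cm, dt = 1 s the factor is 0.4.

The semi-infinite step solution C(x,t) = (C0/2) * erfc(x / (2*sqrt(D t)))
is provided as an independent closed-form oracle for validating the solver
before boundary effects matter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml
from scipy.special import erfc

from .binding import BindingParams, germination_rate
from .errors import ConfigurationError, ValidationError

__all__ = [
    "SourceSpec",
    "DiffusionConfig",
    "ConcentrationField",
    "SpatialGermination",
    "simulate_profile",
    "analytic_step_solution",
    "predict_spatial_germination",
    "opposing_sources_config",
    "single_source_config",
]


@dataclass(frozen=True)
class SourceSpec:
    """A source strip of alanine-loaded agarose appended to one pad edge."""

    side: str  # 'left' | 'right'
    concentration: float  # mM
    width: float = 0.2  # cm
    species: str = "L"  # 'L' | 'D'

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValidationError(f"side must be 'left' or 'right', got {self.side!r}")
        if self.species not in ("L", "D"):
            raise ValidationError(f"species must be 'L' or 'D', got {self.species!r}")
        if self.concentration < 0:
            raise ValidationError("concentration must be >= 0")
        if self.width <= 0:
            raise ValidationError("width must be > 0")


@dataclass(frozen=True)
class DiffusionConfig:
    """Configuration of the FTCS diffusion run (units: cm, s, mM)."""

    total_time: float
    sources: tuple = ()
    diffusion_coefficient: float = 1e-5  # cm^2/s, same for both enantiomers
    pad_length: float = 2.0  # cm
    dx: float = 0.005  # cm
    dt: float = 1.0  # s
    record_every: float = 60.0  # s

    def __post_init__(self) -> None:
        if self.total_time <= 0 or self.dx <= 0 or self.dt <= 0:
            raise ValidationError("total_time, dx and dt must be > 0")
        for src in self.sources:
            if src.width >= self.pad_length:
                raise ValidationError("source width must be < pad_length")
        if self.stability_factor > 0.5:
            raise ConfigurationError(
                f"FTCS unstable: D*dt/dx^2 = {self.stability_factor:.3g} > 0.5"
            )

    @property
    def stability_factor(self) -> float:
        return self.diffusion_coefficient * self.dt / self.dx**2

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "DiffusionConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sources = tuple(SourceSpec(**s) for s in raw.pop("sources", []))
        return cls(sources=sources, **raw)


@dataclass
class ConcentrationField:
    """Recorded L(x,t) and D(x,t) profiles.

    ``x``/``L``/``D`` cover the pad proper (x = 0 at the pad's left edge);
    the ``*_full`` attributes additionally include the source extensions
    (negative x on the left), on which mass conservation is defined.
    """

    x: np.ndarray  # cm, pad bin centres
    times: np.ndarray  # s
    L: np.ndarray  # time x position, mM
    D: np.ndarray
    x_full: np.ndarray = field(repr=False, default=None)
    L_full: np.ndarray = field(repr=False, default=None)
    D_full: np.ndarray = field(repr=False, default=None)
    dx: float = 0.005

    def mass(self, species: str = "L") -> np.ndarray:
        """Total amount on the extended domain per recorded time (mM*cm)."""
        c = self.L_full if species == "L" else self.D_full
        return c.sum(axis=1) * self.dx

    def to_frame(self) -> pd.DataFrame:
        tt = np.repeat(self.times, self.x.size)
        xx = np.tile(self.x, self.times.size)
        return pd.DataFrame(
            {"time_s": tt, "x_cm": xx, "L_mM": self.L.ravel(), "D_mM": self.D.ravel()}
        )

    def to_csv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class SpatialGermination:
    """Probability of germination by exposure time T, per pad position."""

    x: np.ndarray  # cm
    p_germ: np.ndarray  # in [0, 1]
    T: float  # h

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"x_cm": self.x, "p_germ": self.p_germ})

    def to_csv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, index=False)

    def max_abs_slope(self) -> float:
        """Largest |dp/dx| (cm^-1), the steepness of the germination front."""
        return float(np.max(np.abs(np.gradient(self.p_germ, self.x))))


def _ftcs_step(c: np.ndarray, r: float) -> None:
    # (left + right) - 2*centre keeps the update bitwise mirror-symmetric
    lap = (c[2:] + c[:-2]) - 2.0 * c[1:-1]
    left = c[1] - c[0]
    right = c[-2] - c[-1]
    c[1:-1] += r * lap
    c[0] += r * left
    c[-1] += r * right


def simulate_profile(config: DiffusionConfig) -> ConcentrationField:
    """Run the FTCS solver and record concentration profiles.

    Initial condition: each source's concentration inside its strip, zero
    elsewhere; L and D evolve independently with the same diffusion
    coefficient; no-flux outer boundaries.  Recorded at ``record_every``
    cadence (plus t = 0 and the final step); the reported field is
    restricted to the pad, with positions measured from the pad's left
    edge.
    """
    dx = config.dx
    left_w = max((s.width for s in config.sources if s.side == "left"), default=0.0)
    right_w = max((s.width for s in config.sources if s.side == "right"), default=0.0)
    n_left = int(round(left_w / dx))
    n_pad = int(round(config.pad_length / dx))
    n_right = int(round(right_w / dx))
    n = n_left + n_pad + n_right
    x_full = (np.arange(n) + 0.5) * dx - n_left * dx

    fields = {"L": np.zeros(n), "D": np.zeros(n)}
    for src in config.sources:
        n_w = int(round(src.width / dx))
        sl = slice(0, n_w) if src.side == "left" else slice(n - n_w, n)
        fields[src.species][sl] += src.concentration

    r = config.stability_factor
    n_steps = int(round(config.total_time / config.dt))
    stride = max(1, int(round(config.record_every / config.dt)))

    rec_steps = list(range(0, n_steps + 1, stride))
    if rec_steps[-1] != n_steps:
        rec_steps.append(n_steps)
    rec_times = np.array(rec_steps, dtype=float) * config.dt
    recL = np.empty((len(rec_steps), n))
    recD = np.empty((len(rec_steps), n))

    k = 0
    for step in range(n_steps + 1):
        if step == rec_steps[k]:
            recL[k] = fields["L"]
            recD[k] = fields["D"]
            k += 1
        if step < n_steps:
            _ftcs_step(fields["L"], r)
            _ftcs_step(fields["D"], r)

    if np.any(recL < 0) or np.any(recD < 0):  # impossible under stability
        raise RuntimeError("negative concentration produced by a stable FTCS step")

    pad = slice(n_left, n_left + n_pad)
    return ConcentrationField(
        x=x_full[pad],
        times=rec_times,
        L=recL[:, pad],
        D=recD[:, pad],
        x_full=x_full,
        L_full=recL,
        D_full=recD,
        dx=dx,
    )


def analytic_step_solution(
    C0: float, x: Union[float, np.ndarray], t: float, Dcoef: float
) -> Union[float, np.ndarray]:
    """Closed-form diffusion of a concentration step on an infinite line.

    C(x, t) = (C0/2) * erfc(x / (2*sqrt(Dcoef*t))), with the step at x = 0
    (C0 for x < 0 initially).  Used as the solver's independent oracle while
    the boundaries are still out of reach.
    """
    if t <= 0:
        raise ValidationError("t must be > 0")
    x = np.asarray(x, dtype=float)
    out = 0.5 * C0 * erfc(x / (2.0 * np.sqrt(Dcoef * t)))
    return out if out.ndim else float(out)


def predict_spatial_germination(
    field_: ConcentrationField,
    params: BindingParams,
    T: float,
    hazard_to_prob: Optional[Callable[[np.ndarray], np.ndarray]] = None,
) -> SpatialGermination:
    """Map the simulated gradients to a germination-probability profile.

    Per position, the cumulative hazard is the time integral (trapezoid
    over recorded times) of the binding-model rate r(L(x,t), D(x,t)) up to
    exposure time ``T`` (hours); the default link is the exponential-hazard
    law p = 1 - exp(-H).  Any monotone link can be substituted via
    ``hazard_to_prob``.
    """
    if T <= 0:
        raise ValidationError("T must be > 0")
    T_s = T * 3600.0
    times = field_.times
    if T_s > times[-1] + 1e-9:
        raise ValidationError(
            f"T = {T} h exceeds the simulated horizon {times[-1] / 3600.0} h"
        )
    mask = times <= T_s + 1e-9
    t_sel = times[mask]
    L_sel = field_.L[mask]
    D_sel = field_.D[mask]
    if t_sel[-1] < T_s - 1e-9:  # interpolate the exact endpoint
        j = np.searchsorted(times, T_s)
        w = (T_s - times[j - 1]) / (times[j] - times[j - 1])
        L_end = (1 - w) * field_.L[j - 1] + w * field_.L[j]
        D_end = (1 - w) * field_.D[j - 1] + w * field_.D[j]
        t_sel = np.append(t_sel, T_s)
        L_sel = np.vstack([L_sel, L_end])
        D_sel = np.vstack([D_sel, D_end])

    rate = germination_rate(L_sel, D_sel, params)  # h^-1
    hazard = np.trapezoid(rate, x=t_sel / 3600.0, axis=0)
    p = (1.0 - np.exp(-hazard)) if hazard_to_prob is None else hazard_to_prob(hazard)
    return SpatialGermination(x=field_.x.copy(), p_germ=p, T=T)


def opposing_sources_config(
    L_conc: float = 0.1,
    D_conc: float = 0.2,
    total_time: float = 6 * 3600.0,
    source_width: float = 0.2,
    **kwargs,
) -> DiffusionConfig:
    """Two-source preset: L-alanine strip on the left, D-alanine on the right."""
    return DiffusionConfig(
        total_time=total_time,
        sources=(
            SourceSpec(side="left", concentration=L_conc, width=source_width, species="L"),
            SourceSpec(side="right", concentration=D_conc, width=source_width, species="D"),
        ),
        **kwargs,
    )


def single_source_config(
    L_conc: float = 0.1,
    total_time: float = 6 * 3600.0,
    source_width: float = 0.2,
    **kwargs,
) -> DiffusionConfig:
    """Single-gradient preset: only the left L-alanine source strip."""
    return DiffusionConfig(
        total_time=total_time,
        sources=(
            SourceSpec(side="left", concentration=L_conc, width=source_width, species="L"),
        ),
        **kwargs,
    )
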