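"""Seeded generators for every input the analysis pipeline consumes.

Each generator emulates one of the study's data streams with the
statistical structure the downstream analysis assumes, and returns the
ground truth alongside so every stage can be scored:

- rate maps over (L, D) grids: rate-law mean with multiplicative Gaussian
  noise (rates span orders of magnitude, so noise scales with the mean);
- single-spore intensity traces: constant-hazard (exponential) germination
  times censored at movie end, plateau-transition-plateau shape, additive
  Gaussian read noise;
- phase-contrast image pairs: Gaussian-PSF bright spots on a noisy
  background, each spot germinating (going dark) with a position-dependent
  probability;
- species (L, D) secretion tables: log-uniform over 4 orders of magnitude,
  optionally placed just outside the germination region;
- CFU dilution series: Poisson colony counts.

All generators are bit-reproducible given (config, seed) and share the
single rate-law implementation in :mod:`sporesense.binding`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .binding import (
    BindingParams,
    RateMap,
    germination_rate,
    log_grid,
    region_boundary_L,
    response_map,
)
from .errors import PlacementError, ValidationError
from .imaging import ImageFrame
from .traces import IntensityTrace

__all__ = [
    "CohortConfig",
    "ImageLayout",
    "OpticsSpec",
    "gen_rate_map",
    "gen_trace_cohort",
    "gen_spore_image_pair",
    "gen_species_table",
    "gen_cfu_experiment",
]


def gen_rate_map(
    params: BindingParams,
    L_grid: Optional[Sequence[float]] = None,
    D_grid: Optional[Sequence[float]] = None,
    noise_cv: float = 0.05,
    seed: int = 0,
) -> RateMap:
    """Noisy germination-rate map: model rate times (1 + eps), eps ~ N(0, cv).

    The multiplier is truncated at 0 (eps at -1) so rates stay
    non-negative.  Default grids are log-spaced over 1e-3..10 mM with a
    zero row/column, spanning 4 orders of magnitude.
    """
    if noise_cv < 0:
        raise ValidationError("noise_cv must be >= 0")
    if L_grid is None:
        L_grid = log_grid(include_zero=True)
    if D_grid is None:
        D_grid = log_grid(include_zero=True)
    clean = response_map(L_grid, D_grid, params)
    rng = np.random.default_rng(seed)
    mult = np.maximum(1.0 + rng.normal(0.0, noise_cv, size=clean.rate.shape), 0.0)
    return RateMap(L_grid=clean.L_grid, D_grid=clean.D_grid, rate=clean.rate * mult)


@dataclass(frozen=True)
class CohortConfig:
    """Synthetic trace-cohort settings.

    ``true_rate`` is the constant germination hazard in h^-1; build it from
    a concentration pair with :meth:`from_concentrations`.  Intensities are
    in arbitrary units with noise expressed as a fraction of ``pre_level``.
    """

    n_spores: int = 1000
    true_rate: float = 1.0  # h^-1
    movie_length: float = 360.0  # min
    frame_interval: float = 5.0  # min
    pre_level: float = 1.0
    post_level: float = 0.1
    noise_sd: float = 0.05  # fraction of pre_level
    transition_frames: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.post_level >= self.pre_level:
            raise ValidationError("post_level must be < pre_level")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.frame_interval <= 0:
            raise ValidationError("frame_interval must be > 0")
        if self.true_rate < 0:
            raise ValidationError("true_rate must be >= 0")

    @classmethod
    def from_concentrations(
        cls, L: float, D: float, params: BindingParams, **kwargs
    ) -> "CohortConfig":
        return cls(true_rate=float(germination_rate(L, D, params)), **kwargs)


def gen_trace_cohort(config: CohortConfig) -> tuple[list[IntensityTrace], pd.DataFrame]:
    """Draw a cohort of traces plus their ground-truth germination times.

    Germination times are Exponential(true_rate), censored at movie end
    (the spore stays phase-bright).  Each trace holds ``pre_level`` on
    frames before its germination time; phase-darkening begins at the
    first frame at/after it and completes within ``transition_frames``
    frames (with the default of 1, that frame is already at
    ``post_level``); i.i.d. Gaussian noise of sd ``noise_sd * pre_level``
    is added per frame.  The returned table has columns spore_id,
    t_germ_min (NaN when censored), censored.
    """
    if config.transition_frames < 1:
        raise ValidationError("transition_frames must be >= 1")
    rng = np.random.default_rng(config.seed)
    n = config.n_spores
    if config.true_rate > 0:
        t_germ_h = rng.exponential(1.0 / config.true_rate, size=n)
    else:
        t_germ_h = np.full(n, np.inf)
    t_germ_min = t_germ_h * 60.0
    censored = t_germ_min >= config.movie_length

    times = np.arange(0.0, config.movie_length + 1e-9, config.frame_interval)
    traces = []
    for i in range(n):
        tg = t_germ_min[i]
        # frames since the germination event, counting the event frame as 1
        m = np.floor((times - tg) / config.frame_interval) + 1.0
        frac = np.clip(np.where(times >= tg, m, 0.0) / config.transition_frames, 0.0, 1.0)
        clean = config.pre_level + frac * (config.post_level - config.pre_level)
        noisy = clean + rng.normal(0.0, config.noise_sd * config.pre_level, size=times.size)
        traces.append(IntensityTrace(spore_id=i, times=times.copy(), intensity=noisy))
    truth = pd.DataFrame(
        {
            "spore_id": np.arange(n),
            "t_germ_min": np.where(censored, np.nan, t_germ_min),
            "censored": censored,
        }
    )
    return traces, truth


@dataclass(frozen=True)
class ImageLayout:
    """Geometry of a synthetic spore field."""

    shape: tuple = (256, 1024)  # (rows, cols) px
    n_spores: int = 400  # ~5% half-max coverage, a densely seeded strip
    spot_sigma: float = 2.0  # px, Gaussian PSF width
    min_separation: float = 12.0  # px between spot centres
    pixel_size: float = 10.0  # um per px (strip-scale optics)
    max_tries: int = 10000


@dataclass(frozen=True)
class OpticsSpec:
    """Intensity model of the synthetic phase-contrast frames."""

    background: float = 100.0
    amplitude: float = 50.0  # peak above background for a dormant spore
    dark_amplitude: float = 5.0  # residual peak after germination
    noise_sd: float = 5.0  # additive Gaussian read noise

    @property
    def snr(self) -> float:
        return self.amplitude / self.noise_sd


def _place_spots(layout: ImageLayout, rng: np.random.Generator) -> np.ndarray:
    margin = 4.0 * layout.spot_sigma
    centres: list[tuple] = []
    tries = 0
    while len(centres) < layout.n_spores:
        if tries >= layout.max_tries:
            raise PlacementError(
                f"placed {len(centres)}/{layout.n_spores} spots in {tries} tries; "
                "density too high for the requested separation"
            )
        tries += 1
        r = rng.uniform(margin, layout.shape[0] - margin)
        c = rng.uniform(margin, layout.shape[1] - margin)
        if all((r - r0) ** 2 + (c - c0) ** 2 >= layout.min_separation**2 for r0, c0 in centres):
            centres.append((r, c))
    return np.array(centres)


def _render(
    centres: np.ndarray,
    amplitudes: np.ndarray,
    layout: ImageLayout,
    optics: OpticsSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    img = np.full(layout.shape, optics.background, dtype=float)
    half = int(np.ceil(4 * layout.spot_sigma))
    for (r, c), amp in zip(centres, amplitudes):
        r0, c0 = int(round(r)), int(round(c))
        rows = np.arange(max(r0 - half, 0), min(r0 + half + 1, layout.shape[0]))
        cols = np.arange(max(c0 - half, 0), min(c0 + half + 1, layout.shape[1]))
        rr, cc = np.meshgrid(rows, cols, indexing="ij")
        img[rr, cc] += amp * np.exp(
            -((rr - r) ** 2 + (cc - c) ** 2) / (2.0 * layout.spot_sigma**2)
        )
    img += rng.normal(0.0, optics.noise_sd, size=layout.shape)
    return img


def gen_spore_image_pair(
    layout: ImageLayout,
    p_germ_of_x: Callable[[np.ndarray], np.ndarray],
    optics: OpticsSpec = OpticsSpec(),
    seed: int = 0,
) -> tuple[ImageFrame, ImageFrame, pd.DataFrame]:
    """Synthetic (t0, tF) frame pair with known spore positions and fates.

    Spots are placed uniformly with a minimum separation; each germinates
    independently with probability ``p_germ_of_x`` evaluated at its
    horizontal position in mm (column * pixel_size / 1000).  Germinated
    spots drop to ``dark_amplitude`` in the endpoint frame.  Ground truth
    columns: spore_id, row, col, x_mm, germinated.
    """
    rng = np.random.default_rng(seed)
    centres = _place_spots(layout, rng)
    x_mm = centres[:, 1] * layout.pixel_size / 1000.0
    p = np.asarray(p_germ_of_x(x_mm), dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p_germ_of_x must return probabilities in [0, 1]")
    germinated = rng.random(centres.shape[0]) < p

    amps0 = np.full(centres.shape[0], optics.amplitude)
    ampsF = np.where(germinated, optics.dark_amplitude, optics.amplitude)
    frame_t0 = ImageFrame(
        pixels=_render(centres, amps0, layout, optics, rng),
        pixel_size=layout.pixel_size,
        time_label="t0",
    )
    frame_tF = ImageFrame(
        pixels=_render(centres, ampsF, layout, optics, rng),
        pixel_size=layout.pixel_size,
        time_label="tF",
    )
    truth = pd.DataFrame(
        {
            "spore_id": np.arange(centres.shape[0]),
            "row": centres[:, 0],
            "col": centres[:, 1],
            "x_mm": x_mm,
            "germinated": germinated,
        }
    )
    return frame_t0, frame_tF, truth


def gen_species_table(
    n_species: int,
    L_range: tuple = (1e-3, 10.0),
    D_range: tuple = (1e-3, 10.0),
    seed: int = 0,
    just_outside: Optional[dict] = None,
) -> pd.DataFrame:
    """Log-uniform species (L, D) secretion table (mM), 4 orders of magnitude.

    With ``just_outside={'params': BindingParams, 'threshold': rate}`` the D
    coordinate is instead placed above the germination-region boundary at
    each sampled L (up to one decade beyond it), emulating enantiomer
    ratios that fall just outside the germination response region.
    """
    if L_range[0] <= 0 or D_range[0] <= 0:
        raise ValidationError("concentration ranges must be positive")
    rng = np.random.default_rng(seed)
    L = 10.0 ** rng.uniform(np.log10(L_range[0]), np.log10(L_range[1]), size=n_species)
    if just_outside is None:
        D = 10.0 ** rng.uniform(np.log10(D_range[0]), np.log10(D_range[1]), size=n_species)
    else:
        params: BindingParams = just_outside["params"]
        threshold = float(just_outside["threshold"])
        t = threshold / params.alpha
        # invert the boundary: smallest D making rate(L, D) < threshold
        D_boundary = np.maximum((L * (1.0 - t) / t - params.k_l) / params.g, 0.0)
        pad_decades = rng.uniform(0.05, 1.0, size=n_species)
        D = np.maximum(D_boundary, D_range[0]) * 10.0**pad_decades
    return pd.DataFrame({"species": [f"sp{i:03d}" for i in range(n_species)],
                         "L_mM": L, "D_mM": D})


def gen_cfu_experiment(
    true_cfu: dict,
    dilution_factors: Sequence[float] = (1e-3, 1e-4, 1e-5),
    plated_volume: float = 0.1,
    n_replicates: int = 6,
    seed: int = 0,
    species: str = "synthetic",
) -> pd.DataFrame:
    """Poisson dilution-plate counts for a two-arm competition experiment.

    ``true_cfu`` maps arm name ('native'/'forced') to the true viable
    density in CFU/mL; each plate draws
    colonies ~ Poisson(true_cfu * dilution_factor * plated_volume).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for arm, density in true_cfu.items():
        if density < 0:
            raise ValidationError("true_cfu must be >= 0")
        for rep in range(n_replicates):
            for d in dilution_factors:
                lam = density * d * plated_volume
                rows.append(
                    {
                        "species": species,
                        "arm": arm,
                        "replicate_id": rep,
                        "dilution_factor": d,
                        "plated_volume": plated_volume,
                        "colonies": int(rng.poisson(lam)),
                    }
                )
    return pd.DataFrame(rows)
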