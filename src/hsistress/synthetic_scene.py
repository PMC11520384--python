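"""Synthetic hyperspectral acquisitions with the structure the analysis assumes.

Each scene emulates one dark-room acquisition: an elliptical plant whose
per-pixel spectra derive from a species endmember, a white Teflon reference
strip, and dark background. Three multiplicative effects act on the plant
spectra:

* a diurnal effect (per-band midnight/noon ratio; noon is the reference),
* a mite-stress effect (per-band ratios for low and high infestation,
  optionally amplified at midnight),
* plant growth (the plant mask area follows a monotone schedule over the
  seven acquisition days spanning a 16-day study).

Noise has four components: additive per-band Gaussian pixel noise, a
per-pixel multiplicative brightness factor (leaf angle / self-shading), a
per-plant biological factor constant across that plant's acquisitions, and a
per-acquisition illumination jitter. All are Gaussian, seeded, and scale to
zero together so noiseless scenes reproduce the configured effects exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence, Tuple

import numpy as np

from .cube_io import (
    HyperCube,
    Rect,
    SceneMetadata,
    Units,
    WavelengthAxis,
    make_band_axis,
)

__all__ = [
    "SpeciesSpectralModel",
    "AgingEffect",
    "DiurnalEffect",
    "StressEffect",
    "GrowthModel",
    "NoiseModel",
    "ScenePlan",
    "SceneModels",
    "ratio_from_windows",
    "soybean_model",
    "coleus_model",
    "default_models",
    "generate_scene",
    "generate_study",
    "PANEL_REFLECTANCE",
    "BACKGROUND_REFLECTANCE",
]

PANEL_REFLECTANCE = 0.99
BACKGROUND_REFLECTANCE = 0.02

# acquisition days after infestation: baseline, period 1 (7-9 d), period 2 (14-16 d)
ACQUISITION_SCHEDULE = (0, 7, 8, 9, 14, 15, 16)


def ratio_from_windows(
    axis: WavelengthAxis,
    base: float,
    windows: Sequence[Tuple[float, float, float]],
) -> np.ndarray:
    """Piecewise-constant per-band ratio: `base` everywhere, overridden by
    (start_nm, stop_nm, value) windows applied in order on [start, stop)."""
    ratio = np.full(axis.n_bands, float(base))
    wl = axis.wavelengths_nm
    for start, stop, value in windows:
        ratio[(wl >= start) & (wl < stop)] = float(value)
    return ratio


@dataclass
class SpeciesSpectralModel:
    """Endmember spectrum and within-plant pixel noise for one species."""

    species: str
    endmember: np.ndarray
    pixel_sd: np.ndarray
    axis: WavelengthAxis

    def __post_init__(self):
        self.endmember = np.asarray(self.endmember, dtype=float)
        self.pixel_sd = np.broadcast_to(
            np.asarray(self.pixel_sd, dtype=float), self.endmember.shape
        ).copy()
        if self.endmember.shape != (self.axis.n_bands,):
            raise ValueError("endmember length must match the band axis")
        if np.any(self.endmember < 0) or np.any(self.endmember > 1):
            raise ValueError("endmember reflectance must lie in [0, 1]")
        if np.any(self.pixel_sd < 0):
            raise ValueError("pixel_sd must be nonnegative")


@dataclass
class DiurnalEffect:
    """Per-band multiplicative factor applied at midnight (noon = 1)."""

    ratio: np.ndarray

    def __post_init__(self):
        self.ratio = np.asarray(self.ratio, dtype=float)
        if np.any(self.ratio <= 0):
            raise ValueError("diurnal ratio must be strictly positive")


@dataclass
class StressEffect:
    """Per-band multiplicative factors for low and high mite infestation.

    midnight_gain > 1 amplifies the (log) stress response at midnight,
    mirroring the stronger midnight stress signatures of the study design.
    """

    ratio_low: np.ndarray
    ratio_high: np.ndarray
    midnight_gain: float = 1.5

    def __post_init__(self):
        self.ratio_low = np.asarray(self.ratio_low, dtype=float)
        self.ratio_high = np.asarray(self.ratio_high, dtype=float)
        if self.ratio_low.shape != self.ratio_high.shape:
            raise ValueError("low/high ratios must share the band axis")
        if np.any(self.ratio_low <= 0) or np.any(self.ratio_high <= 0):
            raise ValueError("stress ratios must be strictly positive")
        dep_low = np.abs(np.log(self.ratio_low))
        dep_high = np.abs(np.log(self.ratio_high))
        if np.any(dep_high < dep_low - 1e-12):
            raise ValueError("ratio_high must depart from 1 at least as much as ratio_low")

    def ratio_for(self, treatment: str, session: str) -> np.ndarray:
        if treatment in ("baseline", "control"):
            return np.ones_like(self.ratio_high)
        ratio = self.ratio_low if treatment == "low" else self.ratio_high
        if session == "midnight":
            return ratio**self.midnight_gain
        return ratio


@dataclass
class AgingEffect:
    """Per-band multiplicative drift of leaf reflectance as plants mature.

    ratio_final is the factor reached at the last schedule day; intermediate
    days interpolate geometrically (ratio_final ** (elapsed/total)), so day 0
    is exactly 1. This drift is what separates the baseline class from later
    control acquisitions.
    """

    ratio_final: np.ndarray
    total_days: int = ACQUISITION_SCHEDULE[-1]

    def __post_init__(self):
        self.ratio_final = np.asarray(self.ratio_final, dtype=float)
        if np.any(self.ratio_final <= 0):
            raise ValueError("aging ratio must be strictly positive")

    def ratio_at(self, elapsed_days: float) -> np.ndarray:
        return self.ratio_final ** (elapsed_days / self.total_days)


@dataclass
class GrowthModel:
    """Plant-mask area schedule across the acquisition days."""

    area_day0: float
    fold_total: float
    schedule: Tuple[int, ...] = ACQUISITION_SCHEDULE

    def __post_init__(self):
        if self.area_day0 <= 0 or self.fold_total < 1:
            raise ValueError("need positive initial area and fold_total >= 1")
        if any(b < a for a, b in zip(self.schedule, self.schedule[1:])):
            raise ValueError("schedule days must be non-decreasing")

    def multiplier(self, day_index: int) -> float:
        """Area multiplier at acquisition day_index; geometric in elapsed days."""
        span = self.schedule[-1] - self.schedule[0]
        if span == 0:
            return 1.0
        elapsed = self.schedule[day_index] - self.schedule[0]
        return float(self.fold_total ** (elapsed / span))

    def area(self, day_index: int) -> float:
        return self.area_day0 * self.multiplier(day_index)


@dataclass
class NoiseModel:
    """Noise components of a synthetic acquisition (all Gaussian, seeded).

    scale multiplies every component, including the species model's per-band
    pixel_sd, so scale=0 yields exactly the deterministic effect chain.
    """

    pixel_scale_sd: float = 0.10  # per-pixel multiplicative brightness spread
    replicate_sd: float = 0.02  # per-plant biological factor (constant per plant)
    acquisition_jitter_sd: float = 0.01  # per-scene illumination factor
    panel_sd: float = 0.002  # white-panel pixel noise
    scale: float = 1.0

    @classmethod
    def none(cls) -> "NoiseModel":
        return cls(scale=0.0)


def _gaussian(wl: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-(((wl - center) / width) ** 2))


def _sigmoid(wl: np.ndarray, center: float, width: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(wl - center) / width))


def soybean_model(axis: WavelengthAxis | None = None, pixel_sd: float = 0.02) -> SpeciesSpectralModel:
    """Green-leaf endmember: chlorophyll red absorption near 668 nm, green
    bump at 550 nm, sharp red edge, NIR plateau ~0.46, weak 970 nm water dip."""
    axis = axis or make_band_axis()
    wl = axis.wavelengths_nm
    refl = (
        0.04
        + 0.08 * _gaussian(wl, 550, 45)
        + 0.44 * _sigmoid(wl, 720, 10)
        - 0.008 * _gaussian(wl, 668, 12)
        - 0.05 * _gaussian(wl, 970, 25)
    )
    return SpeciesSpectralModel("soybean", np.clip(refl, 0, 1), pixel_sd, axis)


def coleus_model(axis: WavelengthAxis | None = None, pixel_sd: float = 0.02) -> SpeciesSpectralModel:
    """Anthocyanin-rich reddish endmember: 600-700 nm reflectance elevated
    over the 500-580 nm green region, NIR plateau ~0.45."""
    axis = axis or make_band_axis()
    wl = axis.wavelengths_nm
    refl = (
        0.05
        + 0.05 * _gaussian(wl, 560, 40)
        + 0.13 * _sigmoid(wl, 600, 15)
        + 0.27 * _sigmoid(wl, 720, 12)
        - 0.04 * _gaussian(wl, 970, 25)
    )
    return SpeciesSpectralModel("coleus", np.clip(refl, 0, 1), pixel_sd, axis)


def default_diurnal(species: str, axis: WavelengthAxis | None = None) -> DiurnalEffect:
    """Default midnight/noon ratios: soybean darker at midnight except
    730-900 nm; coleus brighter at midnight except 580-670 nm."""
    axis = axis or make_band_axis()
    if species == "soybean":
        ratio = ratio_from_windows(
            axis,
            0.97,
            [(380, 500, 0.93), (600, 700, 0.92), (730, 900, 1.03), (960, 1016, 0.94)],
        )
    elif species == "coleus":
        ratio = ratio_from_windows(
            axis,
            1.05,
            [(450, 580, 1.08), (580, 670, 0.94), (750, 950, 1.015), (950, 1016, 1.06)],
        )
    else:
        raise ValueError(f"unknown species {species!r}")
    return DiurnalEffect(ratio)


def default_stress(species: str, axis: WavelengthAxis | None = None, low_fraction: float = 0.4) -> StressEffect:
    """Default infestation ratios: reflectance rises in the visible absorption
    regions and drops in the NIR; low infestation is a damped high effect."""
    axis = axis or make_band_axis()
    if species == "soybean":
        high = ratio_from_windows(
            axis, 1.0, [(380, 510, 1.10), (570, 700, 1.12), (700, 800, 0.94)]
        )
    elif species == "coleus":
        high = ratio_from_windows(
            axis, 1.0, [(450, 480, 1.06), (615, 720, 1.10), (760, 800, 0.96), (950, 1016, 0.95)]
        )
    else:
        raise ValueError(f"unknown species {species!r}")
    low = high**low_fraction
    return StressEffect(ratio_low=low, ratio_high=high)


def default_aging(species: str, axis: WavelengthAxis | None = None) -> AgingEffect:
    """Default maturation drift over the 16-day study: chlorophyll build-up
    deepens the red absorption while canopy development raises the NIR."""
    axis = axis or make_band_axis()
    ratio = ratio_from_windows(
        axis, 1.0, [(380, 500, 0.92), (500, 600, 0.95), (600, 700, 0.82), (730, 1016, 1.12)]
    )
    return AgingEffect(ratio)


def default_growth(species: str, scene_shape: Tuple[int, int] = (120, 120)) -> GrowthModel:
    """Growth defaults: soybean ~4-fold, coleus ~3-fold area increase over
    the study; initial area is 3% of the scene."""
    fold = 4.0 if species == "soybean" else 3.0
    area0 = 0.03 * scene_shape[0] * scene_shape[1]
    return GrowthModel(area_day0=area0, fold_total=fold)


@dataclass
class SceneModels:
    """Bundle of generative models for one species."""

    spectral: SpeciesSpectralModel
    diurnal: DiurnalEffect
    stress: StressEffect
    growth: GrowthModel
    aging: AgingEffect | None = None
    noise: NoiseModel = field(default_factory=NoiseModel)


def default_models(
    species: str,
    axis: WavelengthAxis | None = None,
    scene_shape: Tuple[int, int] = (120, 120),
    noise: NoiseModel | None = None,
) -> SceneModels:
    axis = axis or make_band_axis()
    return SceneModels(
        spectral=soybean_model(axis) if species == "soybean" else coleus_model(axis),
        diurnal=default_diurnal(species, axis),
        stress=default_stress(species, axis),
        growth=default_growth(species, scene_shape),
        aging=default_aging(species, axis),
        noise=noise if noise is not None else NoiseModel(),
    )


def default_panel_region(scene_shape: Tuple[int, int]) -> Rect:
    rows, cols = scene_shape
    height = max(4, rows // 12)
    return (2, 2 + height, 2, cols - 2)


def _halogen_gain(axis: WavelengthAxis) -> np.ndarray:
    """Halogen-lamp-like count gain rising toward the NIR (counts per unit
    reflectance); used when scenes are emitted as raw sensor counts."""
    wl = axis.wavelengths_nm
    return 1500.0 + 2500.0 * (wl - wl[0]) / (wl[-1] - wl[0])


def _ellipse_mask(shape: Tuple[int, int], center: Tuple[float, float], area: float, aspect: float = 1.2) -> np.ndarray:
    """Boolean ellipse of the requested pixel area (up to rasterization)."""
    b = math.sqrt(area / (math.pi * aspect))  # row semi-axis
    a = aspect * b
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return ((rr - center[0]) / b) ** 2 + ((cc - center[1]) / a) ** 2 <= 1.0


def generate_scene(
    models: SceneModels,
    meta: SceneMetadata,
    scene_shape: Tuple[int, int] = (120, 120),
    *,
    plant_factor: float | None = None,
    as_counts: bool = False,
    return_mask: bool = False,
):
    """Render one acquisition.

    Plant pixels follow endmember x diurnal^[midnight] x stress^[treatment],
    each pixel perturbed by the noise model and clamped at zero. The white
    panel fills meta.panel_region at reflectance 0.99; everything else is dark
    background. Reproducible from meta.seed. With as_counts=True the cube is
    emitted as raw sensor counts under a halogen-like illumination gain,
    exercising the empirical line calibration downstream.
    """
    spectral, noise = models.spectral, models.noise
    axis = spectral.axis
    rows, cols = scene_shape
    rng = np.random.default_rng(meta.seed)

    area = models.growth.area(meta.day_index)
    panel = meta.panel_region
    center = ((panel[1] + rows) / 2.0, cols / 2.0)
    plant_mask = _ellipse_mask(scene_shape, center, area)
    if not plant_mask.any() or plant_mask[0, :].any() or plant_mask[-1, :].any():
        raise ValueError("plant mask does not fit the scene; enlarge scene_shape")
    plant_mask[panel[0] : panel[1], panel[2] : panel[3]] = False

    if plant_factor is None:
        plant_factor = 1.0 + noise.scale * noise.replicate_sd * rng.standard_normal()

    effect = np.ones(axis.n_bands)
    if meta.session == "midnight":
        effect = effect * models.diurnal.ratio
    effect = effect * models.stress.ratio_for(meta.treatment, meta.session)
    if models.aging is not None:
        elapsed = models.growth.schedule[meta.day_index] - models.growth.schedule[0]
        effect = effect * models.aging.ratio_at(elapsed)

    mean_spectrum = spectral.endmember * effect * plant_factor
    jitter = 1.0 + noise.scale * noise.acquisition_jitter_sd * rng.standard_normal()

    data = np.full((rows, cols, axis.n_bands), BACKGROUND_REFLECTANCE)
    n_plant = int(plant_mask.sum())
    pixel_scale = 1.0 + noise.scale * noise.pixel_scale_sd * rng.standard_normal(n_plant)
    band_noise = noise.scale * spectral.pixel_sd * rng.standard_normal((n_plant, axis.n_bands))
    data[plant_mask] = mean_spectrum * pixel_scale[:, None] + band_noise

    r0, r1, c0, c1 = panel
    panel_shape = (r1 - r0, c1 - c0, axis.n_bands)
    data[r0:r1, c0:c1] = PANEL_REFLECTANCE + noise.scale * noise.panel_sd * rng.standard_normal(panel_shape)

    data *= jitter
    np.clip(data, 0.0, None, out=data)

    if as_counts:
        data = data * _halogen_gain(axis)
        cube = HyperCube(data, axis, Units.raw_counts)
    else:
        cube = HyperCube(data, axis, Units.reflectance)
    meta.validate_against(cube)
    if return_mask:
        return cube, plant_mask
    return cube


@dataclass
class ScenePlan:
    """Full factorial acquisition design: days x sessions x treatment groups
    x replicates per species (7 x 2 x 3 x 8 = 336 at full scale)."""

    species: Tuple[str, ...] = ("soybean", "coleus")
    n_days: int = 7
    sessions: Tuple[str, ...] = ("noon", "midnight")
    treatments: Tuple[str, ...] = ("control", "low", "high")
    replicates: int = 8
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.species, str):
            self.species = (self.species,)
        if not 1 <= self.n_days <= len(ACQUISITION_SCHEDULE):
            raise ValueError(f"n_days must be in 1..{len(ACQUISITION_SCHEDULE)}")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")

    @property
    def n_combinations_per_species(self) -> int:
        return self.n_days * len(self.sessions) * len(self.treatments) * self.replicates

    def combinations(self) -> Iterator[Tuple[str, int, str, str, int]]:
        for sp in self.species:
            for day in range(self.n_days):
                for session in self.sessions:
                    for treatment in self.treatments:
                        for rep in range(1, self.replicates + 1):
                            yield sp, day, session, treatment, rep


def _derived_seed(master: int, *key: int) -> int:
    ss = np.random.SeedSequence((int(master),) + tuple(int(k) for k in key))
    return int(ss.generate_state(1)[0] % (2**31))


def generate_study(
    plan: ScenePlan,
    models: dict[str, SceneModels] | None = None,
    scene_shape: Tuple[int, int] = (120, 120),
    *,
    noise: NoiseModel | None = None,
    as_counts: bool = False,
) -> Iterator[Tuple[HyperCube, SceneMetadata]]:
    """Yield one (cube, metadata) per design combination, lazily.

    Day-0 scenes are emitted with treatment "baseline" (plants imaged before
    infestation), so all treatment groups contribute to the baseline pool.
    Each plant keeps one biological factor across all of its acquisitions;
    scene seeds derive deterministically from plan.seed.
    """
    if models is None:
        models = {
            sp: default_models(sp, scene_shape=scene_shape, noise=noise)
            for sp in plan.species
        }
    elif noise is not None:
        models = {sp: replace(m, noise=noise) for sp, m in models.items()}

    panel = default_panel_region(scene_shape)
    for sp, day, session, treatment, rep in plan.combinations():
        m = models[sp]
        sp_i = plan.species.index(sp)
        tr_i = plan.treatments.index(treatment)
        se_i = plan.sessions.index(session)
        plant_rng = np.random.default_rng(_derived_seed(plan.seed, 7, sp_i, tr_i, rep))
        plant_factor = 1.0 + m.noise.scale * m.noise.replicate_sd * plant_rng.standard_normal()
        meta = SceneMetadata(
            species=sp,
            treatment="baseline" if day == 0 else treatment,
            day_index=day,
            session=session,
            replicate=rep,
            panel_region=panel,
            seed=_derived_seed(plan.seed, 11, sp_i, day, se_i, tr_i, rep),
        )
        cube = generate_scene(
            m, meta, scene_shape, plant_factor=plant_factor, as_counts=as_counts
        )
        yield cube, meta
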