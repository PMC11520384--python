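"""Raw scenes to analysis-ready observations.

Empirical line method (ELM) calibration against a white Teflon panel,
NDVI-style green-pixel filtering, green-pixel counting (the growth
indicator), and spatial binning of plant pixels into k x k block means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Tuple

import numpy as np
import pandas as pd

from .cube_io import HyperCube, Rect, Units, WavelengthAxis

__all__ = [
    "PixelMask",
    "BinnedObservationSet",
    "GreenFilterParams",
    "elm_calibrate",
    "green_mask",
    "count_green_pixels",
    "spatial_bin",
    "REFLECTANCE_FLAG_CEILING",
]

# calibrated reflectance above this is physically suspect (specular/noise)
REFLECTANCE_FLAG_CEILING = 1.5


@dataclass
class PixelMask:
    """Boolean pixel selection with its provenance."""

    values: np.ndarray
    provenance: str = "manual"
    empty_warning: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("mask must be 2-D rows x cols")

    @property
    def count(self) -> int:
        return int(self.values.sum())


def elm_calibrate(
    raw: HyperCube,
    panel_region: Rect,
    panel_reflectance: float | np.ndarray = 0.99,
) -> HyperCube:
    """One-point empirical line calibration against the white panel.

    Per band b the gain is panel_reflectance_b / mean(panel counts in b);
    reflectance = raw counts x gain. Zero dark signal is assumed, so the
    calibrated panel mean equals panel_reflectance by construction, and the
    output is invariant to rescaling all counts. Output is clamped at 0;
    values above 1.5 are permitted (specular highlights / noise).
    """
    if raw.units != Units.raw_counts:
        raise ValueError("elm_calibrate expects a cube in raw counts")
    r0, r1, c0, c1 = panel_region
    if not (0 <= r0 < r1 <= raw.n_rows and 0 <= c0 < c1 <= raw.n_cols):
        raise ValueError(f"panel_region {panel_region} invalid for cube {raw.shape[:2]}")
    panel = raw.data[r0:r1, c0:c1].reshape(-1, raw.axis.n_bands)
    panel_mean = panel.mean(axis=0)
    bad = np.flatnonzero(panel_mean <= 0)
    if bad.size:
        nm = raw.axis.wavelengths_nm[bad[0]]
        raise ValueError(
            f"panel signal non-positive in band {bad[0]} ({nm:.1f} nm): dark or saturated panel"
        )
    target = np.broadcast_to(np.asarray(panel_reflectance, dtype=float), panel_mean.shape)
    gain = target / panel_mean
    data = np.clip(raw.data * gain, 0.0, None)
    return HyperCube(data, raw.axis, Units.reflectance)


@dataclass
class GreenFilterParams:
    """NDVI-style vegetation filter: (NIR - red)/(NIR + red) >= ndvi_min and
    mean NIR reflectance >= bright_min. Window bounds in nm. The coleus
    default lowers ndvi_min because reddish leaves depress red/NIR contrast.
    """

    red_window: Tuple[float, float] = (660.0, 680.0)
    nir_window: Tuple[float, float] = (780.0, 800.0)
    ndvi_min: float = 0.5
    bright_min: float = 0.15

    @classmethod
    def for_species(cls, species: str) -> "GreenFilterParams":
        if species == "coleus":
            return cls(ndvi_min=0.2)
        return cls()


def green_mask(
    cube: HyperCube,
    params: GreenFilterParams | None = None,
    panel_region: Rect | None = None,
) -> PixelMask:
    """Radiometric filter keeping leaf pixels, excluding background and panel."""
    if cube.units != Units.reflectance:
        raise ValueError("green_mask expects a reflectance cube")
    params = params or GreenFilterParams()
    axis = cube.axis
    red_sel = axis.window(*params.red_window)
    nir_sel = axis.window(*params.nir_window)
    if not red_sel.any() or not nir_sel.any():
        raise ValueError("red/NIR windows select no bands on this axis")
    red = cube.data[:, :, red_sel].mean(axis=2)
    nir = cube.data[:, :, nir_sel].mean(axis=2)
    denom = nir + red
    with np.errstate(divide="ignore", invalid="ignore"):
        ndvi = np.where(denom > 0, (nir - red) / denom, 0.0)
    mask = (ndvi >= params.ndvi_min) & (nir >= params.bright_min)
    if panel_region is not None:
        r0, r1, c0, c1 = panel_region
        mask[r0:r1, c0:c1] = False
    return PixelMask(mask, provenance="green_filter", empty_warning=not mask.any())


def count_green_pixels(mask: PixelMask) -> int:
    """Number of retained leaf pixels — the plant growth indicator."""
    return mask.count


@dataclass
class BinnedObservationSet:
    """Observations from non-overlapping k x k block means of masked pixels."""

    spectra: np.ndarray  # n_obs x n_bands
    bin_factor: int
    block_coords: np.ndarray  # n_obs x 2 block origins (row, col)
    valid_counts: np.ndarray  # masked pixels averaged per observation
    axis: WavelengthAxis

    @property
    def n_obs(self) -> int:
        return int(self.spectra.shape[0])

    def to_frame(self, **metadata) -> pd.DataFrame:
        """One row per observation: metadata columns then per-band columns."""
        cols = {k: v for k, v in metadata.items()}
        cols["bin_factor"] = self.bin_factor
        cols["valid_count"] = self.valid_counts
        frame = pd.DataFrame(cols, index=range(self.n_obs))
        bands = pd.DataFrame(
            self.spectra,
            columns=[f"b{w:.1f}" for w in self.axis.wavelengths_nm],
            index=frame.index,
        )
        return pd.concat([frame, bands], axis=1)


def spatial_bin(cube: HyperCube, mask: PixelMask, k: int) -> BinnedObservationSet:
    """Average masked pixels over a k x k tiling.

    Tiles are anchored at the mask's bounding-box origin; a tile yields one
    observation (the per-band mean over its masked pixels) when at least
    ceil(k^2 / 2) of its pixels are masked, which keeps edge tiles but rejects
    blocks dominated by background. k=1 returns each masked pixel unchanged.
    """
    if k < 1:
        raise ValueError(f"bin factor must be >= 1, got {k}")
    m = mask.values
    if m.shape != cube.shape[:2]:
        raise ValueError("mask shape does not match cube")
    if not m.any():
        empty = np.empty((0, cube.axis.n_bands))
        return BinnedObservationSet(empty, k, np.empty((0, 2), int), np.empty(0, int), cube.axis)

    rows_any = np.flatnonzero(m.any(axis=1))
    cols_any = np.flatnonzero(m.any(axis=0))
    r_origin, c_origin = rows_any[0], cols_any[0]
    r_stop, c_stop = rows_any[-1] + 1, cols_any[-1] + 1

    if k == 1:
        rr, cc = np.nonzero(m)
        return BinnedObservationSet(
            cube.data[rr, cc].astype(float),
            1,
            np.column_stack([rr, cc]),
            np.ones(rr.size, dtype=int),
            cube.axis,
        )

    min_valid = math.ceil(k * k / 2)
    spectra, coords, counts = [], [], []
    for r in range(r_origin, r_stop, k):
        for c in range(c_origin, c_stop, k):
            tile_mask = m[r : r + k, c : c + k]
            n_valid = int(tile_mask.sum())
            if n_valid < min_valid:
                continue
            tile = cube.data[r : r + k, c : c + k]
            spectra.append(tile[tile_mask].mean(axis=0))
            coords.append((r, c))
            counts.append(n_valid)
    if spectra:
        out = np.asarray(spectra, dtype=float)
    else:
        out = np.empty((0, cube.axis.n_bands))
    return BinnedObservationSet(
        out, k, np.asarray(coords, int).reshape(-1, 2), np.asarray(counts, int), cube.axis
    )
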