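"""Radiometric repeatability and per-band diurnal/stress comparisons.

Radiometric repeatability of a spectral band over m repeated acquisitions is

    repeatability = 100 - (R_max - R_min) * 100 / R_mean

where R_max, R_min, R_mean are taken across the acquisitions' mean
reflectances in that band. 100 means perfectly repeatable; the statistic is
unbounded below (a range exceeding the mean goes negative).

Band-wise comparisons between two matched acquisition sets (midnight vs noon,
infested vs control) are expressed as per-band mean ratios and looped paired
t-tests over the acquisition pairs, reported without multiplicity correction
(each band is judged at the plain per-band alpha); a Benjamini-Hochberg
adjusted column is available but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cube_io import HyperCube, WavelengthAxis
from .preprocess import PixelMask

__all__ = [
    "ProfileSet",
    "RepeatabilityProfile",
    "BandTestResult",
    "mean_profile",
    "pooled_profile",
    "radiometric_repeatability",
    "band_ratio_profile",
    "paired_band_ttests",
]

DEFAULT_PIXEL_SAMPLE = 1200


@dataclass
class ProfileSet:
    """m x n_bands matrix of per-acquisition mean reflectance profiles."""

    profiles: np.ndarray
    axis: WavelengthAxis
    labels: Sequence[str] | None = None

    def __post_init__(self):
        self.profiles = np.atleast_2d(np.asarray(self.profiles, dtype=float))
        if self.profiles.shape[1] != self.axis.n_bands:
            raise ValueError("profile width must match the band axis")
        if np.any(self.profiles < 0):
            raise ValueError("reflectance profiles must be nonnegative")

    @property
    def n_acquisitions(self) -> int:
        return int(self.profiles.shape[0])


def mean_profile(
    cube: HyperCube,
    mask: PixelMask,
    n_pixels: int = DEFAULT_PIXEL_SAMPLE,
    seed: int | None = None,
) -> np.ndarray:
    """Mean spectrum of a fixed-size random sample of masked pixels.

    Sampling a fixed pixel count per acquisition keeps growing plants from
    contributing disproportionately many pixels. If fewer than n_pixels are
    masked, all masked pixels are used.
    """
    rr, cc = np.nonzero(mask.values)
    if rr.size == 0:
        raise ValueError("cannot build a profile from an empty mask")
    if n_pixels < rr.size:
        idx = np.random.default_rng(seed).choice(rr.size, size=n_pixels, replace=False)
        rr, cc = rr[idx], cc[idx]
    return cube.data[rr, cc].mean(axis=0)


def pooled_profile(
    cubes: Sequence[HyperCube],
    masks: Sequence[PixelMask],
    n_pixels: int = DEFAULT_PIXEL_SAMPLE,
    seed: int | None = None,
) -> np.ndarray:
    """Mean spectrum of a fixed-size random sample pooled across replicates.

    All masked pixels of the given cubes (e.g. the eight replicate plants of
    one day x session x treatment combination) are pooled and a fixed number
    sampled without replacement, so every combination contributes equally
    many pixels regardless of plant size.
    """
    stacks = [c.data[m.values] for c, m in zip(cubes, masks)]
    pixels = np.vstack(stacks)
    if pixels.shape[0] == 0:
        raise ValueError("no masked pixels to pool")
    if n_pixels < pixels.shape[0]:
        idx = np.random.default_rng(seed).choice(pixels.shape[0], size=n_pixels, replace=False)
        pixels = pixels[idx]
    return pixels.mean(axis=0)


@dataclass
class RepeatabilityProfile:
    """Per-band repeatability in percent (<= 100; unbounded below)."""

    values: np.ndarray
    axis: WavelengthAxis
    undefined: np.ndarray  # bands whose mean reflectance was zero

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "band_nm": self.axis.wavelengths_nm,
                "repeatability_pct": self.values,
                "undefined": self.undefined,
            }
        )


def radiometric_repeatability(profiles: ProfileSet) -> RepeatabilityProfile:
    """Max-min range as a percentage of the mean, subtracted from 100, per band."""
    if profiles.n_acquisitions < 2:
        raise ValueError("repeatability needs at least two acquisitions")
    p = profiles.profiles
    band_mean = p.mean(axis=0)
    band_range = p.max(axis=0) - p.min(axis=0)
    undefined = band_mean <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        values = 100.0 - band_range * 100.0 / band_mean
    values = np.where(undefined, np.nan, values)
    return RepeatabilityProfile(values, profiles.axis, undefined)


def band_ratio_profile(a: ProfileSet, b: ProfileSet) -> np.ndarray:
    """Per-band ratio mean_a / mean_b; 1 means no average effect.

    Bands where b has zero mean are returned as NaN (undefined ratio).
    """
    if a.axis != b.axis:
        raise ValueError("profile sets must share the band axis")
    num = a.profiles.mean(axis=0)
    den = b.profiles.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(den > 0, num / den, np.nan)
    return ratio


@dataclass
class BandTestResult:
    """Looped per-band paired t-test between two matched acquisition sets."""

    axis: WavelengthAxis
    ratio: np.ndarray  # mean_a / mean_b per band
    t: np.ndarray
    p: np.ndarray
    df: int
    n_pairs: int
    alpha: float = 0.05
    p_adjusted: np.ndarray | None = None  # BH-adjusted, only if requested

    @property
    def undefined(self) -> np.ndarray:
        """Bands with zero-variance differences (p cannot be computed)."""
        return np.isnan(self.p)

    @property
    def significant(self) -> np.ndarray:
        p = self.p_adjusted if self.p_adjusted is not None else self.p
        return ~np.isnan(p) & (p < self.alpha)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "band_nm": self.axis.wavelengths_nm,
                "ratio": self.ratio,
                "t": self.t,
                "df": self.df,
                "p": self.p,
                "significant": self.significant,
            }
        )
        if self.p_adjusted is not None:
            frame["p_adjusted"] = self.p_adjusted
        return frame


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values; NaNs pass through."""
    adjusted = np.full_like(p, np.nan)
    finite = ~np.isnan(p)
    pv = p[finite]
    m = pv.size
    if m == 0:
        return adjusted
    order = np.argsort(pv)
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    adjusted[finite] = out
    return adjusted


def paired_band_ttests(
    a: ProfileSet,
    b: ProfileSet,
    alpha: float = 0.05,
    adjust: bool = False,
) -> BandTestResult:
    """Two-sided paired t-test in every band over matched acquisition pairs.

    Rows of `a` and `b` are paired (e.g. midnight and noon of the same day);
    df = n_pairs - 1. Bands whose paired differences have zero variance get
    NaN t and p and are flagged undefined rather than silently significant.
    """
    if a.axis != b.axis:
        raise ValueError("profile sets must share the band axis")
    if a.n_acquisitions != b.n_acquisitions:
        raise ValueError("paired test needs equally many acquisitions in each set")
    n = a.n_acquisitions
    if n < 2:
        raise ValueError("paired test needs at least two pairs")

    diffs = a.profiles - b.profiles
    zero_var = np.isclose(diffs.std(axis=0), 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_rel(a.profiles, b.profiles, axis=0)
    t = np.where(zero_var, np.nan, res.statistic)
    p = np.where(zero_var, np.nan, res.pvalue)

    result = BandTestResult(
        axis=a.axis,
        ratio=band_ratio_profile(a, b),
        t=t,
        p=p,
        df=n - 1,
        n_pairs=n,
        alpha=alpha,
    )
    if adjust:
        result.p_adjusted = _benjamini_hochberg(p)
    return result
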