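"""Hyperspectral cube I/O and band-axis conventions.

Cubes are stored as ENVI header (.hdr) plus a raw binary file. The default
layout is band-interleaved-by-pixel (BIP, all bands of a pixel contiguous),
32-bit little-endian floats; BIL and BSQ are accepted on read. Scene metadata
(species, treatment, day, session, replicate, white-panel region, seed) is
carried as extra key-value entries in the header.

Conventions used throughout the package: arrays are rows x cols x bands,
0-based and row-major; rectangular regions are half-open
(row_start, row_stop, col_start, col_stop).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Tuple

import numpy as np

__all__ = [
    "WavelengthAxis",
    "Units",
    "HyperCube",
    "SceneMetadata",
    "CubeIOError",
    "CorruptFileError",
    "UnsupportedFormatError",
    "InvalidAxisError",
    "make_band_axis",
    "band_index",
    "read_cube",
    "write_cube",
    "DEFAULT_START_NM",
    "DEFAULT_END_NM",
    "DEFAULT_N_BANDS",
]

# Camera band axis of the study: 150 bands spanning 380-1,015 nm
# (nominal ~4.2 nm sampling; exact spacing 635/149).
DEFAULT_START_NM = 380.0
DEFAULT_END_NM = 1015.0
DEFAULT_N_BANDS = 150


class CubeIOError(Exception):
    """Base error for cube reading/writing."""


class CorruptFileError(CubeIOError):
    """Header and binary payload are inconsistent."""


class UnsupportedFormatError(CubeIOError):
    """Interleave or data type we do not handle."""


class InvalidAxisError(ValueError):
    """Degenerate wavelength-axis request."""


@dataclass(frozen=True)
class WavelengthAxis:
    """Ordered band centers in nanometres."""

    wavelengths_nm: np.ndarray

    def __post_init__(self):
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        if wl.ndim != 1 or wl.size < 2:
            raise InvalidAxisError("axis needs at least two band centers")
        if not np.all(np.diff(wl) > 0):
            raise InvalidAxisError("band centers must be strictly increasing")
        object.__setattr__(self, "wavelengths_nm", wl)

    @property
    def n_bands(self) -> int:
        return int(self.wavelengths_nm.size)

    @property
    def spacing_nm(self) -> float:
        return float(np.mean(np.diff(self.wavelengths_nm)))

    def window(self, start_nm: float, stop_nm: float) -> np.ndarray:
        """Boolean selector for band centers in [start_nm, stop_nm]."""
        wl = self.wavelengths_nm
        return (wl >= start_nm) & (wl <= stop_nm)

    def __eq__(self, other) -> bool:
        if not isinstance(other, WavelengthAxis):
            return NotImplemented
        return np.array_equal(self.wavelengths_nm, other.wavelengths_nm)

    def __len__(self) -> int:
        return self.n_bands


class Units(str, Enum):
    raw_counts = "raw_counts"
    reflectance = "reflectance"


def make_band_axis(
    start_nm: float = DEFAULT_START_NM,
    end_nm: float = DEFAULT_END_NM,
    n_bands: int = DEFAULT_N_BANDS,
) -> WavelengthAxis:
    """Evenly spaced band centers with first = start_nm and last = end_nm."""
    if n_bands < 2:
        raise InvalidAxisError(f"n_bands must be >= 2, got {n_bands}")
    if not end_nm > start_nm:
        raise InvalidAxisError(f"need end_nm > start_nm, got [{start_nm}, {end_nm}]")
    return WavelengthAxis(np.linspace(start_nm, end_nm, n_bands))


def band_index(axis: WavelengthAxis, target_nm: float) -> int:
    """0-based index of the band center nearest target_nm.

    Ties break toward the lower index. Targets more than one band spacing
    outside the axis raise ValueError.
    """
    wl = axis.wavelengths_nm
    spacing = axis.spacing_nm
    if target_nm < wl[0] - spacing or target_nm > wl[-1] + spacing:
        raise ValueError(
            f"target {target_nm} nm outside axis range "
            f"[{wl[0] - spacing}, {wl[-1] + spacing}]"
        )
    # argmin returns the first minimiser -> lower index on ties
    return int(np.argmin(np.abs(wl - target_nm)))


Rect = Tuple[int, int, int, int]  # half-open (row_start, row_stop, col_start, col_stop)


@dataclass
class HyperCube:
    """rows x cols x bands image with its wavelength axis and units."""

    data: np.ndarray
    axis: WavelengthAxis
    units: Units = Units.reflectance

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("cube data must be rows x cols x bands")
        if self.data.shape[2] != self.axis.n_bands:
            raise ValueError(
                f"cube has {self.data.shape[2]} bands but axis has {self.axis.n_bands}"
            )
        self.units = Units(self.units)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape

    @property
    def n_rows(self) -> int:
        return self.data.shape[0]

    @property
    def n_cols(self) -> int:
        return self.data.shape[1]


VALID_SPECIES = ("soybean", "coleus")
VALID_TREATMENTS = ("baseline", "control", "low", "high")
VALID_SESSIONS = ("noon", "midnight")


@dataclass
class SceneMetadata:
    """Provenance of one acquisition in the factorial design."""

    species: str
    treatment: str
    day_index: int
    session: str
    replicate: int
    panel_region: Rect
    seed: int = 0

    def __post_init__(self):
        if self.species not in VALID_SPECIES:
            raise ValueError(f"unknown species {self.species!r}")
        if self.treatment not in VALID_TREATMENTS:
            raise ValueError(f"unknown treatment {self.treatment!r}")
        if self.session not in VALID_SESSIONS:
            raise ValueError(f"unknown session {self.session!r}")
        if not 0 <= self.day_index <= 6:
            raise ValueError(f"day_index must be in 0..6, got {self.day_index}")
        if self.treatment == "baseline" and self.day_index != 0:
            raise ValueError("baseline scenes only occur at day_index 0")
        r0, r1, c0, c1 = self.panel_region
        if not (r1 > r0 and c1 > c0):
            raise ValueError(f"panel_region {self.panel_region} is empty")

    def validate_against(self, cube: HyperCube) -> None:
        r0, r1, c0, c1 = self.panel_region
        if r0 < 0 or c0 < 0 or r1 > cube.n_rows or c1 > cube.n_cols:
            raise ValueError(
                f"panel_region {self.panel_region} exceeds cube shape {cube.shape[:2]}"
            )


# ---------------------------------------------------------------------------
# ENVI header + raw binary serialization
# ---------------------------------------------------------------------------

_DTYPE_CODES = {
    1: np.dtype("uint8"),
    2: np.dtype("<i2"),
    3: np.dtype("<i4"),
    4: np.dtype("<f4"),
    5: np.dtype("<f8"),
    12: np.dtype("<u2"),
}
_CODE_FOR_DTYPE = {v: k for k, v in _DTYPE_CODES.items()}

_META_KEYS = ("species", "treatment", "day_index", "session", "replicate", "seed")


def _format_header(cube: HyperCube, meta: SceneMetadata | None) -> str:
    rows, cols, bands = cube.shape
    # repr gives the shortest string that round-trips the double exactly
    wl = ", ".join(repr(float(w)) for w in cube.axis.wavelengths_nm)
    lines = [
        "ENVI",
        "description = {hsistress hyperspectral cube}",
        f"samples = {cols}",
        f"lines = {rows}",
        f"bands = {bands}",
        "header offset = 0",
        "file type = ENVI Standard",
        "data type = 4",
        "interleave = bip",
        "byte order = 0",
        "wavelength units = Nanometers",
        f"wavelength = {{ {wl} }}",
        f"units = {cube.units.value}",
    ]
    if meta is not None:
        for key in _META_KEYS:
            lines.append(f"{key} = {getattr(meta, key)}")
        r0, r1, c0, c1 = meta.panel_region
        lines.append(f"panel_region = {{ {r0}, {r1}, {c0}, {c1} }}")
    return "\n".join(lines) + "\n"


def _parse_header(text: str) -> dict:
    if not text.lstrip().startswith("ENVI"):
        raise CorruptFileError("missing ENVI magic line")
    fields: dict[str, str] = {}
    body = text.split("\n", 1)[1] if "\n" in text else ""
    # join brace-delimited multi-line values before splitting into entries
    pattern = re.compile(r"^\s*([\w #\-]+?)\s*=\s*(\{[^}]*\}|[^\n]*)", re.M | re.S)
    for m in pattern.finditer(body):
        fields[m.group(1).strip().lower()] = m.group(2).strip()
    return fields


def _parse_list(value: str) -> list[str]:
    inner = value.strip()
    if inner.startswith("{"):
        inner = inner[1:-1]
    return [tok.strip() for tok in inner.split(",") if tok.strip()]


def write_cube(cube: HyperCube, path, metadata: SceneMetadata | None = None) -> Path:
    """Write cube as ENVI .hdr + BIP float32 binary; returns the header path."""
    if metadata is not None:
        metadata.validate_against(cube)
    path = Path(path)
    hdr_path = path if path.suffix == ".hdr" else path.with_suffix(path.suffix + ".hdr")
    data_path = hdr_path.with_suffix("")
    if data_path.suffix == "":
        data_path = hdr_path.with_suffix(".bip")
    hdr_path.write_text(_format_header(cube, metadata))
    # BIP: bands vary fastest, i.e. plain C order of rows x cols x bands
    np.ascontiguousarray(cube.data, dtype="<f4").tofile(data_path)
    return hdr_path


def _locate_data_file(hdr_path: Path) -> Path:
    stem = hdr_path.with_suffix("")
    candidates = [stem] if stem.suffix else []
    candidates += [stem.with_suffix(ext) for ext in (".bip", ".bil", ".bsq", ".img", ".dat")]
    for cand in candidates:
        if cand.exists() and cand != hdr_path:
            return cand
    raise CorruptFileError(f"no data file found next to {hdr_path}")


def read_cube(path) -> Tuple[HyperCube, SceneMetadata | None]:
    """Read an ENVI cube written by :func:`write_cube` (or BIL/BSQ variants)."""
    hdr_path = Path(path)
    if hdr_path.suffix != ".hdr":
        hdr_path = hdr_path.with_suffix(hdr_path.suffix + ".hdr")
    fields = _parse_header(hdr_path.read_text())

    try:
        cols = int(fields["samples"])
        rows = int(fields["lines"])
        bands = int(fields["bands"])
        dtype_code = int(fields.get("data type", "4"))
        interleave = fields.get("interleave", "bip").lower()
    except (KeyError, ValueError) as exc:
        raise CorruptFileError(f"bad or missing header field: {exc}") from exc

    if dtype_code not in _DTYPE_CODES:
        raise UnsupportedFormatError(f"ENVI data type {dtype_code} not supported")
    if interleave not in ("bip", "bil", "bsq"):
        raise UnsupportedFormatError(f"interleave {interleave!r} not supported")
    dtype = _DTYPE_CODES[dtype_code]
    if int(fields.get("byte order", "0")) == 1:
        dtype = dtype.newbyteorder(">")

    data_path = _locate_data_file(hdr_path)
    offset = int(fields.get("header offset", "0"))
    expected = rows * cols * bands * dtype.itemsize + offset
    actual = data_path.stat().st_size
    if actual != expected:
        raise CorruptFileError(
            f"{data_path} holds {actual} bytes, header implies {expected}"
        )

    flat = np.fromfile(data_path, dtype=dtype, offset=offset)
    if interleave == "bip":
        data = flat.reshape(rows, cols, bands)
    elif interleave == "bil":
        data = flat.reshape(rows, bands, cols).transpose(0, 2, 1)
    else:  # bsq
        data = flat.reshape(bands, rows, cols).transpose(1, 2, 0)

    if "wavelength" in fields:
        wl = np.array([float(x) for x in _parse_list(fields["wavelength"])])
        if wl.size != bands:
            raise CorruptFileError("wavelength list length does not match bands")
        axis = WavelengthAxis(wl)
    else:
        axis = make_band_axis(n_bands=bands)

    units = Units(fields.get("units", "reflectance"))
    cube = HyperCube(np.ascontiguousarray(data), axis, units)

    meta = None
    if all(k in fields for k in _META_KEYS) and "panel_region" in fields:
        rect = tuple(int(x) for x in _parse_list(fields["panel_region"]))
        meta = SceneMetadata(
            species=fields["species"],
            treatment=fields["treatment"],
            day_index=int(fields["day_index"]),
            session=fields["session"],
            replicate=int(fields["replicate"]),
            panel_region=rect,  # type: ignore[arg-type]
            seed=int(fields["seed"]),
        )
    return cube, meta
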