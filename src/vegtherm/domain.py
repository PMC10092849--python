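"""Grid domain, static field stacks, and pixel masks.

The analysis assumes all inputs are co-gridded on one pixel lattice (the
original products lived on an equal-area grid; regridding happens upstream
and is a precondition here, not a feature).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

#: IGBP-style land-cover codes used by the synthetic scenes and masks.
IGBP_BARREN = 16
KNOWN_LANDCOVER_CODES = frozenset(range(1, 18))

# Mask label codes
MASK_BARE = 0
MASK_DRYLAND = 1
MASK_HUMID = 2


@dataclass(frozen=True)
class GridDomain:
    """A flat pixel lattice with geographic coordinates.

    pixel ids are contiguous from 0; lat/lon are pixel centers in degrees.
    """

    lat: np.ndarray
    lon: np.ndarray
    cell_size: float  # degrees (nominal)

    def __post_init__(self) -> None:
        lat = np.asarray(self.lat, dtype=float)
        lon = np.asarray(self.lon, dtype=float)
        if lat.shape != lon.shape or lat.ndim != 1:
            raise ValueError("lat and lon must be 1-D arrays of equal length")
        if lat.size == 0:
            raise ValueError("empty domain")
        if np.any((lat < -90) | (lat > 90)):
            raise ValueError("lat out of [-90, 90]")
        if np.any((lon < -180) | (lon > 180)):
            raise ValueError("lon out of [-180, 180]")
        object.__setattr__(self, "lat", lat)
        object.__setattr__(self, "lon", lon)

    @property
    def n_pixels(self) -> int:
        return self.lat.size

    @property
    def pixel_id(self) -> np.ndarray:
        return np.arange(self.n_pixels)


# Units every FieldStack array must carry; mismatches are rejected rather
# than silently converted.
FIELD_UNITS: Dict[str, str] = {
    "fvc_mean": "1",
    "theta_mean": "m3 m-3",
    "rs_mean": "W m-2",
    "albedo_mean": "1",
    "vpd_mean": "hPa",
    "precip_annual": "mm yr-1",
    "landcover": "code",
}


@dataclass
class FieldStack:
    """Long-term per-pixel fields: FVC, soil moisture, shortwave radiation,
    albedo, VPD, annual precipitation and land cover, all on one GridDomain."""

    fvc_mean: np.ndarray       # fraction [0, 1]
    theta_mean: np.ndarray     # m3 m-3
    rs_mean: np.ndarray        # W m-2
    albedo_mean: np.ndarray    # fraction [0, 1]
    vpd_mean: np.ndarray       # hPa
    precip_annual: np.ndarray  # mm yr-1
    landcover: np.ndarray      # IGBP-style integer codes
    units: Dict[str, str] = field(default_factory=lambda: dict(FIELD_UNITS))

    def __post_init__(self) -> None:
        n = np.asarray(self.fvc_mean).size
        for name in ("fvc_mean", "theta_mean", "rs_mean", "albedo_mean",
                     "vpd_mean", "precip_annual", "landcover"):
            arr = np.asarray(getattr(self, name))
            if arr.size != n:
                raise ValueError(f"{name} not aligned to the grid ({arr.size} != {n})")
            setattr(self, name, arr)
        for frac in ("fvc_mean", "albedo_mean"):
            v = getattr(self, frac)
            if np.any((v < 0) | (v > 1)):
                raise ValueError(f"{frac} outside [0, 1]")
        if np.any(self.precip_annual < 0):
            raise ValueError("negative annual precipitation")
        for name, expected in FIELD_UNITS.items():
            got = self.units.get(name)
            if got != expected:
                raise ValueError(
                    f"unit mismatch for {name}: expected {expected!r}, got {got!r}"
                )

    @property
    def n_pixels(self) -> int:
        return np.asarray(self.fvc_mean).size


@dataclass
class PixelMask:
    """Boolean per-pixel masks partitioning the surface into bare, dryland
    and humid vegetated pixels (dryland and humid partition the vegetated set)."""

    vegetated: np.ndarray
    dryland: np.ndarray
    humid: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.dryland & self.humid):
            raise ValueError("dryland and humid masks overlap")
        if not np.array_equal(self.dryland | self.humid, self.vegetated):
            raise ValueError("dryland + humid must partition vegetated pixels")

    @property
    def bare(self) -> np.ndarray:
        return ~self.vegetated


def vegetated_mask(
    fvc_mean: np.ndarray,
    landcover: Optional[np.ndarray] = None,
    mode: str = "fvc_zero",
) -> np.ndarray:
    """Flag vegetated pixels.

    mode "fvc_zero" removes pixels with zero long-term mean FVC; mode
    "igbp_bare" removes the barren land-cover class instead.
    """
    fvc = np.asarray(fvc_mean, dtype=float)
    if np.any((fvc < 0) | (fvc > 1)):
        raise ValueError("fvc_mean outside [0, 1]")
    if mode == "fvc_zero":
        return fvc > 0.0
    if mode == "igbp_bare":
        if landcover is None:
            raise ValueError("igbp_bare mode requires land-cover codes")
        lc = np.asarray(landcover)
        unknown = set(np.unique(lc)) - KNOWN_LANDCOVER_CODES
        if unknown:
            raise ValueError(f"unknown land-cover code(s): {sorted(unknown)}")
        return lc != IGBP_BARREN
    raise ValueError(f"unknown mode {mode!r}")


def dryland_mask(
    precip_annual: np.ndarray,
    threshold: float = 500.0,
    vegetated: Optional[np.ndarray] = None,
) -> PixelMask:
    """Split vegetated pixels into dryland (< threshold mm/yr, strictly)
    and humid (>= threshold).  Pixels exactly at the threshold are humid."""
    precip = np.asarray(precip_annual, dtype=float)
    if not np.all(np.isfinite(precip)):
        raise ValueError("precipitation must be finite")
    if np.any(precip < 0):
        raise ValueError("negative annual precipitation")
    if vegetated is None:
        vegetated = np.ones(precip.shape, dtype=bool)
    vegetated = np.asarray(vegetated, dtype=bool)
    dry = vegetated & (precip < threshold)
    humid = vegetated & ~dry
    return PixelMask(vegetated=vegetated, dryland=dry, humid=humid)
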