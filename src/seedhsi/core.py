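"""Hyperspectral cube handling: calibration, band subsetting, seed masking,
and per-seed mean-spectrum extraction.

The cube layout is ``(row, col, band)`` with 0-based coordinates and the
origin at the top-left.  Wavelengths are band centres in nanometres and must
be strictly increasing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

__all__ = [
    "HyperspectralCube",
    "CalibrationSet",
    "SeedMask",
    "SpectralTable",
    "DegenerateReferenceError",
    "calibrate_cube",
    "subset_wavelengths",
    "nearest_band",
    "segment_seeds",
    "mean_spectra",
]


class DegenerateReferenceError(ValueError):
    """White and dark references coincide on at least one voxel."""


@dataclass
class HyperspectralCube:
    """A reflectance cube ``(height, width, bands)`` plus its wavelength axis.

    Parameters
    ----------
    data : ndarray
        Reflectance values, nominally in ``[0, 1]`` after calibration.
    wavelengths : ndarray
        Band centres in nm, strictly increasing, one per band.
    """

    data: np.ndarray
    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.wavelengths = np.asarray(self.wavelengths, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"cube must be 3-D (H, W, B); got shape {self.data.shape}")
        if self.wavelengths.ndim != 1 or len(self.wavelengths) != self.data.shape[2]:
            raise ValueError(
                f"wavelength vector length {self.wavelengths.shape} does not match "
                f"{self.data.shape[2]} bands"
            )
        if len(self.wavelengths) > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]


@dataclass
class CalibrationSet:
    """Raw intensity cube plus white-board and dark-current reference cubes."""

    raw: np.ndarray
    white: np.ndarray
    dark: np.ndarray
    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=np.float64)
        self.white = np.asarray(self.white, dtype=np.float64)
        self.dark = np.asarray(self.dark, dtype=np.float64)
        self.wavelengths = np.asarray(self.wavelengths, dtype=np.float64)
        if not (self.raw.shape == self.white.shape == self.dark.shape):
            raise ValueError(
                f"raw/white/dark shapes differ: {self.raw.shape}, "
                f"{self.white.shape}, {self.dark.shape}"
            )


@dataclass
class SeedMask:
    """Integer-labelled seed instance image: 0 = background, k >= 1 = seed k."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label image must be 2-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("label image must be integer-typed")
        if self.labels.min() < 0:
            raise ValueError("labels must be nonnegative")

    @property
    def n_seeds(self) -> int:
        m = int(self.labels.max())
        return m

    def instance_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]


@dataclass
class SpectralTable:
    """Per-seed mean spectra: one row per seed instance."""

    spectra: np.ndarray
    wavelengths: np.ndarray
    seed_ids: np.ndarray
    class_labels: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.spectra = np.atleast_2d(np.asarray(self.spectra, dtype=np.float64))
        self.wavelengths = np.asarray(self.wavelengths, dtype=np.float64)
        self.seed_ids = np.asarray(self.seed_ids)
        if self.spectra.size and self.spectra.shape[1] != len(self.wavelengths):
            raise ValueError("spectra column count must equal wavelength count")
        if len(self.seed_ids) != self.spectra.shape[0] and self.spectra.size:
            raise ValueError("one seed id per spectrum row required")

    @property
    def n_seeds(self) -> int:
        return self.spectra.shape[0] if self.spectra.size else 0


def calibrate_cube(cal: CalibrationSet) -> HyperspectralCube:
    """Convert raw intensities to reflectance against white/dark references.

    Every voxel becomes ``(raw - dark) / (white - dark)``.  The wavelength
    vector is passed through unchanged.

    Raises
    ------
    DegenerateReferenceError
        If ``white == dark`` on any voxel.
    """
    denom = cal.white - cal.dark
    if np.any(denom == 0):
        n_bad = int(np.count_nonzero(denom == 0))
        raise DegenerateReferenceError(
            f"white and dark references coincide on {n_bad} voxel(s)"
        )
    data = (cal.raw - cal.dark) / denom
    return HyperspectralCube(data=data, wavelengths=cal.wavelengths)


def subset_wavelengths(
    cube: HyperspectralCube, lo_nm: float, hi_nm: float
) -> HyperspectralCube:
    """Keep only bands with ``lo_nm <= wavelength <= hi_nm`` (order preserved)."""
    if lo_nm >= hi_nm:
        raise ValueError(f"lo_nm ({lo_nm}) must be < hi_nm ({hi_nm})")
    keep = (cube.wavelengths >= lo_nm) & (cube.wavelengths <= hi_nm)
    if not keep.any():
        raise ValueError(
            f"no bands in [{lo_nm}, {hi_nm}] nm; cube spans "
            f"[{cube.wavelengths[0]}, {cube.wavelengths[-1]}] nm"
        )
    return HyperspectralCube(
        data=cube.data[:, :, keep], wavelengths=cube.wavelengths[keep]
    )


def nearest_band(wavelengths: np.ndarray, target_nm: float) -> int:
    """Index of the band closest to ``target_nm``; ties go to the lower band."""
    wavelengths = np.asarray(wavelengths, dtype=np.float64)
    dist = np.abs(wavelengths - target_nm)
    # argmin returns the first (lower) index on exact ties
    return int(np.argmin(dist))


# 4-connectivity: seed instances must not merge across diagonals
_STRUCT_4 = ndimage.generate_binary_structure(2, 1)


def segment_seeds(
    cube: HyperspectralCube,
    band_nm: float,
    threshold: float | None = None,
    min_area: int = 50,
) -> SeedMask:
    """Threshold a single-band grey image into labelled seed instances.

    Pixels brighter than ``threshold`` at the band nearest ``band_nm`` are
    foreground.  When ``threshold`` is None, Otsu's method on that band image
    is used.  Connected components (4-connected) smaller than ``min_area``
    pixels are discarded; survivors are relabelled ``1..n``.
    """
    band = nearest_band(cube.wavelengths, band_nm)
    img = cube.data[:, :, band]
    if threshold is None:
        threshold = float(threshold_otsu(img))
    fg = img > threshold
    if not fg.any():
        warnings.warn("no foreground pixels above threshold; zero-seed mask")
        return SeedMask(labels=np.zeros(img.shape, dtype=np.int32))
    labels, n = ndimage.label(fg, structure=_STRUCT_4)
    if min_area > 1 and n:
        areas = np.bincount(labels.ravel(), minlength=n + 1)
        small = np.flatnonzero(areas < min_area)
        small = small[small > 0]
        if small.size:
            labels[np.isin(labels, small)] = 0
    # relabel survivors consecutively
    ids = np.unique(labels)
    ids = ids[ids > 0]
    remap = np.zeros(int(labels.max()) + 1, dtype=np.int32)
    remap[ids] = np.arange(1, len(ids) + 1, dtype=np.int32)
    out = remap[labels]
    if len(ids) == 0:
        warnings.warn("all components below min_area; zero-seed mask")
    return SeedMask(labels=out)


def mean_spectra(
    cube: HyperspectralCube,
    mask: SeedMask,
    class_labels: np.ndarray | None = None,
) -> SpectralTable:
    """Average the reflectance of every seed instance over its mask pixels.

    Row ``k`` of the result is the per-band arithmetic mean over the pixels of
    instance ``k``.
    """
    if mask.labels.shape != cube.data.shape[:2]:
        raise ValueError(
            f"mask shape {mask.labels.shape} does not match cube spatial shape "
            f"{cube.data.shape[:2]}"
        )
    ids = mask.instance_ids()
    if ids.size == 0:
        return SpectralTable(
            spectra=np.empty((0, cube.n_bands)),
            wavelengths=cube.wavelengths,
            seed_ids=np.empty(0, dtype=int),
            class_labels=class_labels,
        )
    rows = np.empty((len(ids), cube.n_bands))
    for i, k in enumerate(ids):
        sel = mask.labels == k
        if not sel.any():
            raise ValueError(f"seed instance {k} has no pixels")
        rows[i] = cube.data[sel].mean(axis=0)
    return SpectralTable(
        spectra=rows,
        wavelengths=cube.wavelengths,
        seed_ids=ids,
        class_labels=class_labels,
    )
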