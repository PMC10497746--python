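"""Synthetic inputs for the whole pipeline: calibration triplets with
elliptical seed scenes of known class structure, and bud masks of known
centerline length.

Scenes place non-touching elliptical seeds on a grid over a dark
background.  Per-pixel spectra are a smooth class-mean curve (sum of
Gaussian bumps over wavelength) plus a small smooth per-seed deviation and
white pixel noise; the nonviable class is offset upward, either uniformly
or only at designated informative bands.  Raw/white/dark frames are
synthesised so that reflectance calibration recovers the intended
reflectance exactly (bit-for-bit in the noise-free limit).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_dilation
from skimage.morphology import disk

from .budlen import BudMask
from .core import CalibrationSet, HyperspectralCube, SeedMask

__all__ = [
    "SceneSpec",
    "SeedScene",
    "BudSpec",
    "generate_seed_scene",
    "generate_bud_mask",
]

# zero dark current and a power-of-two gain make (raw - dark)/(white - dark)
# reproduce the reflectance with zero floating-point error
_DARK_LEVEL = 0.0
_GAIN = 4096.0


@dataclass
class SceneSpec:
    n_seeds: int = 96
    grid: tuple[int, int] | None = None  # (rows, cols); auto if None
    image_size: tuple[int, int] = (512, 512)
    n_bands: int = 64
    wavelength_range: tuple[float, float] = (420.0, 1000.0)
    viable_fraction: float = 0.5
    class_offset: float = 0.05
    informative_bands: tuple[int, ...] | None = None
    seed_deviation_sd: float = 0.005
    noise_sd: float = 0.01
    background_reflectance: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.viable_fraction <= 1.0:
            raise ValueError("viable_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.informative_bands is not None:
            bad = [b for b in self.informative_bands if not 0 <= b < self.n_bands]
            if bad:
                raise ValueError(f"informative bands out of range: {bad}")


@dataclass
class SeedScene:
    calibration: CalibrationSet
    mask: SeedMask
    classes: dict[int, int]  # seed_id -> 1 (viable) / 2 (nonviable)
    class_spectra: np.ndarray  # (2, B): row 0 viable, row 1 nonviable
    reflectance: HyperspectralCube
    spec: SceneSpec = field(repr=False, default=None)


def _smooth_curve(rng: np.random.Generator, wavelengths: np.ndarray) -> np.ndarray:
    """Sum of 3-5 Gaussian bumps, scaled into a plausible reflectance range."""
    lo, hi = wavelengths[0], wavelengths[-1]
    n_bumps = int(rng.integers(3, 6))
    curve = np.zeros_like(wavelengths)
    for _ in range(n_bumps):
        center = rng.uniform(lo, hi)
        width = rng.uniform(0.1, 0.35) * (hi - lo)
        amp = rng.uniform(0.1, 0.3)
        curve += amp * np.exp(-0.5 * ((wavelengths - center) / width) ** 2)
    return 0.2 + 0.5 * (curve - curve.min()) / max(np.ptp(curve), 1e-9)


def _auto_grid(n: int, h: int, w: int) -> tuple[int, int]:
    rows = max(int(np.floor(np.sqrt(n * h / w))), 1)
    cols = int(np.ceil(n / rows))
    while rows * cols < n:
        cols += 1
    return rows, cols


def generate_seed_scene(spec: SceneSpec) -> SeedScene:
    """Build a labelled scene plus the calibration frames that produce it."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    rows, cols = spec.grid if spec.grid is not None else _auto_grid(spec.n_seeds, h, w)
    if rows * cols < spec.n_seeds:
        raise ValueError(
            f"grid {rows}x{cols} cannot fit {spec.n_seeds} seeds"
        )
    cell_h, cell_w = h // rows, w // cols
    if min(cell_h, cell_w) < 4:
        raise ValueError("image too small for the requested layout")

    wavelengths = np.linspace(*spec.wavelength_range, spec.n_bands)
    viable = _smooth_curve(rng, wavelengths)
    if spec.informative_bands is None:
        offset = np.full(spec.n_bands, spec.class_offset)
    else:
        # narrow bumps centred on the informative bands keep the offset
        # smooth but localised
        offset = np.zeros(spec.n_bands)
        idx = np.arange(spec.n_bands)
        for b in spec.informative_bands:
            offset += spec.class_offset * np.exp(-0.5 * ((idx - b) / 0.7) ** 2)
    nonviable = viable + offset
    class_spectra = np.stack([viable, nonviable])

    # class labels in acquisition (raster) order, exact viable fraction
    n_viable = int(round(spec.viable_fraction * spec.n_seeds))
    label_pool = np.array([1] * n_viable + [2] * (spec.n_seeds - n_viable))
    rng.shuffle(label_pool)

    labels = np.zeros((h, w), dtype=np.int32)
    refl = np.full((h, w, spec.n_bands), spec.background_reflectance)
    classes: dict[int, int] = {}
    yy, xx = np.mgrid[0:h, 0:w]
    sid = 0
    for r in range(rows):
        for c in range(cols):
            if sid >= spec.n_seeds:
                break
            sid += 1
            cy = r * cell_h + cell_h / 2 + rng.uniform(-0.05, 0.05) * cell_h
            cx = c * cell_w + cell_w / 2 + rng.uniform(-0.05, 0.05) * cell_w
            ay = rng.uniform(0.28, 0.42) * cell_h
            ax = rng.uniform(0.28, 0.42) * cell_w
            inside = ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0
            labels[inside] = sid
            cls = int(label_pool[sid - 1])
            classes[sid] = cls
            spectrum = class_spectra[cls - 1]
            if spec.seed_deviation_sd > 0:
                dev_rng = rng
                center = dev_rng.uniform(0, spec.n_bands)
                width = dev_rng.uniform(0.2, 0.5) * spec.n_bands
                dev = spec.seed_deviation_sd * dev_rng.standard_normal() * np.exp(
                    -0.5 * ((np.arange(spec.n_bands) - center) / width) ** 2
                )
                spectrum = spectrum + dev
            n_px = int(np.count_nonzero(inside))
            values = spectrum[None, :] + (
                rng.standard_normal((n_px, spec.n_bands)) * spec.noise_sd
                if spec.noise_sd > 0
                else 0.0
            )
            refl[inside] = values

    dark = np.full(refl.shape, _DARK_LEVEL)
    white = np.full(refl.shape, _DARK_LEVEL + _GAIN)
    raw = refl * _GAIN + _DARK_LEVEL
    cal = CalibrationSet(raw=raw, white=white, dark=dark, wavelengths=wavelengths)
    return SeedScene(
        calibration=cal,
        mask=SeedMask(labels=labels),
        classes=classes,
        class_spectra=class_spectra,
        reflectance=HyperspectralCube(data=refl, wavelengths=wavelengths),
        spec=spec,
    )


@dataclass
class BudSpec:
    length_px: float = 100.0
    width_px: int = 5
    curvature: float = 0.0  # total heading change over the centerline, radians
    n_spurs: int = 0
    spur_length_px: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_px < 1:
            raise ValueError("width must be >= 1")
        if self.length_px <= self.width_px:
            raise ValueError("length must exceed width")


_MAX_RETRIES = 20


def _centerline(spec: BudSpec, rng: np.random.Generator) -> np.ndarray:
    """Continuous arc-length-parametrised curve of exact length ``length_px``."""
    ds = 0.25
    n_steps = int(round(spec.length_px / ds))
    theta0 = rng.uniform(0, 2 * np.pi)
    # constant-curvature arc plus a gentle random heading drift
    drift = rng.standard_normal(n_steps) * 0.002
    theta = theta0 + spec.curvature * np.arange(n_steps) / max(n_steps, 1)
    theta = theta + np.cumsum(drift)
    steps = np.stack([np.sin(theta), np.cos(theta)], axis=1) * ds
    pts = np.concatenate([[[0.0, 0.0]], np.cumsum(steps, axis=0)])
    return pts


def _self_intersects(pts: np.ndarray, width: float) -> bool:
    ds = 0.25
    min_sep = int(3 * width / ds) + 4
    sub = pts[:: max(min_sep // 8, 1)]
    for i in range(len(sub)):
        d = np.linalg.norm(sub[i + (min_sep // max(min_sep // 8, 1)) + 1 :] - sub[i],
                           axis=1)
        if (d < width).any():
            return True
    return False


def generate_bud_mask(spec: BudSpec) -> tuple[BudMask, float]:
    """Rasterise a curved strip of known centerline length; returns the mask
    and the exact generating length in pixels.

    A self-intersecting draw at the requested curvature is retried with a
    perturbed seed, a bounded number of times.
    """
    last_err: Exception | None = None
    for attempt in range(_MAX_RETRIES):
        rng = np.random.default_rng(spec.seed + attempt * 7919)
        pts = _centerline(spec, rng)
        if _self_intersects(pts, spec.width_px):
            last_err = ValueError("self-intersecting centerline")
            continue
        margin = spec.width_px + spec.spur_length_px + 4
        shifted = pts - pts.min(axis=0) + margin
        hsize = int(np.ceil(shifted[:, 0].max() + margin))
        wsize = int(np.ceil(shifted[:, 1].max() + margin))
        canvas = np.zeros((hsize, wsize), dtype=bool)
        rr = np.clip(np.round(shifted[:, 0]).astype(int), 0, hsize - 1)
        cc = np.clip(np.round(shifted[:, 1]).astype(int), 0, wsize - 1)
        canvas[rr, cc] = True

        if spec.n_spurs > 0:
            ds = 0.25
            for _ in range(spec.n_spurs):
                i = int(rng.integers(len(pts) // 5, 4 * len(pts) // 5))
                tangent = shifted[min(i + 4, len(pts) - 1)] - shifted[max(i - 4, 0)]
                tnorm = np.linalg.norm(tangent)
                if tnorm == 0:
                    continue
                normal = np.array([-tangent[1], tangent[0]]) / tnorm
                n_sp = int(spec.spur_length_px / ds)
                spur = shifted[i] + normal[None, :] * (np.arange(n_sp)[:, None] * ds)
                sr = np.clip(np.round(spur[:, 0]).astype(int), 0, hsize - 1)
                sc = np.clip(np.round(spur[:, 1]).astype(int), 0, wsize - 1)
                canvas[sr, sc] = True

        radius = max(spec.width_px // 2, 1)
        mask = binary_dilation(canvas, structure=disk(radius))
        return BudMask(image=mask), float(spec.length_px)
    raise RuntimeError(
        f"could not draw a non-self-intersecting centerline in {_MAX_RETRIES} tries"
    ) from last_err
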