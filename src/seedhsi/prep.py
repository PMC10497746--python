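"""Row-wise spectral preprocessing (Savitzky-Golay, SNV) and per-band
z-score standardization of block sets.

Preprocessing order for mean spectra is SG then SNV.  Block standardization
computes its statistics on the training set only, so no information leaks
from held-out data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .blocks import BlockSet

__all__ = [
    "savitzky_golay_smooth",
    "snv_transform",
    "StandardizationStats",
    "standardize_blocks",
    "apply_standardization",
]


def savitzky_golay_smooth(
    spectra: np.ndarray, window: int = 11, polyorder: int = 2
) -> np.ndarray:
    """Savitzky-Golay least-squares polynomial smoothing along each row.

    Edges are handled by fitting a polynomial to the truncated boundary
    window rather than padding with fabricated values.
    """
    spectra = np.atleast_2d(np.asarray(spectra, dtype=np.float64))
    if window % 2 == 0:
        raise ValueError(f"window must be odd; got {window}")
    if window <= polyorder:
        raise ValueError(f"window ({window}) must exceed polyorder ({polyorder})")
    if window > spectra.shape[1]:
        raise ValueError(
            f"window ({window}) exceeds band count ({spectra.shape[1]})"
        )
    return savgol_filter(spectra, window, polyorder, axis=1, mode="interp")


def snv_transform(spectra: np.ndarray) -> np.ndarray:
    """Standard Normal Variate: centre and scale every row to mean 0, sd 1.

    Uses the sample standard deviation (ddof=1).  Constant rows are rejected.
    """
    spectra = np.atleast_2d(np.asarray(spectra, dtype=np.float64))
    mu = spectra.mean(axis=1, keepdims=True)
    sd = spectra.std(axis=1, ddof=1, keepdims=True)
    degenerate = np.flatnonzero(sd.ravel() == 0)
    if degenerate.size:
        raise ValueError(
            f"zero-variance spectrum in row(s) {degenerate.tolist()}; SNV undefined"
        )
    return (spectra - mu) / sd


@dataclass
class StandardizationStats:
    """Per-band mean/sd computed on the training blocks only."""

    mean: np.ndarray  # (K,)
    sd: np.ndarray  # (K,)


_SD_EPS = 1e-12


def _band_stats(data: np.ndarray) -> StandardizationStats:
    # data: (n, s, s, K) -> stats over all pixels of all blocks, per band
    flat = data.reshape(-1, data.shape[-1])
    mean = flat.mean(axis=0)
    sd = flat.std(axis=0)
    degenerate = sd <= _SD_EPS * np.maximum(1.0, np.abs(mean))
    if degenerate.any():
        warnings.warn("zero-sd band(s); clamping sd to epsilon")
        sd = np.where(degenerate, _SD_EPS, sd)
    return StandardizationStats(mean=mean, sd=sd)


def apply_standardization(bs: BlockSet, stats: StandardizationStats) -> BlockSet:
    data = bs.data_array()
    return bs.with_data((data - stats.mean) / stats.sd)


def standardize_blocks(
    train_blocks: BlockSet, other_blocks: BlockSet | None = None
) -> tuple[BlockSet, BlockSet | None, StandardizationStats]:
    """Z-score both block sets with per-band statistics from the training set.

    Statistics are computed on ``train_blocks`` alone and returned for
    persistence; ``other_blocks`` (validation/test) is transformed with the
    same statistics.
    """
    if len(train_blocks) == 0:
        raise ValueError("train_blocks is empty")
    stats = _band_stats(train_blocks.data_array())
    train_std = apply_standardization(train_blocks, stats)
    other_std = (
        apply_standardization(other_blocks, stats) if other_blocks is not None else None
    )
    return train_std, other_std, stats
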