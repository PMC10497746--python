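"""Successive projections algorithm (SPA) for key-wavelength selection.

SPA is a greedy forward search over band columns: starting from a chosen
band, it repeatedly projects all unselected columns onto the orthogonal
complement of the span of the already-selected columns and picks the column
with the largest residual norm, which minimises collinearity in the subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestCentroid

__all__ = ["BandSubset", "spa_select", "choose_subset_size", "RankDeficiencyError"]

_ZERO_TOL = 1e-10


class RankDeficiencyError(ValueError):
    """Residual norms vanished before the requested subset size was reached."""


@dataclass
class BandSubset:
    indices: np.ndarray  # selection order preserved
    wavelengths_nm: np.ndarray | None = None
    criterion_trace: dict = field(default_factory=dict)
    residual_norms: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.indices)


def spa_select(
    spectra: np.ndarray,
    start_band: int,
    k: int,
    wavelengths: np.ndarray | None = None,
) -> BandSubset:
    """Select ``k`` minimally collinear bands by successive projections.

    Deterministic given ``(spectra, start_band, k)``.  The returned indices
    are in selection order; ``residual_norms`` holds the residual norm of
    each pick at the moment of its selection (non-increasing).
    """
    X = np.asarray(spectra, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("spectra must be a 2-D samples x bands matrix")
    n, b = X.shape
    if not (1 <= k <= min(n, b)):
        raise ValueError(f"k must be in [1, min(samples, bands)] = [1, {min(n, b)}]")
    if not (0 <= start_band < b):
        raise ValueError(f"start_band {start_band} out of range [0, {b})")

    residual = X.copy()  # column j = component of X[:, j] orthogonal to span(selected)
    selected = [start_band]
    norms = [float(np.linalg.norm(X[:, start_band]))]
    available = np.ones(b, dtype=bool)
    available[start_band] = False

    for _ in range(k - 1):
        v = residual[:, selected[-1]]
        nv = np.linalg.norm(v)
        if nv < _ZERO_TOL:
            raise RankDeficiencyError(
                f"data rank exhausted after {len(selected)} of {k} bands"
            )
        u = v / nv
        residual -= np.outer(u, u @ residual)  # Gram-Schmidt step
        col_norms = np.linalg.norm(residual, axis=0)
        col_norms[~available] = -1.0
        nxt = int(np.argmax(col_norms))
        if col_norms[nxt] < _ZERO_TOL:
            raise RankDeficiencyError(
                f"data rank exhausted after {len(selected)} of {k} bands"
            )
        selected.append(nxt)
        norms.append(float(col_norms[nxt]))
        available[nxt] = False

    idx = np.array(selected, dtype=int)
    return BandSubset(
        indices=idx,
        wavelengths_nm=None if wavelengths is None else np.asarray(wavelengths)[idx],
        residual_norms=np.array(norms),
    )


def _cv_error(X: np.ndarray, y: np.ndarray, cols: np.ndarray, seed: int) -> float:
    """Stratified 5-fold CV error of a nearest-mean classifier on ``cols``."""
    classes, counts = np.unique(y, return_counts=True)
    n_splits = min(5, int(counts.min()))
    if n_splits < 2:
        raise ValueError("need at least 2 samples per class for cross-validation")
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    err = 0.0
    for tr, te in skf.split(X, y):
        clf = NearestCentroid()
        clf.fit(X[np.ix_(tr, cols)], y[tr])
        err += float(np.mean(clf.predict(X[np.ix_(te, cols)]) != y[te]))
    return err / n_splits


def choose_subset_size(
    spectra: np.ndarray,
    labels: np.ndarray,
    k_range,
    wavelengths: np.ndarray | None = None,
    seed: int = 0,
) -> BandSubset:
    """Pick the SPA subset minimising cross-validated classification error.

    Runs ``spa_select`` over every size in ``k_range`` and every start band,
    scoring each candidate subset with the stratified 5-fold error of a
    nearest-mean classifier; returns the minimiser with its per-size trace.
    Ties break toward the smaller subset, then the lower start band.
    """
    X = np.asarray(spectra, dtype=np.float64)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("labels are degenerate (single class)")
    ks = sorted(set(int(k) for k in k_range))
    if not ks or ks[0] < 1 or ks[-1] > min(X.shape):
        raise ValueError("k_range outside valid subset sizes")
    k_max = ks[-1]

    best = None  # (err, k, start, indices)
    trace: dict[int, float] = {}
    for start in range(X.shape[1]):
        try:
            chain = spa_select(X, start, k_max).indices
        except RankDeficiencyError:
            continue
        for k in ks:
            cols = chain[:k]
            err = _cv_error(X, y, cols, seed)
            if k not in trace or err < trace[k]:
                trace[k] = err
            cand = (err, k, start, cols)
            if best is None or cand[:3] < best[:3]:
                best = cand
    if best is None:
        raise RankDeficiencyError("no start band admits a subset of the requested size")
    _, _, _, cols = best
    return BandSubset(
        indices=np.asarray(cols),
        wavelengths_nm=None if wavelengths is None else np.asarray(wavelengths)[cols],
        criterion_trace=trace,
    )
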