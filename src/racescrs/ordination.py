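"""PCA of conditioned cohorts and loading-window interpretation.

The chemometric justification for carotenoid sorting is that the first
principal axis of the cohort's spectral variance is driven by the carotenoid
resonance bands: the high-|loading| wavenumber windows on PC1 coincide with
the ν1/ν2/ν3 windows.  This module computes the decomposition and extracts
those top-loading windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA as _SKPCA

from .preprocess import ProcessedSpectrum
from .spectral_io import SpectralValidationError


@dataclass
class PCAResult:
    """Mean-centred principal component decomposition of a spectral matrix.

    ``loadings`` has shape (n_points, n_components) with orthonormal columns;
    the sign convention fixes each column's largest-|value| entry positive so
    results are reproducible across backends.
    """

    scores: np.ndarray                 # (n_cells, k)
    loadings: np.ndarray               # (n_points, k)
    explained_variance_ratio: np.ndarray
    mean: np.ndarray
    wavenumbers: np.ndarray
    cell_ids: list[str]

    def reconstruct(self) -> np.ndarray:
        """scores · loadingsᵀ + mean (truncated reconstruction)."""
        return self.scores @ self.loadings.T + self.mean


@dataclass(frozen=True)
class LoadingWindow:
    """A contiguous high-|loading| wavenumber run on one component."""

    component: int
    lo: float
    hi: float
    peak_abs_loading: float

    def overlaps(self, lo: float, hi: float) -> bool:
        return self.lo <= hi and lo <= self.hi


def pca_matrix(matrix: np.ndarray, wavenumbers: np.ndarray,
               n_components: int = 5,
               cell_ids: list[str] | None = None) -> PCAResult:
    """PCA of an (n_cells, n_points) intensity matrix."""
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise SpectralValidationError("PCA needs at least 2 spectra")
    k = min(n_components, X.shape[0], X.shape[1])
    model = _SKPCA(n_components=k, svd_solver="full")
    scores = model.fit_transform(X)
    loadings = model.components_.T.copy()  # (n_points, k)

    # Deterministic sign: largest-|loading| entry of each column positive.
    for j in range(k):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1.0
            scores[:, j] *= -1.0

    ids = cell_ids if cell_ids is not None else [str(i) for i in range(X.shape[0])]
    return PCAResult(
        scores=scores, loadings=loadings,
        explained_variance_ratio=model.explained_variance_ratio_,
        mean=model.mean_, wavenumbers=np.asarray(wavenumbers, dtype=float),
        cell_ids=list(ids))


def pca(processed: list[ProcessedSpectrum], n_components: int = 5,
        exclude_fluorescent: bool = True, calls=None) -> PCAResult:
    """PCA of a conditioned cohort.

    By default fluorescence-dominated cells are excluded (their 20×-amplitude
    background residuals would swamp the first axis); pass ``calls`` from the
    classifier to use its screen, otherwise the ``fluorescence_dominated`` /
    ``low_signal`` preprocessing flags are used.  Set
    ``exclude_fluorescent=False`` to ordinate every cell.
    """
    keep = processed
    if exclude_fluorescent:
        if calls is not None:
            fluor = {c.cell_id for c in calls if c.is_fluorescent}
            keep = [p for p in processed if p.cell_id not in fluor]
        else:
            keep = [p for p in processed if not p.flags]
    if len(keep) < 2:
        raise SpectralValidationError("PCA needs at least 2 spectra")
    X = np.vstack([p.corrected for p in keep])
    return pca_matrix(X, keep[0].wavenumbers, n_components,
                      cell_ids=[p.cell_id for p in keep])


def top_loading_windows(result: PCAResult, component: int = 0,
                        alpha: float = 0.5, merge_gap_points: int = 3,
                        signed: bool = True) -> list[LoadingWindow]:
    """Maximal contiguous runs of high loading on one component.

    With ``signed=True`` (default) a run is where the loading, taken in the
    component's dominant-feature orientation (the deterministic sign
    convention makes the strongest feature positive), satisfies
    ``loading ≥ alpha · max(loading)``: these are the wavenumbers that move
    *with* the axis's dominant chemical signal.  On vector-normalized spectra
    the bands of the complementary population load negatively (closure
    anti-correlation), and ``signed=False`` switches to thresholding
    ``|loading|``, which reports those anti-correlated windows too.

    Runs separated by fewer than ``merge_gap_points`` grid points are merged.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    col = result.loadings[:, component]
    v = col if signed else np.abs(col)
    thresh = alpha * v.max()
    above = v >= thresh
    if not above.any():
        return []

    # Contiguous runs of True.
    idx = np.flatnonzero(above)
    splits = np.flatnonzero(np.diff(idx) > 1) + 1
    runs = [(seg[0], seg[-1]) for seg in np.split(idx, splits)]

    merged = [runs[0]]
    for lo, hi in runs[1:]:
        if lo - merged[-1][1] - 1 < merge_gap_points:
            merged[-1] = (merged[-1][0], hi)
        else:
            merged.append((lo, hi))

    w = result.wavenumbers
    return [LoadingWindow(component=component, lo=float(w[lo]), hi=float(w[hi]),
                          peak_abs_loading=float(v[lo:hi + 1].max()))
            for lo, hi in merged]
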