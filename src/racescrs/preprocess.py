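"""Raw-spectrum conditioning: baseline, noise scale, smoothing, normalization.

Single-cell Raman spectra sit on a smooth broadband background (substrate
coating, cellular autofluorescence).  Classification and ordination operate on
baseline-subtracted, vector-normalized spectra together with a per-spectrum
robust noise scale; this module produces those.

The baseline estimator is asymmetric least squares (ALS): minimise

    Σᵢ wᵢ (yᵢ − bᵢ)² + λ Σ (Δ²b)²,   wᵢ = p if yᵢ > bᵢ else 1 − p,

with p « 0.5, so the smooth curve b hugs the lower envelope of the spectrum
and peaks are left in the residual.  The normal equations are pentadiagonal,
solved with a banded Cholesky factorisation per iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solveh_banded
from scipy.signal import savgol_filter

from .spectral_io import Spectrum, SpectrumSet, SpectralValidationError

FLAG_FLUORESCENCE = "fluorescence_dominated"
FLAG_LOW_SIGNAL = "low_signal"


@dataclass
class PreprocessConfig:
    """Defaults for the conditioning stage.

    λ = 1e5 and p = 0.01 are standard ALS settings for fluorescence-
    contaminated Raman at ~1000-point resolution.  Smoothing is off by
    default (window 0): the ~1 cm⁻¹ marker bands must not be broadened.
    """

    lam: float = 1e5
    p: float = 0.01
    n_iter: int = 10
    smooth_window: int = 0  # 0 disables Savitzky-Golay smoothing
    smooth_poly_order: int = 2
    norm_method: str = "vector"  # "vector" | "max"


@dataclass
class ProcessedSpectrum:
    """A conditioned spectrum ready for classification and PCA.

    ``corrected`` is baseline-subtracted and normalized; ``norm`` is the
    constant dividing the corrected trace, so ``corrected * norm + baseline``
    reproduces the (optionally smoothed) input.
    """

    spectrum: Spectrum                # the raw input (metadata carrier)
    corrected: np.ndarray             # normalized, baseline-subtracted
    baseline: np.ndarray              # estimated background, raw scale
    noise_sigma: float                # robust noise scale, normalized units
    norm: float                       # normalization constant (raw units)
    flags: set = field(default_factory=set)

    @property
    def cell_id(self) -> str:
        return self.spectrum.cell_id

    @property
    def wavenumbers(self) -> np.ndarray:
        return self.spectrum.wavenumbers

    def denormalize(self) -> np.ndarray:
        """Corrected trace back on the raw intensity scale."""
        return self.corrected * self.norm


def estimate_baseline(intensities: np.ndarray, lam: float = 1e5, p: float = 0.01,
                      n_iter: int = 10) -> np.ndarray:
    """Asymmetric-least-squares baseline of one intensity vector."""
    y = np.asarray(intensities, dtype=float)
    if not np.all(np.isfinite(y)):
        raise SpectralValidationError("non-finite intensities")
    if lam <= 0:
        raise ValueError("lam must be > 0")
    if not (0.0 < p < 0.5):
        raise ValueError("p must be in (0, 0.5)")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    n = y.size
    if n < 3:
        return y.copy()

    # lam * D2^T D2 in symmetric banded form (upper form for solveh_banded):
    # stencil rows give diagonals [1, -4, 6, -4, 1] with boundary corrections.
    main = np.full(n, 6.0)
    main[[0, -1]] = 1.0
    main[[1, -2]] = 5.0
    off1 = np.full(n - 1, -4.0)
    off1[[0, -1]] = -2.0
    off2 = np.full(n - 2, 1.0)

    ab = np.zeros((3, n))
    ab[0, 2:] = lam * off2
    ab[1, 1:] = lam * off1
    base_diag = lam * main

    w = np.ones(n)
    b = y.copy()
    for _ in range(n_iter):
        ab[2] = base_diag + w
        b = solveh_banded(ab, w * y, lower=False)
        w_new = np.where(y > b, p, 1.0 - p)
        if np.array_equal(w_new, w):
            break
        w = w_new
    return b


def estimate_noise(corrected: np.ndarray) -> float:
    """Robust noise scale from first differences.

    σ̂ = 1.4826 · median(|Δy − median(Δy)|) / √2 — the MAD of successive
    differences, insensitive to the sparse peaks; exactly scale-equivariant.
    """
    y = np.asarray(corrected, dtype=float)
    if y.size < 16:
        raise SpectralValidationError("noise estimation needs >= 16 points")
    d = np.diff(y)
    return float(1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2.0))


def smooth(intensities: np.ndarray, window_points: int,
           poly_order: int = 2) -> np.ndarray:
    """Savitzky-Golay smoothing; window must be odd and exceed the order."""
    if window_points % 2 == 0:
        raise ValueError("smoothing window must be odd")
    if window_points <= poly_order:
        raise ValueError("smoothing window must exceed the polynomial order")
    return savgol_filter(np.asarray(intensities, dtype=float),
                         window_points, poly_order)


def normalize(corrected: np.ndarray, method: str = "vector"
              ) -> tuple[np.ndarray, float, set]:
    """Normalize a corrected trace; returns (normalized, norm constant, flags).

    ``vector`` divides by the Euclidean norm; ``max`` by the maximum value.
    A trace with no positive signal is flagged ``low_signal`` and left
    unchanged (identity normalization, norm 1).
    """
    y = np.asarray(corrected, dtype=float)
    if method == "vector":
        norm = float(np.linalg.norm(y))
    elif method == "max":
        norm = float(y.max()) if y.size else 0.0
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    if norm <= 0 or np.all(y <= 0):
        return y.copy(), 1.0, {FLAG_LOW_SIGNAL}
    return y / norm, norm, set()


def preprocess_spectrum(spectrum: Spectrum,
                        config: PreprocessConfig | None = None
                        ) -> ProcessedSpectrum:
    """Full conditioning of one raw spectrum.

    Order: optional Savitzky-Golay smoothing → ALS baseline subtraction →
    normalization → robust noise estimate on the normalized trace.
    """
    cfg = config or PreprocessConfig()
    y = spectrum.intensities
    if cfg.smooth_window:
        y = smooth(y, cfg.smooth_window, cfg.smooth_poly_order)
    baseline = estimate_baseline(y, lam=cfg.lam, p=cfg.p, n_iter=cfg.n_iter)
    corrected_raw = y - baseline
    corrected, norm, flags = normalize(corrected_raw, cfg.norm_method)
    noise_sigma = estimate_noise(corrected) if corrected.size >= 16 else 0.0
    return ProcessedSpectrum(
        spectrum=spectrum, corrected=corrected, baseline=baseline,
        noise_sigma=noise_sigma, norm=norm, flags=flags,
    )


def preprocess_set(spectrum_set: SpectrumSet,
                   config: PreprocessConfig | None = None
                   ) -> list[ProcessedSpectrum]:
    """Condition every spectrum in a cohort (shared grid enforced upstream)."""
    cfg = config or PreprocessConfig()
    return [preprocess_spectrum(s, cfg) for s in spectrum_set]
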