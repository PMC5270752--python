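"""Shared fixtures: the seeded emulation cohort and small helper builders."""

from __future__ import annotations

import numpy as np
import pytest

import racescrs as rs
from racescrs.preprocess import ProcessedSpectrum
from racescrs.spectral_io import Spectrum, WavenumberGrid

EMULATION_SEED = 1


@pytest.fixture(scope="session")
def emulation_cohort():
    """The full surface-seawater emulation: 5321 cells, default noise, seed 1."""
    return rs.simulate_cohort(rs.red_sea_default(5321), rs.NoiseModel(),
                              seed=EMULATION_SEED)


@pytest.fixture(scope="session")
def emulation_processed(emulation_cohort):
    return rs.preprocess_set(emulation_cohort)


@pytest.fixture(scope="session")
def emulation_report(emulation_processed):
    return rs.classify_cohort(emulation_processed)


@pytest.fixture(scope="session")
def small_noisy_cohort():
    """A 300-cell cohort with default noise for cheaper integration tests."""
    return rs.simulate_cohort(rs.red_sea_default(300), rs.NoiseModel(), seed=11)


def make_processed(values: np.ndarray, noise_sigma: float = 0.0,
                   start: float = 0.0, step: float = 1.0) -> ProcessedSpectrum:
    """Wrap a plain vector as a ProcessedSpectrum for detector-level tests."""
    values = np.asarray(values, dtype=float)
    grid = WavenumberGrid.uniform(start, step, values.size)
    spectrum = Spectrum(grid=grid, intensities=np.maximum(values, 0.0),
                        cell_id="t")
    return ProcessedSpectrum(spectrum=spectrum, corrected=values,
                             baseline=np.zeros_like(values),
                             noise_sigma=noise_sigma, norm=1.0)


# ---------------------------------------------------------------------------
# Independent brute-force oracles (used by property and acceptance tests)
# ---------------------------------------------------------------------------

def oracle_peaks(y: np.ndarray, threshold: float) -> list[tuple[int, float]]:
    """Exhaustive peak detection: every interior strict local maximum, with
    prominence computed by a full basin scan (walk out to the next strictly
    higher point or border; take the minimum along each side; prominence is
    the height above the higher of the two side minima)."""
    y = np.asarray(y, dtype=float)
    out = []
    for i in range(1, y.size - 1):
        if not (y[i] > y[i - 1] and y[i] > y[i + 1]):
            continue
        left_min = y[i]
        j = i - 1
        while j >= 0 and y[j] <= y[i]:
            left_min = min(left_min, y[j])
            j -= 1
        right_min = y[i]
        j = i + 1
        while j < y.size and y[j] <= y[i]:
            right_min = min(right_min, y[j])
            j += 1
        prom = y[i] - max(left_min, right_min)
        if prom >= threshold:
            out.append((i, prom))
    return out


def oracle_partition(points: np.ndarray, tol: float) -> list[set[int]]:
    """Connected components of the pairwise Chebyshev d <= tol graph,
    by union-find."""
    n = len(points)
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(n):
        for j in range(i + 1, n):
            if np.max(np.abs(points[i] - points[j])) <= tol:
                parent[find(i)] = find(j)
    groups: dict[int, set[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return sorted(groups.values(), key=lambda s: min(s))


def oracle_eigendecomposition(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Brute-force PCA: eigendecomposition of the sample covariance matrix.

    Returns (eigenvalues descending, eigenvectors as columns).
    """
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / (X.shape[0] - 1)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    return vals[order], vecs[:, order]
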