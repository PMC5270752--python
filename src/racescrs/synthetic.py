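"""Seeded synthetic single-cell Raman cohorts.

Real SCRS surveys of seawater communities are dominated by a few phenotype
classes: ordinary heterotrophic cells with generic protein/nucleic-acid bands,
carotenoid-containing cells whose resonance-enhanced ν1/ν2/ν3 bands dwarf the
rest of the spectrum, PHB-accumulating cells with the four ester/C-C marker
bands, cells whose autofluorescence buries the Raman signal under a broad
"bump", and cells carrying other distinctive compounds.  This module renders
those archetypes as sums of Lorentzian peaks over a smooth background and
assembles them into seeded cohorts whose class composition matches a named
preset, so the whole downstream pipeline is testable without instrument data.

The ``red_sea_default`` preset emulates a surface-seawater cohort of 5321
cells: 33% fluorescence-dominated, 23% carotenoid-containing, with the
remainder split between typical, PHB and other-compound cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectral_io import Spectrum, SpectrumSet, WavenumberGrid

# Carotenoid resonance band windows (cm⁻¹).  ν1 is the low-wavenumber methyl
# rocking band; ν2 and ν3 shift with conjugated C=C chain length, so the
# triplet of positions fingerprints the carotenoid structure at ~1 cm⁻¹
# resolution.
CAROTENOID_V1_WINDOW = (997.0, 1007.0)
CAROTENOID_V2_WINDOW = (1145.0, 1161.0)
CAROTENOID_V3_WINDOW = (1503.0, 1526.0)

#: PHB (poly-β-hydroxybutyrate) marker band positions (cm⁻¹).
PHB_MARKERS = (839.0, 1058.0, 1123.0, 1403.0)

#: Generic cellular bands present in every non-empty archetype
#: (centre cm⁻¹, relative height, FWHM cm⁻¹).
BASE_CELL_BANDS = (
    (785.0, 0.3, 20.0),   # nucleic acids
    (1003.0, 0.5, 20.0),  # phenylalanine ring breathing
    (1245.0, 0.3, 20.0),  # amide III
    (1450.0, 0.4, 20.0),  # CH2 deformation
    (1660.0, 0.5, 20.0),  # amide I
)

# Resonance heights for the carotenoid triplet: the ν3 C=C stretch is the
# strongest, consistent with sharp, strong resonance spectra.
_CAROTENOID_HEIGHTS = {"v1": 1.5, "v2": 3.0, "v3": 5.0}
_CAROTENOID_FWHM = 12.0

_PHB_HEIGHTS = (1.5, 1.2, 1.0, 0.8)
_PHB_FWHM = 12.0

# Bands of an "other distinctive compound" cell (heterocyclic-aromatic-like
# fingerprint); chosen off every classifier window except a single CH2 band so
# such cells are neither typical nor biomarker-positive.
_OTHER_COMPOUND_BANDS = (
    (730.0, 1.2, 14.0),
    (960.0, 1.0, 14.0),
    (1290.0, 1.3, 14.0),
    (1560.0, 0.9, 14.0),
    (1450.0, 0.4, 20.0),
)

ARCHETYPE_NAMES = ("typical", "carotenoid", "phb", "fluorescent", "other_compound")


class ConfigError(ValueError):
    """Raised for invalid generator configuration."""


@dataclass
class Archetype:
    """A phenotype template: Lorentzian peaks plus an optional broad background.

    ``background`` is ``None`` or ``("broad_gaussian", {"center", "sigma",
    "height"})`` — the autofluorescence bump.  The smooth polynomial substrate
    baseline is part of :class:`NoiseModel`, not the archetype, because it
    varies per acquisition rather than per phenotype.
    """

    name: str
    peaks: list[tuple[float, float, float]]  # (center cm⁻¹, height, fwhm cm⁻¹)
    background: tuple[str, dict] | None = None
    triplet: tuple[float, float, float] | None = None  # carotenoid (ν1, ν2, ν3)

    def __post_init__(self) -> None:
        for c, h, w in self.peaks:
            if h <= 0 or w <= 0:
                raise ConfigError(f"archetype {self.name}: peak heights and "
                                  f"FWHM must be > 0 (got h={h}, fwhm={w})")


@dataclass
class NoiseModel:
    """Per-acquisition stochastic components.

    * ``read_sigma`` — additive detector read noise (counts).
    * ``shot_scale`` — signal-dependent shot noise, σ_shot = shot_scale·√signal.
    * ``baseline_poly_degree`` / ``baseline_amplitude`` — smooth random
      polynomial substrate background per cell (min 0, max = amplitude).
    * ``cosmic_ray_rate`` — expected spike count per spectrum (default off).
    """

    read_sigma: float = 0.02
    shot_scale: float = 0.05
    baseline_poly_degree: int = 3
    baseline_amplitude: float = 0.3
    cosmic_ray_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("read_sigma", "shot_scale", "baseline_amplitude",
                     "cosmic_ray_rate"):
            if getattr(self, name) < 0:
                raise ConfigError(f"noise parameter {name} must be >= 0")

    @classmethod
    def noiseless(cls) -> "NoiseModel":
        return cls(read_sigma=0.0, shot_scale=0.0, baseline_poly_degree=0,
                   baseline_amplitude=0.0, cosmic_ray_rate=0.0)


@dataclass
class CompositionPreset:
    """Cohort composition: archetype fractions and cohort size."""

    fractions: dict[str, float]
    n_cells: int
    name: str = "custom"

    def __post_init__(self) -> None:
        bad = set(self.fractions) - set(ARCHETYPE_NAMES)
        if bad:
            raise ConfigError(f"unknown archetypes in preset: {sorted(bad)}")
        if any(f < 0 for f in self.fractions.values()):
            raise ConfigError("fractions must be >= 0")
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"fractions must sum to 1 (got {total!r})")
        if self.n_cells < 0:
            raise ConfigError("n_cells must be >= 0")


def red_sea_default(n_cells: int = 5321) -> CompositionPreset:
    """The surface-seawater emulation preset.

    33% fluorescence-dominated and 23% carotenoid-containing are the anchored
    fractions; the residual 44% is split 30/7/7 between typical, PHB and
    other-compound cells (an assumption, configurable).
    """
    return CompositionPreset(
        fractions={"fluorescent": 0.33, "carotenoid": 0.23,
                   "typical": 0.30, "phb": 0.07, "other_compound": 0.07},
        n_cells=n_cells,
        name="red_sea_default",
    )


PRESETS = {"red_sea_default": red_sea_default}


# ---------------------------------------------------------------------------
# Archetype construction
# ---------------------------------------------------------------------------

def _draw_triplet(rng: np.random.Generator) -> tuple[float, float, float]:
    return (
        float(rng.uniform(*CAROTENOID_V1_WINDOW)),
        float(rng.uniform(*CAROTENOID_V2_WINDOW)),
        float(rng.uniform(*CAROTENOID_V3_WINDOW)),
    )


def make_archetype(
    name: str,
    rng: np.random.Generator | None = None,
    pinned_triplet: tuple[float, float, float] | None = None,
) -> Archetype:
    """Build a concrete archetype, drawing its random aspects from ``rng``.

    Carotenoid archetypes draw (ν1, ν2, ν3) uniformly inside the canonical
    windows unless ``pinned_triplet`` fixes them; the fluorescent archetype
    draws its bump centre uniformly in 1100–1500 cm⁻¹.
    """
    if name not in ARCHETYPE_NAMES:
        raise ConfigError(f"unknown archetype {name!r}")
    if rng is None:
        rng = np.random.default_rng(0)
    base = [tuple(b) for b in BASE_CELL_BANDS]

    if name == "typical":
        return Archetype(name=name, peaks=base)
    if name == "carotenoid":
        triplet = pinned_triplet if pinned_triplet is not None else _draw_triplet(rng)
        v1, v2, v3 = triplet
        for lo_hi, v in zip(
            (CAROTENOID_V1_WINDOW, CAROTENOID_V2_WINDOW, CAROTENOID_V3_WINDOW),
            triplet,
        ):
            if not (lo_hi[0] <= v <= lo_hi[1]):
                raise ConfigError(f"pinned band {v} outside window {lo_hi}")
        peaks = base + [
            (v1, _CAROTENOID_HEIGHTS["v1"], _CAROTENOID_FWHM),
            (v2, _CAROTENOID_HEIGHTS["v2"], _CAROTENOID_FWHM),
            (v3, _CAROTENOID_HEIGHTS["v3"], _CAROTENOID_FWHM),
        ]
        return Archetype(name=name, peaks=peaks, triplet=(v1, v2, v3))
    if name == "phb":
        peaks = base + [
            (pos, h, _PHB_FWHM) for pos, h in zip(PHB_MARKERS, _PHB_HEIGHTS)
        ]
        return Archetype(name=name, peaks=peaks)
    if name == "fluorescent":
        # Broad Gaussian bump 20x the strongest base band; it dwarfs the
        # Raman peaks, which stay present underneath.
        center = float(rng.uniform(1100.0, 1500.0))
        strongest = max(h for _, h, _ in base)
        bg = ("broad_gaussian",
              {"center": center, "sigma": 300.0, "height": 20.0 * strongest})
        return Archetype(name=name, peaks=base, background=bg)
    # other_compound
    return Archetype(name=name, peaks=[tuple(b) for b in _OTHER_COMPOUND_BANDS])


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def lorentzian(wavenumbers: np.ndarray, center: float, height: float,
               fwhm: float) -> np.ndarray:
    """L(ν) = h·(Γ/2)² / ((ν−ν₀)² + (Γ/2)²)."""
    half = fwhm / 2.0
    return height * half**2 / ((wavenumbers - center) ** 2 + half**2)


def _random_poly_baseline(wavenumbers: np.ndarray, degree: int, amplitude: float,
                          rng: np.random.Generator) -> np.ndarray:
    """Smooth random polynomial substrate background, min 0, max = amplitude."""
    if degree <= 0 or amplitude <= 0:
        return np.zeros_like(wavenumbers)
    x = np.linspace(-1.0, 1.0, wavenumbers.size)
    coeffs = rng.standard_normal(degree + 1)
    b = np.polynomial.chebyshev.chebval(x, coeffs)
    b = b - b.min()
    peak = b.max()
    if peak <= 0:
        return np.zeros_like(wavenumbers)
    return amplitude * b / peak


def render_archetype(
    archetype: Archetype,
    grid: WavenumberGrid | None = None,
    rng: np.random.Generator | None = None,
    noise: NoiseModel | None = None,
    cell_id: str = "",
    position: tuple[float, float] | None = None,
) -> Spectrum:
    """Render an archetype on a grid: Σ Lorentzians + background (+ noise).

    Pass ``noise=None`` for a noiseless render (pure deterministic signal,
    no substrate baseline).  The ground-truth archetype name is attached as
    the spectrum label.
    """
    if grid is None:
        grid = WavenumberGrid.default()
    w = grid.values
    y = np.zeros_like(w)
    for center, height, fwhm in archetype.peaks:
        if not (w[0] <= center <= w[-1]):
            raise ConfigError(
                f"peak centre {center} cm-1 outside grid {w[0]:g}-{w[-1]:g}")
        y += lorentzian(w, center, height, fwhm)
    if archetype.background is not None:
        kind, params = archetype.background
        if kind == "broad_gaussian":
            y += params["height"] * np.exp(
                -0.5 * ((w - params["center"]) / params["sigma"]) ** 2)
        else:
            raise ConfigError(f"unknown background kind {kind!r}")

    if noise is not None:
        if rng is None:
            raise ConfigError("a noise model requires an rng")
        y = y + _random_poly_baseline(
            w, noise.baseline_poly_degree, noise.baseline_amplitude, rng)
        sigma = np.sqrt(
            noise.read_sigma**2 + (noise.shot_scale**2) * np.maximum(y, 0.0))
        if np.any(sigma > 0):
            y = y + rng.normal(0.0, 1.0, size=y.size) * sigma
        if noise.cosmic_ray_rate > 0:
            n_spikes = rng.poisson(noise.cosmic_ray_rate)
            for _ in range(n_spikes):
                y[rng.integers(0, y.size)] += rng.uniform(5.0, 50.0)
        y = np.maximum(y, 0.0)  # detector counts are non-negative

    meta = {"archetype": archetype.name}
    if archetype.triplet is not None:
        meta["triplet"] = archetype.triplet
    return Spectrum(grid=grid, intensities=y, cell_id=cell_id,
                    position=position, label=archetype.name, meta=meta)


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

def simulate_cohort(
    preset: CompositionPreset,
    noise: NoiseModel | None = None,
    seed: int = 0,
    grid: WavenumberGrid | None = None,
) -> SpectrumSet:
    """Generate a seeded cohort with the preset's class composition.

    Ground-truth label counts follow one multinomial draw from the preset
    fractions; cell order is then shuffled so labels are not blocked.  Chip
    positions are assigned uniquely on a simulated raster (10 µm pitch).
    Identical seeds give bit-identical cohorts.
    """
    if noise is None:
        noise = NoiseModel()
    if grid is None:
        grid = WavenumberGrid.default()
    rng = np.random.default_rng(seed)

    names = sorted(preset.fractions)  # stable archetype order
    probs = np.array([preset.fractions[n] for n in names])
    counts = rng.multinomial(preset.n_cells, probs)
    labels = np.repeat(names, counts)
    rng.shuffle(labels)

    n_cols = max(1, int(np.ceil(np.sqrt(preset.n_cells)))) if preset.n_cells else 1
    spectra = []
    width = max(5, len(str(max(preset.n_cells, 1))))
    for i, label in enumerate(labels):
        pos = (10.0 * (i % n_cols), 10.0 * (i // n_cols))  # raster, µm
        arch = make_archetype(str(label), rng=rng)
        spectra.append(render_archetype(
            arch, grid=grid, rng=rng, noise=noise,
            cell_id=f"cell_{i:0{width}d}", position=pos))
    return SpectrumSet(spectra, provenance={"preset": preset.name, "seed": seed})


# ---------------------------------------------------------------------------
# Sorted-sample reference spectra
# ---------------------------------------------------------------------------

#: Pinned (ν1, ν2, ν3) triplets for the seven sorted-sample reference spectra.
#: The three Pelomonas-like samples (P728-5, P709-11, P610-5) share one
#: triplet; the other four are mutually distinct, giving five carotenoid
#: types.  Exact positions are synthetic values placed inside the canonical
#: band windows.
SORTED_SAMPLE_TRIPLETS: dict[str, tuple[float, float, float]] = {
    "P728-5": (1001.0, 1152.0, 1508.0),
    "B728-3": (1004.0, 1156.0, 1512.0),
    "H808-5": (999.0, 1149.0, 1518.0),
    "S709-6": (1003.0, 1158.0, 1522.0),
    "P709-11": (1001.0, 1152.0, 1508.0),
    "G610-8": (1006.0, 1154.0, 1525.0),
    "P610-5": (1001.0, 1152.0, 1508.0),
}


def sorted_samples_reference(grid: WavenumberGrid | None = None) -> SpectrumSet:
    """Seven noiseless carotenoid reference spectra resolving into five types."""
    if grid is None:
        grid = WavenumberGrid.default()
    spectra = []
    for name, triplet in SORTED_SAMPLE_TRIPLETS.items():
        arch = make_archetype("carotenoid", pinned_triplet=triplet)
        spectra.append(render_archetype(arch, grid=grid, cell_id=name))
    return SpectrumSet(spectra, provenance={"preset": "sorted_samples_reference"})
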