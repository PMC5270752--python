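# Methods

This note records the models, defaults and numerical behavior behind
`racescrs`, in enough detail to re-derive or audit every pipeline stage.

## Spectral grid

All spectra live on a shared wavenumber grid; the default is 1019 points
at 1.0 cm⁻¹ spacing starting at 700 cm⁻¹ (700–1718 cm⁻¹). The point count
and spacing reflect a typical confocal Raman detector readout for the
fingerprint region; the 700 cm⁻¹ start is a design choice that covers
every band the classifier uses (lowest marker: PHB at 839 cm⁻¹) with
margin. Non-uniform grids are accepted for I/O and flagged; peak
positions are always reported in cm⁻¹ at grid points.

## Synthetic cohorts

Cells are drawn from five archetypes, each a sum of Lorentzian bands
L(ν) = h·(Γ/2)² / ((ν−ν₀)² + (Γ/2)²):

- **carotenoid** — a resonance triplet with ν1 ∈ [997, 1007],
  ν2 ∈ [1145, 1161], ν3 ∈ [1503, 1526] cm⁻¹ (heights 1.5 / 3.0 / 5.0,
  FWHM 12) on top of weak base-cell bands. The triplet is drawn per cell,
  so a cohort contains a continuum of carotenoid variants.
- **phb** — marker bands at 839, 1058, 1123, 1403 cm⁻¹ plus base bands.
- **typical** — base-cell bands only (785, 1003, 1245, 1450, 1660 cm⁻¹).
- **other_compound** — bands deliberately off the marker windows.
- **fluorescent** — a broad Gaussian bump (σ = 300 cm⁻¹, height 10)
  dwarfing any Raman bands, emulating fluorescence-dominated readouts.

The noise model adds Gaussian read noise (σ = 0.02), signal-dependent
shot noise (scale 0.05), and a random smooth polynomial background
(Chebyshev degree 3, amplitude 0.3); intensities are clipped at zero.
The `red_sea_default` composition preset emulates a surface-seawater
community: 33% fluorescent, 23% carotenoid, 30% typical, 7% PHB, 7%
other. All randomness flows from `numpy.random.default_rng` seeds;
pipeline stages derive independent child seeds via `SeedSequence`.

Seven noiseless "sorted-sample" reference spectra carry pinned triplets
chosen inside the band windows such that exactly five distinct triplet
values exist and three samples share one (pairwise Chebyshev distances
between distinct values are ≥ 4 cm⁻¹, well above the 2 cm⁻¹ typing
tolerance).

## Preprocessing

Baseline estimation uses asymmetric least squares: minimize
Σ wᵢ (yᵢ − bᵢ)² + λ Σ (Δ²b)² with wᵢ = p where yᵢ > bᵢ and 1 − p
otherwise, iterated (default 10 passes, early stop when weights
stabilize). Defaults λ = 1e5, p = 0.01. The pentadiagonal system is
solved with a banded Cholesky factorization per iteration.

Numerical behavior worth knowing: the second-difference penalty has
natural boundary conditions, so at the default stiffness the estimate
sags near the spectrum borders — on a pure cubic background the error
reaches ~6% of the background range at the borders and ~1.4% in the
interior, while λ = 1e3 tracks the same cubic to <1% everywhere. The
tests freeze these measured bounds (≤8% border / ≤2% interior at the
default, ≤1% at λ = 1e3). On background-free spectra the baseline tracks
residual Lorentzian tails (sub-1% of peak height 80 cm⁻¹ from any band).

Noise is estimated robustly from first differences:
σ̂ = 1.4826 · median(|Δy − median(Δy)|) / √2 (exact for white Gaussian
noise, insensitive to sparse peaks; requires ≥16 points). Spectra are
vector normalized (unit ℓ2) after baseline subtraction; all-zero input is
flagged low-signal and passed through unchanged. Smoothing
(Savitzky–Golay) is off by default.

## Classification

Each cell is processed in a fixed decision order:

1. **Fluorescence screen.** F = Σ baseline / Σ raw (clipped to [0, 1]).
   A cell is fluorescence-dominated when F > 0.85 or when no peak reaches
   3σ prominence. The 0.85 / 3σ values were tuned once so that the
   default generator reproduces its own preset label fractions within
   binomial noise; they are not measured constants.
2. **Peak detection.** Strict local maxima with
   `scipy.signal.peak_prominences`, threshold 5σ. At the phenotype stage
   an additional prominence floor of 0.2 × max(corrected) is applied: on
   this generator genuine required bands always exceed ~35% of the
   spectrum maximum while correlated baseline-residual humps stay below
   ~13%, and the floor removes the latter. This floor was calibrated
   against the <1% classifier-error budget.
3. **Band matching.** Three independent band families (carotenoid ν1–ν3,
   PHB markers ±5 cm⁻¹, base-cell bands). Within a family, windows must
   be disjoint; each band takes the most prominent unassigned peak in its
   window, ties broken by distance to window center, then lower
   wavenumber.
4. **Phenotype call.** carotenoid (all three ν bands) → phb (all four
   markers) → typical (≥2 base bands) → other.

Classification is invariant under raw-intensity scaling (normalization
makes peak heights and noise scale together). On the default seeded
5321-cell emulation, accuracy versus ground truth is ≈99.5%; the dominant
residual error is carotenoid cells whose true band sits within ~1 cm⁻¹ of
a window edge and is detected one grid point outside — an honest
consequence of 1 cm⁻¹ sampling.

## Carotenoid typing

Carotenoid calls carry a (ν1, ν2, ν3) triplet. Types are single-linkage
clusters under the Chebyshev metric with a 2 cm⁻¹ tolerance (equivalently
connected components of the "all band positions within 2 cm⁻¹" graph —
the tests check this equivalence against a union-find oracle). Type
indices are ordered by centroid ν3. Caveat: single linkage chains — on a
large noisy cohort whose triplets fill the band windows densely, most
cells merge into one type; the tolerance is meant for small sorted-sample
panels, and complete linkage is available as an alternative.

## Ordination

PCA (full SVD) over baseline-corrected, normalized spectra, excluding
fluorescence-dominated cells by default. Sign convention: each
component's largest-magnitude loading entry is made positive (scores
flipped accordingly), so results are deterministic.

Loading interpretation: `top_loading_windows` reports contiguous runs
where the loading reaches α (default 0.5) of the component's maximum,
merging runs separated by fewer than 3 points. By default the threshold
is applied to the *signed* loading in the dominant orientation rather
than to |loading|: with vector normalization, strong carotenoid bands
induce anti-correlated negative loadings on the common cell bands, and an
absolute-value rule would report those compensatory windows alongside the
genuine carotenoid ones. The absolute-value rule remains available
(`signed=False`).

## Sort planning

A chip has n wells (default 12) with ≥2 reserved controls: at least one
negative control that must remain cell-free and one positive control.
Targets (cells matching a phenotype query) are taken in ascending cell-id
order and dealt round-robin into the non-control wells; capacities are
1–8 cells per well, either uniform or per-well. Requesting more capacity
than the chip provides raises a capacity error stating the shortfall.
Simulated sessions draw each ejection outcome from a seeded Bernoulli
model (default success probability 1.0; empirical downstream recovery
rates near 25% can be modeled by lowering it) and space ejections by the
5 s per-cell acquisition time.

## Limitations

- The generator emulates band positions, relative intensities, noise and
  fluorescence backgrounds — not instrument response, cosmic rays
  (rate defaults to 0), wavenumber calibration drift, or cell-to-cell
  intensity covariance.
- The ALS boundary sag and the 1 cm⁻¹ detection quantization described
  above bound the achievable classification accuracy near band-window
  edges.
- Single-linkage typing is not meaningful on dense noisy cohorts (see
  above).
- No downstream sequencing or culture steps are modeled; the sort
  manifest is the final artifact.
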