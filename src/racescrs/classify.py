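"""Fluorescence screening and biomarker-band phenotype calls.

The sorting criterion for carotenoid-containing cells is the joint presence
of the three resonance bands ν1 (997–1007), ν2 (1145–1161) and ν3
(1503–1526 cm⁻¹); PHB-accumulating cells are called from the four marker
bands at 839, 1058, 1123 and 1403 cm⁻¹.  Cells whose autofluorescence dwarfs
the Raman signal are screened out first: their spectra are a broad bump with
no usable bands, so no biomarker call is attempted for them.

Decision order per cell: fluorescent → carotenoid → PHB → typical → other.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import peak_prominences

from .preprocess import FLAG_LOW_SIGNAL, ProcessedSpectrum
from .spectral_io import SpectralValidationError
from .synthetic import (
    BASE_CELL_BANDS,
    CAROTENOID_V1_WINDOW,
    CAROTENOID_V2_WINDOW,
    CAROTENOID_V3_WINDOW,
    PHB_MARKERS,
)

LABELS = ("fluorescent", "carotenoid", "phb", "typical", "other")

#: Half-width (cm⁻¹) of the matching window around point markers (PHB and
#: base-cell band positions).
MARKER_TOLERANCE = 5.0


class BandConfigError(ValueError):
    """Raised for invalid band definitions (e.g. overlapping windows)."""


@dataclass(frozen=True)
class BandDefinition:
    """A named biomarker window on the wavenumber axis."""

    name: str
    window: tuple[float, float]  # (lo, hi) cm⁻¹
    role: str  # carotenoid_v1|carotenoid_v2|carotenoid_v3|phb_marker|base_cell

    def __post_init__(self) -> None:
        lo, hi = self.window
        if not lo < hi:
            raise BandConfigError(f"band {self.name}: lo must be < hi")

    @property
    def center(self) -> float:
        return 0.5 * (self.window[0] + self.window[1])

    @classmethod
    def marker(cls, name: str, position: float, role: str,
               tolerance: float = MARKER_TOLERANCE) -> "BandDefinition":
        return cls(name=name, window=(position - tolerance, position + tolerance),
                   role=role)


def carotenoid_bands() -> list[BandDefinition]:
    """The canonical ν1/ν2/ν3 resonance windows."""
    return [
        BandDefinition("v1", CAROTENOID_V1_WINDOW, "carotenoid_v1"),
        BandDefinition("v2", CAROTENOID_V2_WINDOW, "carotenoid_v2"),
        BandDefinition("v3", CAROTENOID_V3_WINDOW, "carotenoid_v3"),
    ]


def phb_bands(tolerance: float = MARKER_TOLERANCE) -> list[BandDefinition]:
    """The four PHB marker bands, each ±tolerance cm⁻¹."""
    return [BandDefinition.marker(f"phb_{int(p)}", p, "phb_marker", tolerance)
            for p in PHB_MARKERS]


def base_cell_bands(tolerance: float = MARKER_TOLERANCE) -> list[BandDefinition]:
    """Generic cellular bands used for the 'typical cell' call."""
    return [BandDefinition.marker(f"base_{int(c)}", c, "base_cell", tolerance)
            for c, _, _ in BASE_CELL_BANDS]


@dataclass(frozen=True)
class Peak:
    """A detected local maximum in a normalized, corrected spectrum."""

    position: float     # cm⁻¹, on the grid
    height: float       # normalized units
    prominence: float   # height above the higher flanking basin minimum


@dataclass
class PhenotypeCall:
    """Per-cell classification output."""

    cell_id: str
    fluorescence_index: float
    is_fluorescent: bool
    band_matches: dict[str, Peak | None]
    label: str
    carotenoid_score: float = 0.0
    triplet: tuple[float, float, float] | None = None
    flags: set = field(default_factory=set)
    position: tuple[float, float] | None = None
    true_label: str | None = None


@dataclass
class ClassifierConfig:
    """Thresholds for screening and band calls.

    * ``theta_f`` — fluorescence-index threshold (baseline mass / raw mass).
    * ``snr_min`` — a cell with no peak of prominence ≥ snr_min·σ has no
      usable Raman signal and is screened with the fluorescent fraction.
    * ``min_prominence_sigma`` — detection threshold in units of the robust
      noise scale.
    * ``prominence_floor_frac`` — band matching additionally ignores peaks
      below this fraction of the strongest corrected intensity: the weakest
      genuine biomarker band in any phenotype is ≥ 40% of its spectrum's
      maximum, while smooth residual humps left by the baseline fit stay
      below ~15%; a 20% floor rejects those humps (and baseline-residual
      ripples in the σ → 0 limit) without touching real bands.
    * ``carotenoid_min_matches`` — ν windows required (3 = all; 2 relaxes).
    * ``phb_min_matches`` — marker bands required out of 4.
    """

    theta_f: float = 0.85
    snr_min: float = 3.0
    min_prominence_sigma: float = 5.0
    prominence_floor_frac: float = 0.2
    carotenoid_min_matches: int = 3
    phb_min_matches: int = 4
    typical_min_matches: int = 2
    marker_tolerance: float = MARKER_TOLERANCE


# ---------------------------------------------------------------------------
# Screening and detection
# ---------------------------------------------------------------------------

def fluorescence_index(raw: np.ndarray, baseline: np.ndarray) -> float:
    """F = Σ baseline / Σ raw, clipped to [0, 1].

    F near 1 means the smooth background carries nearly all the spectral
    mass — the broad autofluorescence bump.  Returns NaN when Σ raw ≤ 0
    (no signal at all); callers flag such cells low_signal.
    """
    total = float(np.sum(raw))
    if total <= 0:
        return float("nan")
    return float(np.clip(np.sum(baseline) / total, 0.0, 1.0))


def detect_peaks(processed: ProcessedSpectrum,
                 min_prominence_sigma: float = 5.0) -> list[Peak]:
    """All strict local maxima with prominence ≥ min_prominence_sigma·σ.

    Prominence is the height above the higher of the two flanking basin
    minima (the standard topographic definition).  Peaks are returned sorted
    by position.
    """
    y = processed.corrected
    idx = np.flatnonzero((y[1:-1] > y[:-2]) & (y[1:-1] > y[2:])) + 1
    if idx.size == 0:
        return []
    prom = peak_prominences(y, idx)[0]
    threshold = min_prominence_sigma * processed.noise_sigma
    keep = prom >= threshold
    w = processed.wavenumbers
    return [Peak(position=float(w[i]), height=float(y[i]), prominence=float(p))
            for i, p in zip(idx[keep], prom[keep])]


# ---------------------------------------------------------------------------
# Band matching
# ---------------------------------------------------------------------------

def match_bands(peaks: list[Peak], band_defs: list[BandDefinition]
                ) -> dict[str, Peak | None]:
    """Assign at most one peak to each band window.

    Bands must be mutually disjoint.  Each band takes the most prominent
    unassigned peak inside its window; ties break to the peak closest to the
    window centre, then to the lower wavenumber.  Bands are processed in
    ascending window order, and a peak satisfies at most one band.
    """
    ordered = sorted(band_defs, key=lambda b: b.window)
    for a, b in zip(ordered, ordered[1:]):
        if b.window[0] <= a.window[1]:
            raise BandConfigError(
                f"overlapping band windows: {a.name} {a.window} / "
                f"{b.name} {b.window}")
    assigned: set[float] = set()
    matches: dict[str, Peak | None] = {}
    for band in ordered:
        lo, hi = band.window
        candidates = [p for p in peaks
                      if lo <= p.position <= hi and p.position not in assigned]
        if not candidates:
            matches[band.name] = None
            continue
        best = min(candidates,
                   key=lambda p: (-p.prominence,
                                  abs(p.position - band.center),
                                  p.position))
        matches[band.name] = best
        assigned.add(best.position)
    return matches


# ---------------------------------------------------------------------------
# Phenotype calls
# ---------------------------------------------------------------------------

def call_phenotype(processed: ProcessedSpectrum,
                   config: ClassifierConfig | None = None) -> PhenotypeCall:
    """Classify one conditioned spectrum.

    The three band families (carotenoid ν windows, PHB markers, base-cell
    bands) are matched independently because the ν1 window contains the
    1003 cm⁻¹ phenylalanine band: one physical peak may legitimately answer
    for both a resonance band and a cellular band.
    """
    cfg = config or ClassifierConfig()
    spec = processed.spectrum
    flags = set(processed.flags)

    f_index = fluorescence_index(spec.intensities, processed.baseline)
    if np.isnan(f_index):
        flags.add(FLAG_LOW_SIGNAL)
        return PhenotypeCall(
            cell_id=spec.cell_id, fluorescence_index=float("nan"),
            is_fluorescent=True, band_matches={}, label="fluorescent",
            flags=flags, position=spec.position, true_label=spec.label)

    peaks = detect_peaks(processed, cfg.min_prominence_sigma)
    max_prom = max((p.prominence for p in peaks), default=0.0)
    is_fluor = (f_index > cfg.theta_f
                or max_prom < cfg.snr_min * processed.noise_sigma)
    if is_fluor:
        return PhenotypeCall(
            cell_id=spec.cell_id, fluorescence_index=f_index,
            is_fluorescent=True, band_matches={}, label="fluorescent",
            flags=flags, position=spec.position, true_label=spec.label)

    # Relative prominence floor: with sigma -> 0 the detection threshold
    # vanishes and baseline-residual ripples would otherwise match windows.
    floor = cfg.prominence_floor_frac * float(processed.corrected.max())
    strong = [p for p in peaks if p.prominence >= floor]

    caro = match_bands(strong, carotenoid_bands())
    phb = match_bands(strong, phb_bands(cfg.marker_tolerance))
    base = match_bands(strong, base_cell_bands(cfg.marker_tolerance))
    band_matches = {**caro, **phb, **base}

    caro_hits = [caro[b.name] for b in carotenoid_bands() if caro[b.name]]
    phb_hits = sum(1 for v in phb.values() if v is not None)
    base_hits = sum(1 for v in base.values() if v is not None)

    label = "other"
    score = 0.0
    triplet = None
    if len(caro_hits) >= cfg.carotenoid_min_matches:
        label = "carotenoid"
        score = float(sum(p.prominence for p in caro_hits))
        if caro["v1"] and caro["v2"] and caro["v3"]:
            triplet = (caro["v1"].position, caro["v2"].position,
                       caro["v3"].position)
    elif phb_hits >= cfg.phb_min_matches:
        label = "phb"
    elif base_hits >= cfg.typical_min_matches:
        label = "typical"

    return PhenotypeCall(
        cell_id=spec.cell_id, fluorescence_index=f_index, is_fluorescent=False,
        band_matches=band_matches, label=label, carotenoid_score=score,
        triplet=triplet, flags=flags, position=spec.position,
        true_label=spec.label)


# ---------------------------------------------------------------------------
# Cohort classification
# ---------------------------------------------------------------------------

#: Ground-truth archetype name -> expected call label.
TRUTH_TO_LABEL = {"typical": "typical", "carotenoid": "carotenoid",
                  "phb": "phb", "fluorescent": "fluorescent",
                  "other_compound": "other"}


@dataclass
class CohortReport:
    """Aggregate classification of one cohort."""

    calls: list[PhenotypeCall]
    counts: dict[str, int]
    fractions: dict[str, float]
    n_cells: int
    n_fluorescent: int
    n_distinguishable: int
    confusion: pd.DataFrame | None = None  # truth rows x call columns
    accuracy: float | None = None

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for c in self.calls:
            v1, v2, v3 = (c.triplet if c.triplet else (np.nan,) * 3)
            x, y = (c.position if c.position else (np.nan, np.nan))
            rows.append({
                "cell_id": c.cell_id, "label": c.label,
                "is_fluorescent": c.is_fluorescent,
                "fluorescence_index": c.fluorescence_index,
                "carotenoid_score": c.carotenoid_score,
                "v1": v1, "v2": v2, "v3": v3, "x": x, "y": y,
                "true_label": c.true_label or "",
            })
        return pd.DataFrame(rows)


def classify_cohort(processed: list[ProcessedSpectrum],
                    config: ClassifierConfig | None = None) -> CohortReport:
    """Classify a conditioned cohort and tally label composition.

    When ground-truth archetype labels are present (synthetic cohorts), a
    truth-vs-call confusion matrix and overall accuracy are included.
    """
    cfg = config or ClassifierConfig()
    if processed:
        grid = processed[0].spectrum.grid
        for p in processed[1:]:
            if p.spectrum.grid != grid:
                raise SpectralValidationError(
                    f"mixed wavenumber grids in cohort (cell "
                    f"{p.spectrum.cell_id!r})")
    calls = [call_phenotype(p, cfg) for p in processed]
    n = len(calls)
    counts = {lab: 0 for lab in LABELS}
    for c in calls:
        counts[c.label] += 1
    fractions = {lab: (counts[lab] / n if n else 0.0) for lab in LABELS}
    n_fluor = counts["fluorescent"]

    confusion = None
    accuracy = None
    truths = [c.true_label for c in calls]
    if n and all(t is not None for t in truths):
        expected = [TRUTH_TO_LABEL.get(t, t) for t in truths]
        predicted = [c.label for c in calls]
        confusion = pd.crosstab(
            pd.Series(expected, name="truth"),
            pd.Series(predicted, name="call"))
        accuracy = float(np.mean([e == p for e, p in zip(expected, predicted)]))

    return CohortReport(
        calls=calls, counts=counts, fractions=fractions, n_cells=n,
        n_fluorescent=n_fluor, n_distinguishable=n - n_fluor,
        confusion=confusion, accuracy=accuracy)
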