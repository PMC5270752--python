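"""Spectral data model and on-disk formats.

A single-cell Raman spectrum (SCRS) is a vector of scattering intensities on a
wavenumber grid, acquired per cell on a sorting chip.  This module defines the
in-memory containers shared by every pipeline stage — :class:`WavenumberGrid`,
:class:`Spectrum` and :class:`SpectrumSet` — together with readers/writers for
the two plain-text formats the package consumes:

* two-column spectrum text (wavenumber, intensity), mirroring what confocal
  Raman instruments export per cell;
* a cohort CSV matrix whose header carries the wavenumber grid and whose rows
  are cells.

All wavenumber coordinates are physical cm⁻¹ values; no public contract uses
grid indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

#: Default acquisition grid: 1019 points at 1.0 cm⁻¹, covering 700–1718 cm⁻¹.
#: The spectral resolution of ~1 cm⁻¹ with 1019 points matches the confocal
#: instrument configuration the pipeline emulates; the 700–1718 range covers
#: every biomarker band the classifier knows about.
DEFAULT_GRID_START = 700.0
DEFAULT_GRID_STEP = 1.0
DEFAULT_GRID_POINTS = 1019


class SpectralFormatError(ValueError):
    """Raised for malformed spectrum or cohort files."""


class SpectralValidationError(ValueError):
    """Raised when spectral data violates a model invariant (e.g. mixed grids)."""


class WavenumberGrid:
    """A strictly increasing wavenumber axis in cm⁻¹.

    Uniform grids are described by ``(start, step, n_points)``; non-uniform
    axes (e.g. from an instrument export) are carried as explicit values and
    flagged via :attr:`is_uniform`.
    """

    __slots__ = ("_values", "_uniform")

    def __init__(self, values: Sequence[float]):
        values = np.asarray(values, dtype=float)
        if values.ndim != 1 or values.size < 2:
            raise SpectralValidationError("grid needs at least 2 wavenumber values")
        if not np.all(np.diff(values) > 0):
            raise SpectralValidationError("grid values must be strictly increasing")
        self._values = values
        steps = np.diff(values)
        self._uniform = bool(np.allclose(steps, steps[0], rtol=0, atol=1e-6))

    @classmethod
    def uniform(
        cls,
        start: float = DEFAULT_GRID_START,
        step: float = DEFAULT_GRID_STEP,
        n_points: int = DEFAULT_GRID_POINTS,
    ) -> "WavenumberGrid":
        if step <= 0:
            raise SpectralValidationError("grid step must be > 0")
        if n_points < 2:
            raise SpectralValidationError("grid needs n_points >= 2")
        return cls(start + step * np.arange(n_points))

    @classmethod
    def default(cls) -> "WavenumberGrid":
        return cls.uniform()

    @property
    def values(self) -> np.ndarray:
        return self._values

    @property
    def is_uniform(self) -> bool:
        return self._uniform

    @property
    def n_points(self) -> int:
        return int(self._values.size)

    @property
    def start(self) -> float:
        return float(self._values[0])

    @property
    def stop(self) -> float:
        return float(self._values[-1])

    @property
    def step(self) -> float:
        """Mean spacing; exact for uniform grids."""
        return float((self._values[-1] - self._values[0]) / (self._values.size - 1))

    def __len__(self) -> int:
        return self.n_points

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavenumberGrid):
            return NotImplemented
        return self._values.shape == other._values.shape and bool(
            np.allclose(self._values, other._values, rtol=0, atol=1e-9)
        )

    def __hash__(self) -> int:  # grids are value objects
        return hash((self.n_points, round(self.start, 6), round(self.stop, 6)))

    def __repr__(self) -> str:
        kind = "uniform" if self._uniform else "non-uniform"
        return (
            f"WavenumberGrid({self.start:g}..{self.stop:g} cm-1, "
            f"{self.n_points} pts, {kind})"
        )

    def window_mask(self, lo: float, hi: float) -> np.ndarray:
        """Boolean mask of grid points inside [lo, hi] cm⁻¹."""
        return (self._values >= lo) & (self._values <= hi)


@dataclass
class Spectrum:
    """One cell's Raman trace plus acquisition metadata.

    ``intensities`` are detector counts (arbitrary units); raw spectra are
    non-negative, while baseline-subtracted traces may dip below zero and are
    marked with the ``baseline_subtracted`` flag.
    """

    grid: WavenumberGrid
    intensities: np.ndarray
    cell_id: str = ""
    position: tuple[float, float] | None = None  # (x µm, y µm) on chip
    label: str | None = None  # ground-truth archetype tag (synthetic only)
    meta: dict = field(default_factory=dict)
    flags: set = field(default_factory=set)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != (self.grid.n_points,):
            raise SpectralValidationError(
                f"intensities length {self.intensities.size} != grid "
                f"n_points {self.grid.n_points}"
            )
        if "baseline_subtracted" not in self.flags and np.any(self.intensities < 0):
            raise SpectralValidationError("raw spectrum has negative intensities")

    @property
    def wavenumbers(self) -> np.ndarray:
        return self.grid.values


class SpectrumSet:
    """An ordered collection of spectra sharing one grid, with unique cell ids."""

    def __init__(self, spectra: Iterable[Spectrum], provenance: dict | None = None):
        spectra = list(spectra)
        if spectra:
            grid = spectra[0].grid
            for s in spectra[1:]:
                if s.grid != grid:
                    raise SpectralValidationError(
                        f"mixed wavenumber grids in SpectrumSet (cell {s.cell_id!r})"
                    )
            ids = [s.cell_id for s in spectra]
            seen: set[str] = set()
            for cid in ids:
                if cid in seen:
                    raise SpectralValidationError(f"duplicate cell_id {cid!r}")
                seen.add(cid)
        self.spectra: list[Spectrum] = spectra
        self.provenance: dict = dict(provenance or {})

    @property
    def grid(self) -> WavenumberGrid:
        if not self.spectra:
            raise SpectralValidationError("empty SpectrumSet has no grid")
        return self.spectra[0].grid

    @property
    def cell_ids(self) -> list[str]:
        return [s.cell_id for s in self.spectra]

    def intensity_matrix(self) -> np.ndarray:
        """(n_cells, n_points) stacked intensities."""
        return np.vstack([s.intensities for s in self.spectra])

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self) -> Iterator[Spectrum]:
        return iter(self.spectra)

    def __getitem__(self, i: int) -> Spectrum:
        return self.spectra[i]


# ---------------------------------------------------------------------------
# Two-column spectrum text
# ---------------------------------------------------------------------------

def read_spectrum_txt(path: str | Path) -> Spectrum:
    """Read a two-column (wavenumber, intensity) text spectrum.

    Whitespace- and comma-delimited rows are both accepted; lines starting
    with ``#`` are parsed as ``key=value`` metadata and preserved.  Descending
    wavenumber order is reversed to ascending; non-uniform spacing is accepted
    and flagged in ``spectrum.flags``.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    wn: list[float] = []
    iy: list[float] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    meta[key.strip()] = val.strip()
                continue
            parts = line.replace(",", " ").split()
            if len(parts) < 2:
                raise SpectralFormatError(
                    f"{path.name}:{lineno}: expected >= 2 columns, got {len(parts)}"
                )
            try:
                wn.append(float(parts[0]))
                iy.append(float(parts[1]))
            except ValueError as exc:
                raise SpectralFormatError(
                    f"{path.name}:{lineno}: non-numeric row: {line!r}"
                ) from exc
    if len(wn) < 2:
        raise SpectralFormatError(f"{path.name}: fewer than 2 data points")

    w = np.asarray(wn)
    y = np.asarray(iy)
    if np.all(np.diff(w) < 0):  # descending export: reverse to ascending
        w, y = w[::-1], y[::-1]
    elif not np.all(np.diff(w) > 0):
        raise SpectralFormatError(f"{path.name}: wavenumbers not monotone")

    grid = WavenumberGrid(w)
    flags: set = set()
    if not grid.is_uniform:
        flags.add("non_uniform_grid")
    cell_id = meta.get("cell_id", path.stem)
    position = None
    if "x" in meta and "y" in meta:
        position = (float(meta["x"]), float(meta["y"]))
    return Spectrum(
        grid=grid, intensities=y, cell_id=cell_id, position=position,
        label=meta.get("label") or None, meta=meta, flags=flags,
    )


def write_spectrum_txt(spectrum: Spectrum, path: str | Path, precision: int = 6) -> None:
    """Write a spectrum as tab-delimited two-column text with '#' metadata."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# cell_id={spectrum.cell_id}\n")
        if spectrum.position is not None:
            fh.write(f"# x={spectrum.position[0]:g}\n# y={spectrum.position[1]:g}\n")
        if spectrum.label:
            fh.write(f"# label={spectrum.label}\n")
        for key, val in spectrum.meta.items():
            if key in {"cell_id", "x", "y", "label"}:
                continue
            fh.write(f"# {key}={val}\n")
        for w, y in zip(spectrum.wavenumbers, spectrum.intensities):
            fh.write(f"{w:.{precision}f}\t{y:.{precision}f}\n")


# ---------------------------------------------------------------------------
# Cohort CSV matrix
# ---------------------------------------------------------------------------

_COHORT_META_COLS = ["cell_id", "x", "y", "label"]


def write_cohort_csv(spectrum_set: SpectrumSet, path: str | Path,
                     precision: int = 6) -> None:
    """Write a cohort as CSV: header ``cell_id,x,y,label,<ν₀>,<ν₁>,…``."""
    grid = spectrum_set.grid
    rows = []
    for s in spectrum_set:
        x, y = (s.position if s.position is not None else (np.nan, np.nan))
        rows.append([s.cell_id, x, y, s.label or ""] + list(s.intensities))
    cols = _COHORT_META_COLS + [f"{w:g}" for w in grid.values]
    df = pd.DataFrame(rows, columns=cols)
    df.to_csv(path, index=False, float_format=f"%.{precision}f")


def read_cohort_csv(path: str | Path) -> SpectrumSet:
    """Read a cohort CSV written by :func:`write_cohort_csv`.

    The grid is inferred from the numeric header columns.  Duplicate cell ids
    raise a validation error naming the offender; ragged rows raise a format
    error.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise SpectralFormatError(f"{path.name}: malformed CSV ({exc})") from exc
    missing = [c for c in _COHORT_META_COLS if c not in df.columns]
    if missing:
        raise SpectralFormatError(f"{path.name}: missing columns {missing}")
    wn_cols = [c for c in df.columns if c not in _COHORT_META_COLS]
    try:
        wn = np.array([float(c) for c in wn_cols])
    except ValueError as exc:
        raise SpectralFormatError(
            f"{path.name}: non-numeric wavenumber column in header"
        ) from exc
    if df[wn_cols].isna().any().any():
        raise SpectralFormatError(f"{path.name}: ragged or missing intensity values")
    dup = df["cell_id"].astype(str)[df["cell_id"].astype(str).duplicated()]
    if len(dup):
        raise SpectralValidationError(f"duplicate cell_id {dup.iloc[0]!r}")
    grid = WavenumberGrid(wn)
    spectra = []
    values = df[wn_cols].to_numpy(dtype=float)
    for i, row in enumerate(df.itertuples(index=False)):
        pos = None
        if np.isfinite(row.x) and np.isfinite(row.y):
            pos = (float(row.x), float(row.y))
        label = str(row.label) if isinstance(row.label, str) and row.label else None
        flags = {"baseline_subtracted"} if np.any(values[i] < 0) else set()
        spectra.append(Spectrum(
            grid=grid, intensities=values[i], cell_id=str(row.cell_id),
            position=pos, label=label, flags=flags,
        ))
    return SpectrumSet(spectra)


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def resample_to_grid(spectrum: Spectrum, grid: WavenumberGrid) -> Spectrum:
    """Linearly interpolate a spectrum onto a target grid.

    The target grid must lie within the source wavenumber range; endpoints are
    reproduced exactly when the grids share points.
    """
    src = spectrum.wavenumbers
    if grid.start < src[0] - 1e-9 or grid.stop > src[-1] + 1e-9:
        raise SpectralValidationError(
            f"target grid [{grid.start:g}, {grid.stop:g}] extends beyond source "
            f"range [{src[0]:g}, {src[-1]:g}]"
        )
    new_y = np.interp(grid.values, src, spectrum.intensities)
    return Spectrum(
        grid=grid, intensities=new_y, cell_id=spectrum.cell_id,
        position=spectrum.position, label=spectrum.label,
        meta=dict(spectrum.meta), flags=set(spectrum.flags) | {"resampled"},
    )
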