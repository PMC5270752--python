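"""RACE sort planning and simulated ejection sessions.

Classification output becomes a sort plan: a deterministic mapping of target
cells (selected by a phenotype/type predicate) to collection wells on the
chip.  A 12-well chip reserves at least two control wells — one negative
control that must remain cell-free and one positive control — and targets go
only to the remaining wells.  A simulated session then walks the plan,
spacing ejections by the per-cell acquisition time and drawing each outcome
from a seeded Bernoulli success model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .classify import PhenotypeCall

#: Per-cell spectral acquisition time, seconds.
DEFAULT_ACQUISITION_TIME_S = 5.0


class SortConfigError(ValueError):
    """Raised for invalid chip layouts or sort-plan parameters."""


class CapacityError(SortConfigError):
    """Raised when target cells need more wells than the chip provides."""


@dataclass
class ChipLayout:
    """Collection-chip geometry: wells and reserved controls."""

    n_wells: int = 12
    negative_controls: tuple[str, ...] = ()
    positive_controls: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_wells < 3:
            raise SortConfigError("chip needs at least 3 wells")
        if not self.negative_controls:
            self.negative_controls = ("W01",)
        if not self.positive_controls:
            self.positive_controls = ("W02",)
        controls = set(self.negative_controls) | set(self.positive_controls)
        if set(self.negative_controls) & set(self.positive_controls):
            raise SortConfigError("a well cannot be both negative and positive")
        if len(controls) < 2:
            raise SortConfigError("need >= 1 negative and >= 1 positive control")
        bad = controls - set(self.well_ids)
        if bad:
            raise SortConfigError(f"control wells not on chip: {sorted(bad)}")

    @property
    def well_ids(self) -> list[str]:
        return [f"W{i + 1:02d}" for i in range(self.n_wells)]

    @property
    def control_wells(self) -> list[str]:
        return sorted(set(self.negative_controls) | set(self.positive_controls))

    @property
    def target_wells(self) -> list[str]:
        controls = set(self.control_wells)
        return [w for w in self.well_ids if w not in controls]


@dataclass
class SortPlan:
    """Deterministic assignment of target cells to non-control wells."""

    query: str
    targets: list[dict]          # cell_id, x, y, well
    controls: dict[str, str]     # well -> "negative" | "positive"
    layout: ChipLayout
    well_capacities: dict[str, int] = field(default_factory=dict)

    @property
    def n_targets(self) -> int:
        return len(self.targets)

    def well_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for t in self.targets:
            counts[t["well"]] = counts.get(t["well"], 0) + 1
        return counts

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.targets,
                            columns=["cell_id", "x", "y", "well"])


@dataclass
class SortManifest:
    """Per-ejection records of a simulated session."""

    records: list[dict]          # cell_id, well, x, y, t_offset_s, outcome
    n_collected: int
    n_failed: int
    acquisition_time_s: float

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.records,
            columns=["cell_id", "well", "x", "y", "t_offset_s", "outcome"])

    def well_cell_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in self.records:
            if r["outcome"] == "collected":
                counts[r["well"]] = counts.get(r["well"], 0) + 1
        return counts


def label_query(label: str) -> Callable[[PhenotypeCall], bool]:
    """Predicate selecting calls with a given phenotype label."""
    return lambda call: call.label == label


def build_sort_plan(
    calls: list[PhenotypeCall],
    query: Callable[[PhenotypeCall], bool] | str,
    layout: ChipLayout | None = None,
    cells_per_well: int | Sequence[int] = 1,
) -> SortPlan:
    """Build a deterministic sort plan from phenotype calls.

    Targets are the calls matched by ``query`` (a predicate, or a label
    string), taken in ascending cell_id order, and dealt one at a time
    round-robin across the non-control wells, skipping wells that have
    reached capacity.  ``cells_per_well`` is a single capacity for every
    target well, or a sequence giving each used well its own capacity
    (1–8 cells per well).
    """
    layout = layout or ChipLayout()
    if isinstance(query, str):
        qlabel = query
        predicate: Callable[[PhenotypeCall], bool] = label_query(query)
    else:
        qlabel = getattr(query, "__name__", "predicate")
        predicate = query

    targets = sorted((c for c in calls if predicate(c)), key=lambda c: c.cell_id)
    for c in targets:
        if c.position is None:
            raise SortConfigError(f"cell {c.cell_id!r} has no chip coordinates")

    avail = layout.target_wells
    if isinstance(cells_per_well, int):
        if not 1 <= cells_per_well <= 8:
            raise SortConfigError("cells_per_well must be in [1, 8]")
        n_needed = -(-len(targets) // cells_per_well) if targets else 0
        if n_needed > len(avail):
            raise CapacityError(
                f"{len(targets)} targets need {n_needed} wells at "
                f"{cells_per_well}/well but only {len(avail)} non-control "
                f"wells are available (short {n_needed - len(avail)})")
        capacities = {w: cells_per_well for w in avail[:max(n_needed, 0)]}
    else:
        sizes = list(cells_per_well)
        if any(not 1 <= s <= 8 for s in sizes):
            raise SortConfigError("each cells_per_well entry must be in [1, 8]")
        if len(sizes) > len(avail):
            raise CapacityError(
                f"{len(sizes)} wells requested but only {len(avail)} "
                f"non-control wells available (short {len(sizes) - len(avail)})")
        if sum(sizes) < len(targets):
            raise CapacityError(
                f"{len(targets)} targets exceed total well capacity "
                f"{sum(sizes)} (short {len(targets) - sum(sizes)} cells)")
        capacities = {w: s for w, s in zip(avail, sizes)}

    wells = list(capacities)
    filled = {w: 0 for w in wells}
    plan_targets = []
    wi = 0
    for c in targets:
        # round-robin deal, skipping full wells
        for _ in range(len(wells) + 1):
            well = wells[wi % len(wells)] if wells else None
            wi += 1
            if well is not None and filled[well] < capacities[well]:
                break
        else:
            raise CapacityError("well capacity exhausted")  # pragma: no cover
        filled[well] += 1
        x, y = c.position
        plan_targets.append({"cell_id": c.cell_id, "x": x, "y": y, "well": well})

    controls = {w: "negative" for w in layout.negative_controls}
    controls.update({w: "positive" for w in layout.positive_controls})
    return SortPlan(query=qlabel, targets=plan_targets, controls=controls,
                    layout=layout, well_capacities=capacities)


def simulate_session(plan: SortPlan, rng: np.random.Generator | None = None,
                     success_prob: float = 1.0,
                     acquisition_time_s: float = DEFAULT_ACQUISITION_TIME_S
                     ) -> SortManifest:
    """Simulate ejections: seeded Bernoulli outcomes, 1 ejection per slot.

    Ejections happen in plan order, spaced by the acquisition time; the
    negative-control well receives no ejections by construction.
    """
    if not 0.0 <= success_prob <= 1.0:
        raise SortConfigError("success_prob must be in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(0)
    records = []
    n_ok = 0
    for i, t in enumerate(plan.targets):
        ok = bool(rng.random() < success_prob)
        n_ok += ok
        records.append({
            "cell_id": t["cell_id"], "well": t["well"],
            "x": t["x"], "y": t["y"],
            "t_offset_s": i * acquisition_time_s,
            "outcome": "collected" if ok else "failed",
        })
    return SortManifest(records=records, n_collected=n_ok,
                        n_failed=len(records) - n_ok,
                        acquisition_time_s=acquisition_time_s)
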