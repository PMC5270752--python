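"""Plan a Raman-activated cell ejection (RACE) session on a 12-well chip.

Carotenoid-positive cells are dealt round-robin into the ten non-control
wells (a 12-well chip reserves a cell-free negative control and a positive
control), then a seeded session simulates the per-cell ejections, spaced
by the 5 s acquisition time.
"""

import numpy as np

import racescrs as rs

cohort = rs.simulate_cohort(rs.red_sea_default(300), rs.NoiseModel(), seed=1)
report = rs.classify_cohort(rs.preprocess_set(cohort))

layout = rs.ChipLayout(n_wells=12)
print(f"chip: {layout.n_wells} wells, controls {layout.control_wells}")

# Keep one chip's worth: up to 8 cells in each of the 10 target wells.
caro = sorted((c for c in report.calls if c.label == "carotenoid"),
              key=lambda c: -c.carotenoid_score)[:80]
keep = {c.cell_id for c in caro}
plan = rs.build_sort_plan(report.calls, lambda c: c.cell_id in keep,
                          layout, cells_per_well=8)
print(f"planned {plan.n_targets} ejections into "
      f"{len(plan.well_counts())} wells")

manifest = rs.simulate_session(plan, np.random.default_rng(1),
                               success_prob=7 / 30)
print(f"collected {manifest.n_collected}, failed {manifest.n_failed} "
      f"(session {manifest.records[-1]['t_offset_s']:.0f} s)")
print("cells per well:", manifest.well_cell_counts())
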