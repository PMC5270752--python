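"""Generate a synthetic single-cell Raman cohort and look at one spectrum.

The red_sea_default composition preset emulates a surface-seawater community:
33% fluorescence-dominated cells, 23% carotenoid-containing, and the rest
split between typical heterotrophs, PHB accumulators, and other compounds.
"""

import racescrs as rs

cohort = rs.simulate_cohort(rs.red_sea_default(500), rs.NoiseModel(), seed=1)
print(f"{len(cohort)} spectra on a "
      f"{cohort.grid.n_points}-point grid "
      f"({cohort.grid.values[0]:g}-{cohort.grid.values[-1]:g} cm-1)")

s = cohort.spectra[0]
print(f"first cell: {s.cell_id}, true label {s.label!r}, "
      f"max intensity {s.intensities.max():.2f} at "
      f"{s.wavenumbers[s.intensities.argmax()]:g} cm-1")

rs.write_cohort_csv(cohort, "cohort.csv")
print("wrote cohort.csv")
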