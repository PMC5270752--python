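"""Resolve carotenoid types from (v1, v2, v3) band-position triplets.

Cells whose triplets agree within 2 cm-1 (Chebyshev distance, single
linkage) carry the same carotenoid type.  The seven bundled sorted-sample
reference spectra resolve into five types; the three Pelomonas isolates
share one.
"""

from racescrs.pipeline import sorted_samples_summary

summary = sorted_samples_summary(tol_cm1=2.0)
print(f"{summary['n_samples']} sorted samples -> "
      f"{summary['n_types']} carotenoid types")
for sample, t in sorted(summary["assignments"].items()):
    print(f"  {sample:8s} type {t}")
print("type centroids (v1, v2, v3):")
for i, c in enumerate(summary["centroids"]):
    print(f"  type {i}: ({c[0]:.1f}, {c[1]:.1f}, {c[2]:.1f}) cm-1")
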