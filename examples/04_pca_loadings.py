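"""PCA of a preprocessed cohort and interpretation of the PC1 loadings.

Fluorescence-dominated cells are excluded, then the dominant loading
windows of the first principal component are reported — on a cohort rich
in carotenoid-containing cells they fall on the carotenoid resonance bands.
"""

import racescrs as rs

cohort = rs.simulate_cohort(rs.red_sea_default(500), rs.NoiseModel(), seed=1)
processed = rs.preprocess_set(cohort)
report = rs.classify_cohort(processed)

result = rs.pca(processed, n_components=5, calls=report.calls)
print("explained variance ratio:",
      [f"{r:.3f}" for r in result.explained_variance_ratio])

windows = rs.top_loading_windows(result, component=0, alpha=0.5)
print("PC1 top-loading windows:")
for w in windows:
    print(f"  {w.lo:g}-{w.hi:g} cm-1 (peak |loading| {w.peak_abs_loading:.3f})")
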