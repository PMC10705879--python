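"""Reproduce the simulation-based verification of the depth pipeline.

Generates 23 speckled B-scans (S = 0.125, swept z1/z2/M, the four surface
kinds), measures the mean Ia/Ie depths with the algorithm (curved and
aligned) and with the independent spreadsheet-style manual oracle, and
prints the trendline R^2 values and difference statistics.
"""
import enameloct as e

cmap = e.default_colormap()
frames = e.simulate_dataset(n_frames=23, seed=7, speckle_sigma_db=1.5,
                            cmap=cmap)
result = e.run_verification(frames, cmap)

print(result.table[["frame_id", "surface_kind", "d_ia_alg", "d_ie_alg",
                    "d_ia_oracle", "d_ie_oracle"]].round(1).to_string(
                        index=False))
print()
for key, value in sorted(result.summary.items()):
    print(f"{key:28s} {value:8.4f}")
# r2_alg_vs_oracle_*  : automated vs manual spreadsheet depths (expect ~1)
# r2_curved_vs_aligned_* : the two depth definitions agree for slightly
#                          curved surfaces
# diff_alg_oracle_*   : absolute differences in um (well below the 4.4 um
#                       axial pixel)
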