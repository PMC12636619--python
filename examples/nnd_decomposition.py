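"""Cross-channel nearest-neighbor distances and their two-Gaussian split.

Molecule pairs are planted 22 nm apart (one molecule per channel) amid a
diffuse background; after the full pipeline the NND histogram separates
into a short-distance pair component and a broad random-proximity
component, fitted with two Gaussians.
"""

from mfsyn import nnd, pipeline, simulate

table, image, truth = simulate.simulate_minflux_fov(simulate.nnd_recovery_config(seed=1))
report, artifacts = pipeline.run_minflux_pipeline([table], [image])

result = artifacts["nnd"]["ch_high_dcr->ch_low_dcr"]
fit = nnd.fit_nnd_histogram(result, bin_width_nm=5.0)
print(f"{result.n_source} source molecules; median NND "
      f"{float(result.distances[len(result.distances) // 2]):.1f} nm")
print(f"short component: {fit.m1:.1f} +/- {fit.s1:.1f} nm (amplitude {fit.a1:.1f})")
print(f"broad component: {fit.m2:.1f} +/- {fit.s2:.1f} nm (amplitude {fit.a2:.1f})")
# the short component should recover the planted 22 nm pair distance;
# the broad one reflects the background molecule density

rev = artifacts["nnd"]["ch_low_dcr->ch_high_dcr"]
fit_rev = nnd.fit_nnd_histogram(rev, bin_width_nm=5.0)
ratio = nnd.peak_amplitude_ratio(fit, fit_rev)
print(f"directed short-peak amplitude ratio: {ratio:.2f}")
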