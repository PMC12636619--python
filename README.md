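# mfsyn

Analysis pipeline for two-color 3D MINFLUX localization microscopy of
presynaptic proteins, with companion tools for the optical-physiology
readouts that typically accompany such studies (FRAP and iGluSnFR glutamate
imaging). It is aimed at groups quantifying the nanoscale organization of
synaptic proteins — e.g. synaptotagmin isoforms relative to the active zone —
who need the whole chain from raw localization tables to cluster statistics
as tested, scriptable Python.

## What it computes

**MINFLUX chain.** Raw localizations carry per-record quality metrics: EFO
(effective emission frequency at the probing-pattern offsets, Hz), CFR
(center/offset frequency ratio) and DCR (gate-channel count ratio separating
the two fluorophores). The pipeline applies, in order:

1. closed-interval QC filters (default EFO ∈ [100, 300] kHz, CFR ∈ [0, 0.9])
   and a strict minimum trace length (len_min = 3, i.e. ≥ 4 localizations
   per trace id);
2. spectral unmixing by a two-Gaussian fit of the DCR distribution
   (EM on the raw values; channel boundary at the equal-density crossing;
   traces labeled by majority vote of their records);
3. the axial refractive-index correction z ← 0.7·z;
4. aggregation of each trace to its centroid, with the per-axis sample SD
   as the localization-precision surrogate;
5. bassoon punctum detection on a confocal image (Otsu threshold,
   8-connected components, equivalent radius 3–20 px, eccentricity ≤ 0.9375,
   circle-overlap suppression at 0.75) and registration of traces to their
   nearest bouton centroid, trimmed at 300 nm;
6. cross-channel nearest-neighbor distances d(i) = min_j ‖x_i − y_j‖ on the
   merged bouton-relative cloud, decomposed as
   A₁e^{−(d−m₁)²/2s₁²} + A₂e^{−(d−m₂)²/2s₂²};
7. from-scratch DBSCAN (eps = 22.5 nm, minPts = 5) and classification of
   cluster centroids against the active-zone ellipse
   (x/a)² + (y/b)² ≤ 1 with 2a = 500 nm, 2b = 200 nm.

**FRAP.** Normalization FRAP(t) = (F_bleach − F_bg)/(F_nonbleached − F_bg)
and the hyperbolic recovery fit F(t′) = f₀ + (R/100 − f₀)·t′/(t½ + t′),
reporting recovery extent R (%) and half-time t½ (s).

**iGluSnFR.** ΔF/F₀ against a 500 ms pre-stimulus baseline, response
detection at > 4×SD of the baseline noise within 10 ms of each AP,
paired-pulse ratio (peak₂/peak₁), ROI response classes, cumulative release
over a 50-AP 20 Hz train, and the vesicle-replenishment rate (SVRR) as the
least-squares slope of the cumulative curve over the last 30 APs.

Every stage has a seeded synthetic generator (`mfsyn.simulate`) that emits
ground truth next to the data, so the whole chain is testable without any
external downloads.

## Worked example

```bash
python examples/minflux_pipeline.py
```

```
simulated 1590 localizations from 200 molecules
QC retained 1456/1590 records (rejected {'efo': 70, 'cfr': 64})
DCR boundary at 0.395 (components 0.250 / 0.602)
196 molecule traces; 4 bassoon puncta; 196 traces within 300 nm of a bouton center
ch_high_dcr: 9 clusters, AZ counts {'inside': 9, 'periphery': 0}
ch_low_dcr: 0 clusters, AZ counts {'inside': 0, 'periphery': 0}
```

The generator planted two-channel molecules at four boutons with ~8%
QC contaminants; the filter counts show exactly what was rejected and why.
The DCR mixture recovers the two fluorophore components (0.25 / 0.60) and
places the channel boundary between them. All planted clusters of the
cluster-bearing channel classify inside the active-zone ellipse; the sparse
companion channel stays below the DBSCAN minPts and yields no clusters.

Other examples: `examples/nnd_decomposition.py` (planted 22 nm pairs
recovered as the short NND component), `examples/frap_fit.py` (recovery %
and t½ for three mobility regimes), `examples/iglusnfr_metrics.py`
(PPR ≈ 1.24 facilitating preset; train SVRR). A thin CLI mirrors the
library: `mfsyn simulate|run|qc-filter|unmix|zcorrect|centroids|frap|glu`.

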