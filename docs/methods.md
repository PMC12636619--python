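# Methods

This note documents the models, parameter conventions, numerical choices and
known limitations of the package, in the order of the analysis chain.

## Localization model and units

A localization record is (fov_id, tid, t, x, y, z, EFO, CFR, DCR). All
coordinates are nanometers in a right-handed, FOV-local frame; EFO is stored
in Hz internally (the CLI accepts kHz, the unit the acquisition software
prints). Records sharing (fov_id, tid) belong to one emission event ("trace")
of a single fluorophore. Timestamps are carried through I/O but no
implemented statistic uses them. Confocal pixel centers map to
((col + 0.5)·px, (row + 0.5)·px) nm; the half-pixel convention keeps
centroid arithmetic symmetric and avoids 0/1-based ambiguity.

## QC filtering

EFO and CFR windows are **closed** intervals (defaults 100–300 kHz and
0–0.9): boundary records are retained, which matters only on sets of measure
zero for continuous data. The trace-length bound is **strict**: len_min = 3
keeps traces with ≥ 4 localizations. Filtering acts at record level for
EFO/CFR and at trace level for length; rejected counts are reported per
criterion (EFO checked first) so input = retained + Σ rejected always holds.
Filtering, unmixing and the Z correction commute, so their order does not
affect results; the canonical order (QC → length → unmix → z → aggregate) is
the one the stage runner uses.

## DCR spectral unmixing

The DCR distribution of a two-fluorophore sample is modeled as a
two-component 1D Gaussian mixture fitted by EM on the raw values (no
histogram binning, hence no bin-width sensitivity). Initialization is a
1D 2-means split, or a user-supplied mean pair. The channel boundary is the
equal weighted-density crossing between the component means (found by
Brent's method), not the midpoint. Degenerate fits (component weight
< 0.02, or non-convergence after 500 iterations) raise an error that
advises a manual boundary. Records are assigned to the component with the
higher posterior density; posterior odds below `ambiguity_odds` (default 1,
i.e. only exact ties) are discarded, and the trace channel is the majority
vote of its records, ties discarded — a trace is one fluorophore, so
per-record splitting would be physically wrong. Which fluorophore (e.g.
FX640 vs FX680) is the high-DCR component depends on the instrument's gate
ordering and is a configuration entry, never hard-coded.

## Axial correction

The refractive-index mismatch between coverglass and aqueous buffer makes
the measured focal position appear shallower than it is; multiplying
measured z by 0.7 restores the physical position. The generator therefore
pre-distorts true z by 1/0.7 so the correction stage is exercised in the
physically meaningful direction. The correction is linear and commutes with
every other stage.

## Trace aggregation and resolution estimate

Each trace collapses to its per-axis mean; the per-axis sample SD
(n−1 denominator) is the working localization-precision surrogate. The
resolution estimate is the mean of trace spreads, with the standard error
taken across FOV means when several FOVs are pooled (mean ± SEM reporting)
or across traces otherwise. The sample SD underestimates σ for short traces
by the known c4(n) factor (≈ 0.97 at n = 10); an optional bias-corrected
mode divides each spread by c4(n). The naive mode is the default because it
matches how per-trace scatter is conventionally reported; recovery tests use
the corrected mode, which retrieves generating noise of
(5.39, 5.14, 3.01) nm per axis within 5% from 500 traces of 10
localizations.

## Nearest-neighbor distances

NND is computed between **trace centroids** (one molecule each), not raw
localizations, in 3D after Z correction (a 2D mode exists for sensitivity
analysis). The histogram (bins from zero, default width 10 nm; width is a
reported analysis choice) is fitted with two Gaussians by least squares on
the bin counts, initialized from the two most prominent local maxima of a
lightly smoothed histogram that are at least three bins apart. If only one
mode is detectable the fit falls back to a single Gaussian and says so; a
fallback fit cannot enter a peak-ratio comparison. The directed peak ratio
compares short-component amplitudes by default (peak heights); an area mode
(A·s·√2π) is provided because height and area ratios differ when the two
directions have unequal widths.

## Puncta detection and registration

Bassoon puncta are detected as: Otsu threshold (256-bin histogram;
the raw bin-center threshold is snapped to the midpoint between the two
intensity classes it separates so that `data > threshold` reproduces the
variance-optimal partition exactly), 8-connected components,
intensity-weighted centroids, equivalent radius √(area/π) within 3–20 px,
moment-ellipse eccentricity ≤ 0.9375, and suppression of the dimmer of any
pair whose bounding circles overlap by more than 0.75 of the smaller
circle's area. The overlap denominator and the moment-based eccentricity are
our documented readings of those filter parameters; the original detection
plugin's internals are not public, so any construction honoring the stated
parameters is equally defensible — ours is oracle-testable.

Traces are assigned to the nearest punctum in XY (centroids are planar),
re-expressed relative to (punctum x, punctum y, centroid_z) with
centroid_z = 0 by default (the confocal focal plane), and trimmed at a 3D
radius of 300 nm. The trim can alternatively be applied at cluster level
(`registration_cut="cluster"`), reflecting an ambiguity in whether distant
molecules or distant clusters should be excluded; trace level is the
default.

## DBSCAN and active-zone classification

DBSCAN is implemented from first principles because it is the load-bearing
spatial statistic: a point is core iff its closed eps-ball (including
itself, the standard convention; a `count_self` flag toggles the strict
neighbor reading) contains ≥ minPts points; clusters grow from core points
in scan order; border ties go to the first-claiming cluster, making labels
deterministic for a given input order while the partition is
permutation-invariant up to border ties. Defaults eps = 22.5 nm,
minPts = 5 (valid range 5–8). Cluster centroids are unweighted means of
member positions.

The active zone is an ellipse of 500 × 200 nm axis diameters centered on
the bouton centroid, axis-aligned by default and boundary-inclusive
("within the boundary" reads inclusively); orientation is configurable, and
an orientation-free variant (PCA alignment before the elliptical-radius
test) exists but is off by default since the fixed ellipse matches how such
summaries are conventionally drawn.

## FRAP

Normalization is frame-wise
(F_bleach − F_bg)/(F_nonbleached − F_bg), which is invariant under common
affine rescaling of all three channels. The recovery fit
F(t′) = f₀ + (R/100 − f₀)·t′/(t½ + t′) fixes the floor f₀ at the first
post-bleach sample — freeing it creates a degeneracy with R on short traces
(a 3-parameter mode exists behind a flag). The generator reads out its
first post-bleach frame 1 ms after the bleach, i.e. essentially at the
floor, then at 4 s intervals (15 frames/min); with that convention the fit
recovers noiseless generating parameters to three significant figures for
(R, t½) ∈ {(74, 18), (62, 61), (18, 150)} (%/s) and the median fitted R
stays within 2 points of truth under σ = 0.02 frame noise.

## iGluSnFR metrics

ΔF/F₀ uses the mean of the first 500 ms as F₀. The acquisition software's
"two-tailed background subtraction" is tool-specific and not publicly
specified; here, background handling is an explicit, bypassable contract —
the mean of a supplied dark trace is subtracted, otherwise nothing.
Noise SD is computed per ROI on its own baseline. A response to an AP is
the maximum ΔF/F₀ within 10 ms after the stimulus (inclusive window ends)
and counts as detected when it exceeds 4× the noise SD; peaks are in-window
maxima, not fitted amplitudes, matching the thresholded-peak definition.
PPR = peak₂/peak₁ is defined only when both APs are detected (class
`both`); otherwise the ROI class records the detection pattern and PPR is
absent, never zero. The train analysis applies the same per-AP criterion;
undetected APs contribute zero to the cumulative curve, and SVRR is the OLS
slope of the cumulative signal over the last 30 stimuli.

## Synthetic generators

The generators define the study conditions, with all randomness derived
from a mandatory seed (identical config + seed ⇒ byte-identical output).

*MINFLUX FOV*: boutons on a jittered grid (2 µm spacing); per bouton,
cluster centers sampled inside a shrunken AZ ellipse (elliptical radius
≤ 0.8) plus optional periphery centers at 1.3× the elliptical radius,
constrained to remain inside the 280 nm analysis ball so they survive
registration (they model clusters just outside the AZ boundary, not outside
the bouton). A configurable minimum 3D center separation (rejection
sampling) makes planted clusters individually resolvable where a recovery
experiment requires it. Molecules scatter around centers with an 8 nm SD;
companions of the other channel sit at a fixed 22 nm from randomly chosen
members; a diffuse two-channel background fills the ball. Traces have
len_min + 1 + Poisson(4) localizations (so defaults never silently empty
the QC), per-axis noise (5.39, 5.14, 3.01) nm, DCR from the channel's
Gaussian (0.25 ± 0.05 / 0.60 ± 0.07), log-normal EFO clipped into the QC
window, Beta-distributed CFR in [0, 0.9], and configurable contaminant
fractions drawn strictly outside the QC bounds. The confocal image renders
one symmetric Gaussian punctum (σ = 3 px, inside the 3–20 px radius filter)
per bouton at 80 nm pixels with additive Gaussian noise.

Two purpose-built configurations fix the geometry of the recovery studies:
`nnd_recovery_config` plants isolated cross-channel pairs 22 nm apart
(single-molecule clusters with one companion each, ≥ 100 nm apart) over a
sparse background, and `az_geometry_config` plants 12 clusters per FOV
(11 inside the AZ ellipse, 1 at 1.3×, ≥ 70 nm apart, cluster SD 6 nm).
Problem sizes throughout (20 seeds × ~1,600 localizations per FOV;
500 traces for resolution; 200 ROIs for PPR; 100 FRAP replicates) are the
package's chosen desk-scale study conditions: large enough for stable
medians, small enough to run anywhere in seconds.

*What the generators do not emulate*: fluorophore blinking/photophysics
(trace structure is imposed, not kinetic), realistic PSFs or camera noise,
chromatic offsets between the confocal and MINFLUX frames, drift (assumed
corrected upstream by fiducial stabilization), and epitope-linkage error
(~15 nm in antibody-labeled samples — planted distances are
fluorophore-to-fluorophore). Passing recovery tests therefore demonstrates
the correctness of the estimators under the stated statistical model, not
robustness to those instrument effects. One consequence worth naming: the
broad "random proximity" NND component's position tracks molecule density —
in the compact simulated boutons it sits near 50–100 nm, whereas sparser
real preparations show it near 150 nm; the short planted-pair component is
density-insensitive and is the quantity the recovery study asserts.

## FRAP / iGluSnFR generator conditions

FRAP traces use a constant reference (1100) and background (100) channel so
the normalized trace is exactly the hyperbolic model plus noise. The
iGluSnFR presets run at 100 Hz for 3.5 s with stimuli from 0.5 s: the
facilitating preset is two APs at 20 Hz with amplitude ratio 1.24 and
certain release; the depressing preset is 50 APs with per-AP amplitude
decaying as 0.2 + 0.8·e^{−k/5} (steady state 0.2 ΔF/F₀ per AP). The sensor
transient decays exponentially with τ = 10 ms (a fast-variant decay), so
the residual of one response under the next 50 ms later is e⁻⁵ ≈ 0.7% —
visible as a ≤ 0.01 bias in otherwise-exact PPR checks.

## Degenerate inputs and tie-breaks

Empty tables pass through filters and abort the pipeline at the first stage
that needs data, with the stage named. Single-localization traces cannot
yield a spread and are excluded from aggregation with a warning. Records at
exactly the DCR boundary are discarded as ties by policy. Constant images
cannot be thresholded. A trace equidistant from two puncta takes the lower
punctum index (argmin). All floating-point comparisons against stated
bounds (300 nm radius, AZ ellipse) are inclusive.

## Known limitations

- Whether the original analyses filtered EFO/CFR per record or per trace is
  not determinable from their description; record-level is implemented.
- The resolution-estimation procedure behind per-axis "fluorophore
  resolution" values is likewise unstated; the per-trace SD averaged across
  traces/FOVs is this package's surrogate.
- DBSCAN minPts within the quoted 5–8 range, the NND histogram bin width,
  and whether the directed peak comparison uses heights or areas are
  analysis choices surfaced as parameters with the defaults documented
  above.
- The pipeline assumes the confocal and MINFLUX frames are pre-aligned
  (single-instrument acquisition); no chromatic or affine calibration is
  performed.
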