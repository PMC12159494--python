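# Methods

`vasowave` analyses mesoscale cerebral-blood-volume (CBV) movies — Power
Doppler image stacks whose intensity is proportional to CBV, sampled at
0.4 s per frame with 100 μm pixels — for the signatures of vasomotion:
quasi-sinusoidal haemodynamic oscillations around 0.1 Hz that can
propagate through the cortical vasculature as travelling waves. This
note records the models, the parameter choices and their rationale,
what the synthetic data generator does and does not emulate, and the
numerical decisions a maintainer would want to know.

## Analysis model

**Bands.** Two fixed temporal bands are used throughout: a wide
resting-state band (0.0008–0.2 Hz) before functional-connectivity and
PCA stages, and the vasomotion band (0.08–0.15 Hz) for fALFF, event
detection and dynamic connectivity. Filtering is a 4th-order Butterworth
applied forward–backward (zero phase) per pixel. On a 20-min record the
0.0008 Hz low cut sits at 1/duration, so the high-pass leg removes
little beyond the mean; it is implemented as stated for fidelity to the
analysis constants. Band-pass filtering is linear and purely temporal,
so it commutes with ROI averaging — which is why it is immaterial
whether ROI means are extracted before or after filtering.

**fALFF.** The fractional amplitude of low-frequency fluctuations is
the sum of one-sided DFT amplitudes over the band of interest divided
by the sum over all positive frequencies (DC excluded). The
amplitude-sum ratio is the default, following the REST-toolbox lineage
of the measure; a squared-amplitude (power) ratio is available via
`SpectralConfig(power_ratio=True)`. ROI fALFF is computed on the
ROI-mean series (signal extraction before analysis), not as the mean of
pixel fALFFs. A linear detrend precedes the FFT by default. No
filtering precedes fALFF: the raw movie is used. Under a white-noise
null the expected value is the band's share of the positive-frequency
axis, (0.15−0.08)/1.25 ≈ 0.056 — the calibration the acceptance suite
checks. Maps are thresholded at fALFF > 0.075 for display.

**Functional connectivity.** Static FC is the Pearson correlation
between ROI-mean series on the wide band; Fisher Z (atanh, with r
clipped to ±(1−10⁻⁷)) precedes group differencing, and differences are
reported both as Δz and back-transformed Δr. Dynamic seed connectivity
correlates the seed-ROI mean with every pixel of the target ROI inside
a sliding window of 15 frames (6 s) advanced 1 frame at a time,
averaging r (not z) over the target ROI per window to match the
displayed heatmap convention; z-aggregation is a switch. Plain Pearson
per window, no extra per-window normalisation.

**Oscillatory modes (group-covariance PCA).** Each acquisition is
band-passed, centred by its global (all-pixel, all-frame) mean, and
divided by its global standard deviation — one scalar per acquisition,
chosen over pixelwise z-scoring because the analysis contrasts
amplitude across regions, which pixelwise scoring would erase
(pixelwise scoring remains possible by preprocessing externally). The
pixel×pixel covariance matrices of a group's acquisitions are averaged;
eigenvectors of the mean covariance, in descending eigenvalue order,
are the spatial modes. Components with eigenvalues above 0.1 are
retained, capped at 10; with the global-sd normalisation the total
eigenvalue mass is approximately the pixel count, so the 0.1 threshold
operates on the covariance of unit-global-variance data. Explained
fractions are eigenvalues over the eigenvalue sum. Eigenvectors are
oriented so their maximum-absolute element is positive, for
reproducible map polarity. Temporal signatures are projections of each
acquisition on the modes; their amplitude spectra are averaged across
acquisitions. Reconstructions sum mapᵢ × projectionᵢ(t) for i ≤ k and
report the residual variance fraction.

**Event detection.** The detector finds spatiotemporal CBV *increases*
in the vasomotion-band movie:

1. per-pixel robust z: band value divided by a noise sd estimated as
   `1.4826·MAD(Δ)/√2` from temporal first differences — first
   differences discount slow in-band signal (a 0.1 Hz sinusoid at
   2.5× the noise sd inflates the estimate by <10 %, where the plain sd
   would nearly double). The differences are taken on the **raw**
   movie: on narrowband data neighbouring frames are correlated ≈0.96
   and a difference-based estimate would shrink ~5-fold, turning the
   z>5 criterion into ~1 noise sd. Zero-variance pixels get an
   epsilon-floored sd with a warning;
2. spatial Gaussian smoothing, σ = 0.5 px per frame (interpreting the
   source tool's "smoothing parameter of 0.5" as a spatial sigma — an
   interpretation, flagged as such);
3. threshold z > 5; spatiotemporal connected components with
   8-neighbour spatial adjacency and frame-to-frame linking whenever
   footprints overlap by ≥1 px (equivalently: same-pixel temporal
   adjacency); components whose largest single-frame footprint is
   below 15 px are discarded;
4. components holding two z-maxima separated by a saddle below 50 % of
   the lower peak are split by marker-based watershed (saddle edges
   merged highest-first so a shallow bridge basin cannot chain two
   genuine peaks — the 50 % figure is a heuristic);
5. an optional minimum peak-ΔCBV% gate stands in for the source tool's
   arbitrary-unit intensity threshold; it is disabled by default
   because the z-score criterion is the operative significance test.

**Event features.** The centroid track is the z-weighted centroid of
each frame's footprint, using the smoothed z for weighting and an
interior 3-point boxcar on the track (endpoints kept, so straight
tracks — and the arithmetic of the propagation definition — are
unchanged); raw-z weighting left enough frame-to-frame jitter to push
slow waves' displacement sums over the dynamic threshold.
Propagation is the sum of consecutive centroid displacements;
events travelling more than 5 px are dynamic, the rest static.
Peak amplitude is the maximum ΔCBV% (relative to the whole-series
mean) inside the footprint. The delay map assigns each footprint pixel
its time of maximal z relative to event onset — peak timing rather
than onset timing, because peaks are robust at realistic noise levels
(onset-based delay would need a further threshold). Scan summaries
average features over dynamic events only and report the percentage of
dynamic events.

**Wave speed.** `EventRecord.speed_mm_s` is propagation ÷ event
duration. For a single raised-cosine cycle this ratio is structurally
biased: the zero-phase band filter spreads every pixel's transient over
~±1/bandwidth, so the detected supra-threshold lobe replays the full
trajectory inside a shortened window (ratio speeds run ~+150 % at
0.1 mm/s and ~−40 % at 0.8 mm/s). The recommended estimator for
sustained waves is `events.train_speed`: one detected event per carrier
cycle, positions (mean centroids, projected on the displacement axis)
regressed on peak times across the train. It recovers 0.1–0.8 mm/s
within ±16 % (mostly ±5 %) and is what the speed-recovery experiment
uses.

**Trajectory taxonomy.** Events are grouped two ways. Descriptively:
binarised delay maps are SVD-reduced (component cap min(3000, rank); at
desk scale rank ≪ 3000) and k-means clustered into 4 spatial groups,
each split in 2 by k-means on the direction vectors — the delay map's
column profile and row profile each reduced to a signed least-squares
slope (the slope choice is an interpretation; signed end-differences
behave similarly on clean gradients). And by explicit rule, because
reproducible semantic names need one: dynamic events are labelled by
the majority tissues of their earliest and latest delay quartiles —
cortex→hippocampus and its reverse get the hippocampal labels,
cortex↔deep subcortex (either direction) is cortico-subcortical (a
cortex→midbrain wave transits the hippocampal band, so quartile
endpoints rather than mere occupancy decide), within-cortex events
spanning both hemispheres with a cross-midline delay ordering are
trans-hemispheric, and remaining cortical events are medio-temporal or
temporo-medial by the sign of the delay slope against distance from the
midline. Directional calls must explain at least one frame period of
delay across the event; everything else, and all static events, is
unclassified. Time-reversing a movie exactly swaps the direction-paired
labels. Pattern tables report per-scan percentages over all events and
renormalised over the six travelling classes.

**Stimulation.** ΔCBV% is computed against the initial 30-s rest; the
four 30-s flicker blocks are onset-aligned and averaged; the scalar
response is the mean ΔCBV% over stimulation epochs. Note the 45-s
inter-block rests are not multiples of the 0.4-s frame, so later block
onsets round to the neighbouring half-frame.

**Artifact-free windows (awake protocol).** The earliest maximal run of
samples below median + 5 robust sd (1.4826·MAD) of the ROI series, at
least 120 s long; the 5-sd default is the package's choice, the
analysis constant being unpublished.

## Synthetic movie generator

The generator emulates the statistical structure the analysis assumes,
not ultrasound physics: it starts at the Power Doppler movie level
(no plane-wave compounding or clutter filtering), on an anatomically
schematic bilateral atlas whose topology — five cortical ROIs in
medial→temporal order, hippocampus and midbrain below, mirrored
hemispheres — is what the pattern labeller needs.

* **Baseline + noise.** Per-region constant baselines (cortex 100,
  subcortex 70–90, background 40, arbitrary units) plus per-pixel
  temporal noise: white (sd 1.0) and spectrally shaped 1/f (sd 0.8,
  exponent 1.0). The noise magnitudes are the package's calibration:
  they place the predicted detector z of 10–30 % CBV waves astride the
  z>5 threshold (z≈5 near 17 %, z≈8 near 28 %), the regime the
  detection-recovery experiments require.
* **Events.** Modulations compose multiplicatively on the baseline
  (Power Doppler is proportional to CBV; relative change is the
  analysed quantity). The carrier is a raised cosine — nonnegative, so
  injected events are CBV increases, matching the positive-peak
  detector. Spatial footprints are Gaussian bumps hard-truncated at 3σ:
  outside the truncated footprint the movie equals the baseline
  exactly. Travelling waves advance the bump centre along a waypoint
  path; an optional motion window confines the motion to the central
  portion of the carrier cycle (pattern templates use 30–70 %, so both
  trajectory endpoints are visible to a z>5 detector). Each event's
  predicted detector z is logged: injected relative amplitude × local
  baseline × the measured band-filter gain of its carrier ÷ the
  predicted first-difference noise sd.
* **Cohorts.** The VEH-like arm carries sparse (0.3/min) low-amplitude
  (8–15 %) medio-temporal/temporo-medial waves and occasional static
  events. The LPS-like arm adds sustained quasi-periodic oscillation
  trains — four Gaussian nodes (σ 1.2 mm) per hemisphere along the
  cortical ribbon, 50–70 % amplitude, 8-cycle trains at 0.10–0.15 Hz
  with 4–12 s gaps, adjacent nodes phase-lagged by 2 s (a slow
  travelling phase gradient) — plus waves of all six patterns at
  20–35 %. The train parameters come from the variance budget the
  oscillatory-mode contrast imposes: band-filtered noise leaves ≈1.1
  variance units per pixel, and four coherent 50–70 % nodes at σ=12 px
  contribute ~10² times the summed noise variance in ≤10 spatial
  modes, which is what drives the >99 % cumulative explained variance
  at 10 components in this arm while the sparse-wave arm stays below
  90 %. The fitted pattern-wave speeds follow from path length ×
  carrier frequency and land in the physiological 0.1–0.8 mm/s range at
  desk-scale grids (the longest subcortical template can slightly
  exceed it on fine grids).
* **Stimulation.** First-order rise/decay kinetics toward a plateau of
  the requested amplitude during each block (rise 0 gives an ideal
  plateau); optional superimposed waves emulate oscillations persisting
  during stimulation.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: vascular anatomy (waves follow geometric
paths, not vessels), movement artifacts beyond optional spikes,
physiological confounds (cardiac, respiratory), spatially correlated
noise, registration error, and the skewed speckle statistics of real
Power Doppler. The nonnegative carrier also gives wave trains a slow
on/off envelope that loads low frequencies in the wide band (visible in
component spectra); real CBV oscillations fluctuate about their mean.
Ground-truth recovery here validates the machinery, not the biology.

## Problem sizes and numerical choices

Experiments run at desk scale by the package's choice: 64×64×1500
(6.4 mm, 10 min) for cohort-level contrasts, 128×128×3000 (the full
acquisition geometry) for detection-recovery and noise-null runs,
128×128×900 for speed ladders. Covariance eigendecomposition is dense
`eigh` on the pixel×pixel matrix (≤4096² at desk scale); the time×time
Gram dual is the escape hatch for larger grids. Detector connectivity
uses `scipy.ndimage.label` with a structure that encodes 8-neighbour
spatial and same-pixel temporal adjacency — provably identical to
linking frame-wise components that overlap by ≥1 px, and checked
exactly against a brute-force flood fill. k-means uses a fixed seed
with 10 restarts. Degenerate cases: single-frame events report speed 0
with a flag; empty scans yield flagged summary rows; zero-variance
series raise naming the ROI; constant movies are rejected by the PCA
preprocessor (sd below 10⁻⁹ of the input scale counts as constant).

## Known limitations

Single-event ratio speeds are biased at the range edges (see above);
use `train_speed` for sustained waves. The watershed saddle rule is a
heuristic with a fixed 50 % fraction. The rule labeller's occupancy
quartile (25 %) and one-frame delay margin are fixed; heavily
overlapping simultaneous events can confuse the per-event matching.
The 0.0008 Hz low cut is nominal at 10–20-min records. fALFF's "entire
frequency range" excludes only DC; bins below 0.0008 Hz are kept
(negligible at 20-min records, where only the first bins lie below).
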