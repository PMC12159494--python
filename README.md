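# vasowave

Detection and quantification of ~0.1 Hz vasomotor oscillations and
travelling haemodynamic waves in mesoscale cerebral-blood-volume (CBV)
movies — functional ultrasound Power Doppler stacks sampled at 0.4 s
per frame with 100 μm pixels, whose intensity is proportional to CBV.

It is written for researchers analysing resting-state or
stimulation-evoked haemodynamics in rodent functional ultrasound (or
comparable mesoscopic) data, and for anyone who needs a ground-truthed
benchmark for vasomotion analysis: a synthetic movie generator injects
known waves into realistic noise so every stage can be validated
end to end.

## What it computes

Given registered movies and a bilateral ROI atlas:

* **fALFF** — fractional amplitude of low-frequency fluctuations:
  Σ|X(f)| over the vasomotion band (0.08–0.15 Hz) divided by Σ|X(f)|
  over all positive frequencies, per pixel and per ROI, with
  fALFF > 0.075 maps.
* **Functional connectivity** — Pearson r between ROI series
  (band-passed 0.0008–0.2 Hz), Fisher-Z transformed (z = atanh r) for
  group differences; and dynamic seed connectivity in 15-frame (6-s)
  sliding windows stepped 1 frame.
* **Oscillatory modes** — PCA of the group-mean pixel×pixel covariance:
  eigenvalues λᵢ (retained if λᵢ > 0.1, up to 10), spatial maps,
  temporal projections with amplitude spectra, reconstructions, and the
  cumulative explained variance Σᵢλᵢ/Σλ.
* **Travelling-wave events** — robust z-scoring (first-difference MAD
  noise estimate), z > 5 threshold with 0.5-px smoothing and a 15-px
  size gate, spatiotemporal connected components; per event: centroid
  track, propagation distance (Σ‖c_{t+1}−c_t‖), peak ΔCBV%, delay map,
  speed; events propagating >5 px are *dynamic* (travelling), the rest
  static.
* **Trajectory taxonomy** — six pattern classes (medio-temporal,
  temporo-medial, trans-hemispheric, cortico-subcortical,
  cortico-hippocampal, hippocampo-cortical, plus unclassified/static)
  via SVD + k-means clustering of binarised delay maps and an explicit
  atlas-occupancy/delay-order rule.
* **Stimulation responses** — ΔCBV% against the pre-stimulus rest,
  block-aligned averages over 4×30-s flicker blocks.

Full model descriptions and parameter rationale: `docs/methods.md`.

## Worked example

Simulate a two-arm cohort (a saline-like arm with sparse small waves;
an inflammation-like arm with sustained high-amplitude oscillation
trains) and run the analyses — these are the `analysis/` drivers:

```sh
cd analysis
python 01_simulate_cohort.py
python 04_pca_modes.py
python 05_detect_waves.py
```

which prints (seed 42, 64×64×1500 cohort, 128×128×1500 recovery scans):

```
LPS: 72 injected events over 3 scans, mean amplitude 47.3% CBV, 81% travelling
VEH: 13 injected events over 3 scans, mean amplitude 10.8% CBV, 38% travelling
...
VEH: 10 retained components; first 10 explain 59.9% of variance; ...
LPS: 10 retained components; first 10 explain 99.9% of variance; ...
...
36 injected events over 3 scans; of the 15 with predicted z >= 8, 100% were detected.
Dynamic/static classification (>5 px rule) correct for 100% of detected high-z events.
Peak-amplitude recovery: median relative error 5%.
```

Reading: the oscillation-rich arm's variance collapses onto a handful
of vasomotion-band modes (99.9 % in 10 components vs 59.9 % for the
control arm), and the event detector recovers essentially all injected
waves whose predicted significance clears z ≈ 8, classifying travelling
vs static correctly at the 5-pixel rule. Each driver writes its tables
under `results/`.

The same stages are scriptable from a shell:

```sh
vasowave simulate --arm LPS --n-scans 3 --seed 1 --out-dir scratch/sim
vasowave demo --seed 1 --out-dir scratch/demo
```

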