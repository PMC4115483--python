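# Methods

This note records the model, the defaults and the design choices behind
`tonguetrack`, in the spirit of a package methods appendix. Nothing here
states a result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Problem setting

Midsagittal MR frames of the vocal tract show the oral airway as a dark
region between the tongue surface and the palate. The quantity of interest
is the tongue's upper boundary per frame, from which three articulatory
parameters are measured in millimetres: TTCL (distance from the tongue tip
to the palate trace), TBCL (minimum distance from the posterior tongue
half to the palate trace) and LA (distance between the lip landmarks).
Frames are 256×256 at 1.057 px/mm by default; coordinates are 0-based
(row, col) with anterior toward smaller columns. All geometry stays in
pixels until measurement time.

## Preprocessing

1. **Seed threshold.** th_I = f·(IM_max − IM_min) + IM_min with f = 0.06.
   The factor is deliberately close to the dark floor: it is highly
   specific to airway pixels but (a) fragile under noise, because IM_min is
   an extreme value, and (b) conservative at blurred edges, whose smoothed
   intensities rise above it.
2. **Denoising.** Before thresholding, the frame is smoothed with an
   anisotropic Gaussian (default σ = 0.7 px across rows, 4 px along
   columns). The airway is an elongated, roughly horizontal band, so
   strong along-band smoothing buys a ~6× noise reduction while the weak
   cross-band component preserves airways as thin as ~6 px — an isotropic
   kernel large enough for the same noise reduction would erase them.
   The threshold is computed on the smoothed image; with σ = 0 the step
   reduces to the plain threshold.
3. **Hysteresis growth.** The seed mask grows by 8-connected propagation
   into pixels below 30% of the intensity range (computed on a lightly
   smoothed copy, σ = 0.7). This is the classic double-threshold remedy
   for the seed threshold's edge bias: only regions anchored by a dark
   seed survive, but their extent recovers the true boundary. Measured on
   the phantom airway, intersection-over-union rises from 0.70 to 0.89.
4. **Cleanup.** A disc(1) closing consolidates speckle left by per-pixel
   thresholding in noisy airways, then a disc(1) opening removes isolated
   specks. Components are labelled with 8-connectivity and filtered by
   size (min 50 px) and by intersection with the jaw segment dilated by a
   disc(5). The jaw segment is an input (phantom truth or annotation);
   no automatic jaw detection is attempted.
5. **Initial points.** The largest surviving component — preferring the
   frame with the largest oral cavity when a sequence is available — is
   closed with a disc(3), and its per-column extreme-row boundaries are
   resampled at approximately equal arc length: 30 movable points from the
   upper boundary, 15 fixed points from the lower. The counts are not
   dictated by the measurement protocol; 30 gives ~5 px spacing across a
   159-column airway, and the fixed points only pin the known side of the
   cavity.

## Snake

Energies are used literally as written in the README. Notable choices:

* **No per-neighbourhood normalisation.** The classic greedy formulation
  rescales each term to [0, 1] within the neighbourhood; the weights
  α = 1.2, β = 1, γ = 5.2 were evidently tuned against unnormalised terms
  (the image term dominates at edges by orders of magnitude, which is what
  anchors points there), so the literal form is the default and the
  normalised variant sits behind `normalize_neighborhood`.
* **Elasticity sign.** E_ela = d̄ − distance rewards stretching beyond the
  mean spacing. On flat image regions this makes end points drift
  laterally by a pixel per iteration until the stopping rule fires; on
  edges the image term pins the points regardless. This is the literal
  reading and is kept.
* **d̄** is the mean distance over consecutive pairs of the whole polyline
  (fixed + movable), recomputed once per sweep, not per point.
* **Sweep order** is serial, anterior→posterior over the movable points,
  each update seeing the moves already made in the sweep — the greedy
  algorithm's nature. Ties in the neighbourhood argmin keep the current
  position (it is evaluated first), then row-major candidate order.
* **Endpoints.** The last movable point, which lacks a successor, reuses
  its predecessor for the curvature term (second difference of a
  reflected neighbour) rather than assuming zero curvature.
* **Stopping.** The rule "fewer than th_stop points moved, th_stop = n/10"
  is the default (`stop_metric="count"`). Because the displacement-norm
  reading of the criterion is also defensible, it is implemented behind
  `stop_metric="displacement"` (mean per-point displacement below
  `stop_fraction` px); both halt within `max_iter` = 200.

## Articulatory measurement

TTCL and TBCL lack a universal operational definition; this package's
convention is: tip = anterior-most contour point; body = posterior half of
the contour by arc length (`tip_fraction` = 0.5); distances are Euclidean
point-to-palate-trace by default, with perpendicular distance to the
ANS–PNS line available as `distance_mode="plane"`. Summary statistics use
the sample (n−1) convention, which exactly reproduces the bundled
published table; rounding to 4 decimals happens only at output. A
single-frame summary reports zero spread and sets a `degenerate` flag.

## Acoustics

The formant extractor is plumbing around standard LPC: resample to
2·max_formant (5000 Hz ceiling for male, 5500 Hz for female), pre-emphasis
0.98, Hann window, autocorrelation LP of order 2·n_formants + 2 = 12,
polynomial roots → frequencies and bandwidths, keep resonances in
(0, max_formant) with bandwidth < 400 Hz. Windows are consecutive and
non-overlapping, matching the rule n_points = ⌊duration / 25 ms⌋; the
30 dB dynamic range acts as a silence gate on window RMS relative to the
loudest window. The per-formant standard deviations are across windows.
Correlation reports Pearson r and the least-squares slope per gender for
(TBCL, F1) and (TTCL, F2), requiring at least three paired vowels.

## Phantom generator

The image phantom renders bright tissue (220), a brighter palate band
(245), and dark (10) airway, lip-gap, jaw-band and speckle regions, then
applies Gaussian blur (σ = 1 px, a surrogate for motion blur) and optional
additive Gaussian noise clipped to [0, 255]. Frames are rendered
vertically flipped relative to radiological display — the palate at larger
row indices — so the tongue surface is the *upper* (low-row) boundary of
the airway, the side the movable snake points track. Tongue postures for
the six Malay vowels are hand-designed monotone (PCHIP) profiles of
"closeness to palate" chosen so the qualitative relations hold by
construction: /a/ has the largest airway and lip aperture, /i/ the lowest
tip and body constriction distances, /u/ the smallest lip aperture, back
raising dominates /o/, /u/, /e/ and front raising /i/, /ə/. The exact
control points are package fixtures, not measured anatomy. Sequences add
a smooth random per-frame perturbation bounded by `jitter` px. Each
truth object carries the analytic tongue contour, palate trace, landmarks,
airway/jaw masks and the measurements computed from that geometry with the
same formulas the pipeline uses.

The audio phantom is an impulse train at f0 shaped by a one-pole glottal
roll-off (−6 dB/oct, coefficient 0.98 — the net source slope of voiced
speech after lip radiation, and the counterpart of the analyzer's
pre-emphasis) and a cascade of second-order resonators; default
bandwidths are 60 + 20k Hz for the k-th formant.

What the phantom does *not* emulate: MR physics (k-space, T1 contrast,
Rician noise), anatomical variability, through-plane motion, consonantal
context, and jitter in f0 or amplitude. Passing tests on phantoms
therefore demonstrate the correctness and noise robustness of the
algorithms, not clinical performance on real scans.

## Problem sizes

The validation suite uses 256×256 frames, 24 phantom frames per noise
level (six vowels × four seeds), 20 synthesized vowels of 0.5 s at
20 kHz, and 1000-case brute-force oracles for the energy and morphology
kernels; the end-to-end pipeline default is six vowels × seven frames,
mirroring the seven consecutive frames per vowel of the reference
protocol.

## Known limitations

* The snake tracks only within the column span the cavity mask covers; a
  heavily under-segmented anterior region shortens the tracked contour and
  biases TTCL upward-anterior (visible in the README example: TTCL 22.7 mm
  tracked vs 24.7 mm analytic).
* Eq-style thresholding keys on global extremes; gross intensity artefacts
  (e.g. a zero-valued burn-in row) would shift the threshold.
* The tip/body split at half arc length is a convention; constriction
  measures are sensitive to it for extreme postures.
* Formant estimation assumes quasi-stationary vowels; it is not a general
  formant tracker and makes no claim of replicating any particular
  software's estimates bit-for-bit.
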