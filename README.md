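# tonguetrack

Tracking the tongue surface in midsagittal MR image sequences, and turning
the tracked contours into articulatory phonetics measurements.

Dynamic MRI of the vocal tract shows how the tongue, lips and palate shape
vowels, but tongue motion during acquisition blurs exactly the boundary one
wants to measure. `tonguetrack` implements a greedy active-contour (snake)
tracker that stays robust to partial blurring: morphological preprocessing
finds the dark oral airway and seeds the snake, the snake locks the movable
points onto the tongue surface, and the tracked contours are reduced to the
three standard articulatory parameters — tongue tip constriction location
(TTCL), tongue body constriction location (TBCL) and lip aperture (LA) —
measured in millimetres against the palatal (ANS–PNS) plane. A companion
acoustics module estimates vowel formants by LPC and correlates them with
the articulation: F1 rises with TBCL, F2 falls with TTCL.

It is aimed at speech-production researchers and biomedical engineers who
need a transparent, fully scriptable alternative to manual tracing, and it
ships a phantom generator (synthetic midsagittal frames and vowel
waveforms with known ground truth) so the whole pipeline is testable
without any imaging data.

## The method

The snake is a polyline of control points v(s_i) = (x_i, y_i). Lower
points, taken from the lower boundary of the extracted oral cavity, stay
fixed; upper points move. Each iteration moves every movable point to the
pixel in its 3×3 neighbourhood minimising

    E_comb(x, y) = α E_ela + β E_curv + γ E_img

where

* E_ela = d̄ − ‖v(s_i) − v(s_{i−1})‖, with d̄ the mean distance between
  consecutive snake points (recomputed each iteration),
* E_curv = ‖v(s_{i+1}) − 2 v(s_i) + v(s_{i−1})‖²,
* E_img = −‖∇(G_σ ∗ I)‖², the negated squared gradient of the
  Gaussian-blurred frame.

Iteration stops when fewer than n/10 of the n points moved in a sweep, or
after 200 iterations. Defaults α = 1.2, β = 1, γ = 5.2, σ = 5 are tuned
for 1.5 T midsagittal frames at 1.057 px/mm.

Seeding uses an intensity threshold close to the dark end of the range,
th_I = 0.06·(IM_max − IM_min) + IM_min, followed by hysteresis growth,
disc-shaped opening, connected-component filtering by size and jaw
proximity, and equal-arc-length sampling of the cavity boundary.

Formants are estimated per 25 ms window (resampled to twice the formant
ceiling, pre-emphasised, Hann-windowed autocorrelation LPC, root solving)
and averaged over ⌊duration/0.025 s⌋ consecutive windows.

## Worked example

Track one synthetic /a/ frame and measure it:

```python
import tonguetrack as tt
from scipy.spatial.distance import cdist

frame, truth = tt.generate_midsagittal_frame(tt.ARCHETYPES["a"], seed=42)
init = tt.preprocess_frame(frame, truth.jaw_mask)
res = tt.run_snake(frame, init)
pts = tt.movable_points(res.state).astype(float)

err = cdist(pts, truth.tongue_contour).min(axis=1).mean()
m = tt.measure_parameters(pts, truth.palate_trace, truth.upper_lip,
                          truth.lower_lip, truth.plane, frame.resolution)
print(f"converged after {res.iterations} iterations")
print(f"mean contour error: {err:.2f} px")
print(f"TTCL = {m.ttcl:.2f} mm   TBCL = {m.tbcl:.2f} mm   LA = {m.la:.2f} mm")
```

prints

```
converged after 18 iterations
mean contour error: 0.31 px
TTCL = 22.71 mm   TBCL = 12.30 mm   LA = 11.35 mm
```

so the snake sits a third of a pixel from the true tongue surface, and the
measurements agree with the analytic truth (TTCL 24.69, TBCL 12.02,
LA 11.35 mm) to within the anterior span the cavity mask covers. The same
pipeline runs from the shell (`tonguetrack all`), and

```bash
tonguetrack correlate --tables-only
```

correlates the bundled published articulation and formant tables:

```
F TBCL~F1: r=+0.961 (+)
F TTCL~F2: r=-0.975 (-)
M TBCL~F1: r=+0.848 (+)
M TTCL~F2: r=-0.837 (-)
```

i.e. tongue-body height tracks F1 directly and tip position tracks F2
inversely, for both speakers.

## Layout

| module | contents |
| --- | --- |
| `tonguetrack.frame` | `Frame` container, PNG/TIFF I/O, px↔mm conversion |
| `tonguetrack.preprocess` | thresholding, morphology, initial-point selection |
| `tonguetrack.snake` | energy terms, greedy step, stopping rule |
| `tonguetrack.articulatory` | TTCL/TBCL/LA, per-vowel summaries, ranking |
| `tonguetrack.acoustics` | LPC formants, window averaging, correlation |
| `tonguetrack.phantom` | synthetic frames, sequences and vowel waveforms |
| `tonguetrack.tables` | bundled published articulation/formant tables |
| `tonguetrack.pipeline`, `tonguetrack.cli` | end-to-end runs, `tonguetrack` CLI |

See `docs/methods.md` for the modelling assumptions, parameter defaults
and known limitations.
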