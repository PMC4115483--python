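"""Synthetic midsagittal phantoms and vowel waveforms with known truth.

No public MRI/audio recordings accompany the measurement protocol this
package implements, so every downstream module is exercised on phantoms:

* image phantoms — bright soft tissue, a dark oral airway between the
  tongue surface and the palate, a lip opening, a jaw band and speckle
  distractors, with Gaussian blur standing in for motion blur and additive
  Gaussian noise;
* audio phantoms — impulse-train source filtered by a cascade of
  second-order resonators at known formant frequencies.

Rendering convention: frames are stored vertically flipped relative to the
usual radiological display — the palate sits at *larger* row indices and
the tongue surface is the *upper* (low-row) boundary of the airway. The
tracker's movable upper points therefore land on the tongue surface, and
all ground-truth geometry is reported in the same (row, col) pixel frame.

Archetype tongue shapes are hand-designed so that the articulatory
ordinal relations across the six Malay vowels (largest oral cavity and lip
aperture for /a/, front raising for /i/ and /ə/, back raising for /o/,
/u/, /e/, smallest lip aperture for /u/) hold by construction; the exact
coordinates are package fixtures, not measured anatomy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.interpolate import PchipInterpolator

from .acoustics import AudioSegment
from .articulatory import ArticulatoryMeasurement, PalatalPlane, measure_parameters
from .frame import DEFAULT_RESOLUTION, Frame

# intensity levels (8-bit scale) and geometry fractions
_TISSUE = 220.0
_PALATE_BAND = 245.0
_AIRWAY = 10.0
_GAP_MIN_PX = 4.0    # airway gap at full tongue raising
_GAP_MAX_PX = 30.0   # airway gap with the tongue fully lowered
_LA_MAX_PX = 16.0    # lip opening at lip_gap = 1


@dataclass
class VowelArchetype:
    """Normalized tongue posture for one vowel.

    ``tongue_control_points`` are (x, y) in the unit box with x running
    anterior→posterior and y the closeness of the tongue surface to the
    palate (1 = touching, 0 = fully lowered). ``lip_gap`` is the lip
    aperture as a fraction of the maximum opening.
    """

    label: str
    tongue_control_points: tuple
    lip_gap: float
    blur_sigma: float = 1.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        xs = [p[0] for p in self.tongue_control_points]
        if len(xs) < 2 or any(b <= a for a, b in zip(xs, xs[1:])):
            raise ValueError("control points must have strictly increasing x")
        if self.lip_gap < 0:
            raise ValueError("lip_gap must be >= 0")


#: Default archetypes for the six Malay vowels. y values are chosen so the
#: tip gap and the posterior-half minimum gap scale like the published
#: male TTCL/TBCL means, and lip_gap like the male LA means.
ARCHETYPES: dict[str, VowelArchetype] = {
    "a": VowelArchetype("a", ((0.0, 0.15), (0.25, 0.30), (0.5, 0.50), (0.75, 0.665), (1.0, 0.60)), 0.75),
    "e": VowelArchetype("e", ((0.0, 0.53), (0.25, 0.60), (0.5, 0.62), (0.75, 0.708), (1.0, 0.65)), 0.73),
    "ə": VowelArchetype("ə", ((0.0, 0.315), (0.25, 0.55), (0.5, 0.75), (0.75, 0.60), (1.0, 0.50)), 0.47),
    "i": VowelArchetype("i", ((0.0, 0.827), (0.25, 0.90), (0.5, 0.90), (0.75, 0.85), (1.0, 0.72)), 0.44),
    "o": VowelArchetype("o", ((0.0, 0.269), (0.25, 0.45), (0.5, 0.65), (0.75, 0.785), (1.0, 0.70)), 0.33),
    "u": VowelArchetype("u", ((0.0, 0.185), (0.25, 0.40), (0.5, 0.70), (0.75, 0.87), (1.0, 0.78)), 0.21),
}


@dataclass
class PhantomTruth:
    """Ground-truth geometry of a generated frame (pixel coordinates)."""

    tongue_contour: np.ndarray
    palate_trace: np.ndarray
    ans: np.ndarray
    pns: np.ndarray
    upper_lip: np.ndarray
    lower_lip: np.ndarray
    airway_mask: np.ndarray
    jaw_mask: np.ndarray
    expected_measurements: ArticulatoryMeasurement

    @property
    def plane(self) -> PalatalPlane:
        return PalatalPlane(self.ans, self.pns)


def _gap_curve(arch: VowelArchetype, n: int) -> np.ndarray:
    """Airway gap (px) sampled at n equally spaced anterior→posterior x."""
    pts = np.asarray(arch.tongue_control_points, float)
    y = PchipInterpolator(pts[:, 0], pts[:, 1])(np.linspace(0, 1, n))
    return _GAP_MIN_PX + (1.0 - y) * (_GAP_MAX_PX - _GAP_MIN_PX)


def generate_midsagittal_frame(arch: VowelArchetype,
                               size: tuple[int, int] = (256, 256),
                               seed: int = 0,
                               resolution: float = DEFAULT_RESOLUTION,
                               frame_index: int = 0,
                               _gap_override: np.ndarray | None = None
                               ) -> tuple[Frame, PhantomTruth]:
    """Render one phantom frame plus its ground truth.

    Deterministic per (archetype, size, seed). Noise is additive Gaussian
    with std ``arch.noise_sd`` clipped to [0, 255]; blur is Gaussian with
    std ``arch.blur_sigma``.
    """
    h, w = size
    if h < 64 or w < 64:
        raise ValueError("frame size must be at least 64x64")
    c0, c1 = int(0.18 * w), int(0.80 * w)
    r_pal = int(0.66 * h)
    ncols = c1 - c0 + 1
    gap = _gap_override if _gap_override is not None else _gap_curve(arch, ncols)
    gap = np.clip(gap, 1.0, r_pal - 2)

    img = np.full((h, w), _TISSUE, dtype=float)
    img[r_pal:min(h, r_pal + 6), :] = _PALATE_BAND

    airway = np.zeros((h, w), dtype=bool)
    cols = np.arange(c0, c1 + 1)
    tongue_rows = r_pal - gap
    for c, tr in zip(cols, tongue_rows):
        lo = int(np.floor(tr)) + 1
        airway[lo:r_pal, c] = True
    img[airway] = _AIRWAY

    # lip opening: separate dark gap anterior to the mouth, split from the
    # airway by a bright "teeth" band
    la_px = arch.lip_gap * _LA_MAX_PX
    lip_c0, lip_c1 = max(0, c0 - 12), max(1, c0 - 5)
    lip_center = r_pal - 14.0
    lip_mid_col = (lip_c0 + lip_c1) / 2.0
    lower_lip = np.array([lip_center - la_px / 2.0, lip_mid_col])
    upper_lip = np.array([lip_center + la_px / 2.0, lip_mid_col])
    if la_px >= 1:
        img[int(np.ceil(lower_lip[0])):int(np.floor(upper_lip[0])) + 1,
            lip_c0:lip_c1 + 1] = _AIRWAY

    # jaw band (dark distractor; smaller rows = anatomically inferior here)
    jaw = np.zeros((h, w), dtype=bool)
    r_jaw = int(0.25 * h)
    jaw[r_jaw:r_jaw + 8, c0:int(c0 + 0.6 * (c1 - c0))] = True
    img[jaw] = _AIRWAY

    # small speckle distractors, deterministic per seed
    rng = np.random.default_rng(seed)
    for _ in range(3):
        rr = int(rng.integers(5, h // 5))
        cc = int(rng.integers(5, w - 5))
        img[rr:rr + 2, cc:cc + 2] = _AIRWAY

    if arch.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, arch.blur_sigma)
    if arch.noise_sd > 0:
        img = img + rng.normal(0.0, arch.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 255.0)

    tongue_contour = np.column_stack([tongue_rows, cols.astype(float)])
    palate_trace = np.column_stack([np.full(ncols, float(r_pal)), cols.astype(float)])
    ans = np.array([float(r_pal), float(c0)])
    pns = np.array([float(r_pal), float(c1)])
    plane = PalatalPlane(ans, pns)
    expected = measure_parameters(tongue_contour, palate_trace, upper_lip,
                                  lower_lip, plane, resolution,
                                  frame_index=frame_index)
    truth = PhantomTruth(tongue_contour=tongue_contour,
                         palate_trace=palate_trace, ans=ans, pns=pns,
                         upper_lip=upper_lip, lower_lip=lower_lip,
                         airway_mask=airway, jaw_mask=jaw,
                         expected_measurements=expected)
    return Frame(img, resolution=resolution, frame_index=frame_index), truth


def generate_frame_sequence(arch: VowelArchetype, n_frames: int = 7,
                            jitter: float = 0.0, seed: int = 0,
                            size: tuple[int, int] = (256, 256),
                            resolution: float = DEFAULT_RESOLUTION):
    """A sequence of frames with per-frame tongue perturbations <= jitter px."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    h, w = size
    ncols = int(0.80 * w) - int(0.18 * w) + 1
    base_gap = _gap_curve(arch, ncols)
    out = []
    for k in range(n_frames):
        if jitter > 0:
            # smooth per-frame perturbation: a random cubic over x
            coef = rng.uniform(-1.0, 1.0, size=4)
            x = np.linspace(0, 1, ncols)
            bump = coef[0] + coef[1] * x + coef[2] * x ** 2 + coef[3] * x ** 3
            bump = bump / max(1e-12, np.abs(bump).max()) * jitter
            gap = base_gap + bump
        else:
            gap = base_gap
        frame, truth = generate_midsagittal_frame(
            arch, size=size, seed=int(rng.integers(0, 2 ** 31 - 1)),
            resolution=resolution, frame_index=k, _gap_override=gap)
        out.append((frame, truth))
    return out


def synthesize_vowel(f0: float, formants, bandwidths=None,
                     duration: float = 0.5, rate: float = 20000.0,
                     seed: int = 0, tilt: float = 0.98) -> AudioSegment:
    """Source–filter vowel synthesis with known resonances.

    An impulse train at ``f0``, shaped by a one-pole glottal roll-off
    (-6 dB/octave, coefficient ``tilt`` — the net source slope of voiced
    speech after lip radiation), is filtered by a cascade of second-order
    resonators at the given formant frequencies and bandwidths, then
    peak-normalized. Deterministic for identical arguments.
    """
    formants = [float(f) for f in formants]
    if duration <= 0:
        raise ValueError("duration must be positive")
    if any(b <= a for a, b in zip(formants, formants[1:])):
        raise ValueError("formants must be strictly ascending")
    if any(f >= rate / 2 for f in formants):
        raise ValueError("formant at or above Nyquist")
    if bandwidths is None:
        bandwidths = [60.0 + 20.0 * k for k in range(len(formants))]
    n = int(round(duration * rate))
    x = np.zeros(n)
    period = rate / f0
    idx = np.round(np.arange(0, n, period)).astype(int)
    x[idx[idx < n]] = 1.0
    from scipy.signal import lfilter
    if tilt > 0:
        x = lfilter([1.0], [1.0, -tilt], x)
    for f, bw in zip(formants, bandwidths):
        r = np.exp(-np.pi * bw / rate)
        theta = 2.0 * np.pi * f / rate
        a = [1.0, -2.0 * r * np.cos(theta), r * r]
        x = lfilter([1.0], a, x)
    peak = np.abs(x).max()
    if peak > 0:
        x = x / peak
    return AudioSegment(samples=x, rate=rate)
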