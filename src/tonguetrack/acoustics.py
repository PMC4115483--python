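"""Vowel formant estimation and articulatory–acoustic correlation.

Formants are estimated by autocorrelation linear prediction: each analysis
window is resampled to twice the formant ceiling, pre-emphasized, Hann
windowed, fitted with an all-pole model, and the complex roots of the
prediction polynomial are converted to resonance frequencies and
bandwidths. Only resonances inside (0, max_formant) with bandwidth below
400 Hz are kept.

Utterance-level values are the averages over consecutive non-overlapping
windows; the number of analysis points equals floor(duration / window
length). Windows whose RMS falls more than ``dyn_range`` dB below the
loudest window are treated as silence and contribute nothing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from fractions import Fraction
from scipy import signal
from scipy.io import wavfile
from scipy.linalg import solve_toeplitz
from scipy.stats import pearsonr


@dataclass
class AudioSegment:
    """Mono waveform with its sampling rate."""

    samples: np.ndarray
    rate: float = 20000.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.samples.size == 0:
            raise ValueError("audio segment must be non-empty")
        if not self.rate > 0:
            raise ValueError("sampling rate must be positive")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.rate

    @classmethod
    def from_wav(cls, path: str) -> "AudioSegment":
        rate, data = wavfile.read(path)
        raw = np.asarray(data)
        data = raw.astype(float)
        if data.ndim > 1:
            data = data.mean(axis=1)
        if np.issubdtype(raw.dtype, np.integer):
            data = data / 32768.0
        return cls(samples=data, rate=float(rate))

    def to_wav(self, path: str) -> None:
        x = np.clip(self.samples, -1.0, 1.0)
        wavfile.write(path, int(self.rate), (x * 32767).astype(np.int16))


@dataclass
class FormantSettings:
    """Analysis settings (ceilings: 5000 Hz male, 5500 Hz female)."""

    max_formant: float = 5000.0
    n_formants: int = 5
    window: float = 0.025
    dyn_range: float = 30.0
    pre_emphasis: float = 0.98
    max_bandwidth: float = 400.0

    def __post_init__(self) -> None:
        if self.max_formant <= 0 or self.window <= 0:
            raise ValueError("max_formant and window must be positive")

    @property
    def lpc_order(self) -> int:
        return 2 * self.n_formants + 2


@dataclass
class FormantSummary:
    vowel: str | None
    gender: str | None
    f_mean: list[float]
    f_std: list[float]
    n_points: int


def _lpc_coefficients(x: np.ndarray, order: int) -> np.ndarray | None:
    """Autocorrelation-method LP coefficients [1, a1..ap]; None if singular."""
    r = np.correlate(x, x, mode="full")[len(x) - 1:len(x) + order]
    if r[0] <= 0:
        return None
    try:
        a = solve_toeplitz((r[:order], r[:order]), r[1:order + 1])
    except np.linalg.LinAlgError:
        return None
    return np.concatenate([[1.0], -a])


def frame_formants(window: AudioSegment, settings: FormantSettings | None = None):
    """Formant frequencies (Hz, ascending) of one analysis window.

    Returns up to ``n_formants`` values in (0, max_formant) with bandwidth
    below ``max_bandwidth``; an (effectively) silent window yields [].
    """
    settings = settings or FormantSettings()
    x = window.samples
    if not np.any(np.abs(x) > 1e-10):
        return []
    fs_target = 2.0 * settings.max_formant
    if abs(window.rate - fs_target) > 1e-9:
        frac = Fraction(fs_target / window.rate).limit_denominator(1000)
        x = signal.resample_poly(x, frac.numerator, frac.denominator)
    if len(x) < 2 * settings.lpc_order:
        raise ValueError("window too short for the LP order")
    x = np.append(x[0], x[1:] - settings.pre_emphasis * x[:-1])
    x = x * np.hanning(len(x))
    a = _lpc_coefficients(x, settings.lpc_order)
    if a is None:
        return []
    roots = np.roots(a)
    roots = roots[np.imag(roots) > 1e-9]
    freqs = np.angle(roots) * fs_target / (2.0 * np.pi)
    bws = -np.log(np.abs(roots)) * fs_target / np.pi
    keep = (freqs > 0) & (freqs < settings.max_formant) & (bws < settings.max_bandwidth)
    out = np.sort(freqs[keep])
    return [float(f) for f in out[:settings.n_formants]]


def average_formants(segment: AudioSegment,
                     settings: FormantSettings | None = None,
                     vowel: str | None = None,
                     gender: str | None = None) -> FormantSummary:
    """Average formants over consecutive non-overlapping windows.

    ``n_points = floor(duration / window)``. Windows gated out by the
    dynamic range (RMS >= dyn_range dB below the loudest window) or
    returning no resonances are excluded from the averages.
    """
    settings = settings or FormantSettings()
    if segment.duration < settings.window:
        raise ValueError("segment shorter than one analysis window")
    w = int(round(settings.window * segment.rate))
    n_points = int(np.floor(segment.duration / settings.window))
    frames = [segment.samples[i * w:(i + 1) * w] for i in range(n_points)]
    rms = np.array([np.sqrt(np.mean(f ** 2)) for f in frames])
    floor = rms.max() * 10 ** (-settings.dyn_range / 20.0)
    per_window: list[list[float]] = []
    for f, r in zip(frames, rms):
        if rms.max() == 0 or r < floor:
            continue
        per_window.append(frame_formants(AudioSegment(f, segment.rate), settings))
    f_mean, f_std = [], []
    for k in range(settings.n_formants):
        vals = [fw[k] for fw in per_window if len(fw) > k]
        if not vals:
            break
        f_mean.append(float(np.mean(vals)))
        f_std.append(float(np.std(vals)))
    return FormantSummary(vowel=vowel, gender=gender, f_mean=f_mean,
                          f_std=f_std, n_points=n_points)


def correlate_articulatory_acoustic(artic: pd.DataFrame,
                                    formants: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of articulation means against formant means.

    Parameters
    ----------
    artic : DataFrame with columns vowel, gender, parameter, mean
        Per-vowel articulatory summaries (TTCL/TBCL in mm).
    formants : DataFrame with columns vowel, gender, f1, f2
        Per-vowel formant means (Hz).

    Returns one row per (gender, pair) with Pearson r, least-squares slope,
    the number of paired vowels and a sign flag, for the pairs
    (TBCL, F1) and (TTCL, F2).
    """
    rows = []
    for gender in sorted(artic["gender"].unique()):
        fsub = formants[formants["gender"] == gender].set_index("vowel")
        for param, fcol in (("TBCL", "f1"), ("TTCL", "f2")):
            asub = artic[(artic["gender"] == gender)
                         & (artic["parameter"] == param)].set_index("vowel")
            common = [v for v in asub.index if v in fsub.index]
            if len(common) < 3:
                raise ValueError(f"need >= 3 paired vowels for {gender}/{param}, "
                                 f"got {len(common)}")
            x = asub.loc[common, "mean"].to_numpy(float)
            y = fsub.loc[common, fcol].to_numpy(float)
            r, _ = pearsonr(x, y)
            slope = float(np.polyfit(x, y, 1)[0])
            rows.append({"gender": gender, "parameter": param,
                         "formant": fcol.upper(), "r": float(r),
                         "slope": slope, "n": len(common),
                         "sign": "+" if r > 0 else "-"})
    return pd.DataFrame(rows)
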