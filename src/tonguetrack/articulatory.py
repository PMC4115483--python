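"""Articulatory measurements from tracked contours.

Three standard parameters are measured per frame, in millimetres, in the
coordinate frame of the palatal plane (the line from the anterior nasal
spine, ANS, to the posterior nasal spine, PNS):

TTCL (tongue tip constriction location)
    Distance from the tongue-tip landmark — the anterior-most tracked
    tongue point — to the palate trace. Low for front vowels.
TBCL (tongue body constriction location)
    Minimum distance from the posterior half of the tongue contour to the
    palate trace. Low for high vowels.
LA (lip aperture)
    Distance between the upper-lip and lower-lip landmarks.

Distances default to Euclidean point-to-trace; perpendicular distance to
the ANS–PNS line is available via ``distance_mode="plane"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

VOWELS = ("a", "e", "ə", "i", "o", "u")
PARAMETERS = ("TTCL", "TBCL", "LA")


@dataclass
class PalatalPlane:
    """ANS→PNS reference line, endpoints in pixel (row, col) coordinates."""

    ans: np.ndarray
    pns: np.ndarray

    def __post_init__(self) -> None:
        self.ans = np.asarray(self.ans, dtype=float)
        self.pns = np.asarray(self.pns, dtype=float)
        if np.allclose(self.ans, self.pns):
            raise ValueError("ANS and PNS must be distinct points")


@dataclass
class ArticulatoryMeasurement:
    ttcl: float
    tbcl: float
    la: float
    frame_index: int = 0

    def __post_init__(self) -> None:
        vals = (self.ttcl, self.tbcl, self.la)
        if not all(np.isfinite(v) and v >= 0 for v in vals):
            raise ValueError("measurements must be finite and non-negative")


@dataclass
class VowelSummary:
    """Per-frame values of one parameter for one vowel/gender, with sample
    (n−1 denominator) summary statistics."""

    vowel: str
    gender: str
    parameter: str
    per_frame: list[float]
    mean: float
    std: float
    variance: float
    degenerate: bool = False


def _perpendicular_distance(points: np.ndarray, plane: PalatalPlane) -> np.ndarray:
    d = plane.pns - plane.ans
    d = d / np.linalg.norm(d)
    rel = np.asarray(points, float) - plane.ans
    # component of rel orthogonal to the plane direction
    along = rel @ d
    return np.linalg.norm(rel - np.outer(along, d), axis=1)


def _arc_length(points: np.ndarray) -> np.ndarray:
    deltas = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(deltas)])


def measure_parameters(tongue, palate, upper_lip, lower_lip,
                       plane: PalatalPlane, resolution: float,
                       distance_mode: str = "trace",
                       tip_fraction: float = 0.5,
                       frame_index: int = 0) -> ArticulatoryMeasurement:
    """Measure TTCL, TBCL and LA (mm) from contours in pixel coordinates.

    Parameters
    ----------
    tongue, palate : (k, 2) arrays of (row, col) points
        Tracked tongue contour (anterior→posterior) and palate trace.
    upper_lip, lower_lip : (row, col) points
    plane : PalatalPlane
        Used when ``distance_mode="plane"``; distances are then measured
        perpendicular to the ANS–PNS line instead of to the palate trace.
    resolution : float
        Pixels per millimetre; all pixel distances are divided by it.
    tip_fraction : float
        Arc-length fraction separating the tip from the body; the
        posterior part (arc length >= tip_fraction of total) defines TBCL.
    """
    tongue = np.atleast_2d(np.asarray(tongue, dtype=float))
    palate = np.atleast_2d(np.asarray(palate, dtype=float))
    if tongue.size == 0 or palate.size == 0:
        raise ValueError("tongue and palate contours must be non-empty")
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    if distance_mode not in ("trace", "plane"):
        raise ValueError("distance_mode must be 'trace' or 'plane'")

    # anterior-most point = tongue tip (ties: smallest row)
    order = np.lexsort((tongue[:, 0], tongue[:, 1]))
    tip = tongue[order[0]]

    if distance_mode == "trace":
        def dist_to_palate(pts):
            return cdist(np.atleast_2d(pts), palate).min(axis=1)
    else:
        def dist_to_palate(pts):
            return _perpendicular_distance(np.atleast_2d(pts), plane)

    ttcl_px = float(dist_to_palate(tip)[0])

    s = _arc_length(tongue)
    if s[-1] > 0:
        posterior = tongue[s >= tip_fraction * s[-1]]
    else:
        posterior = tongue
    tbcl_px = float(dist_to_palate(posterior).min())

    la_px = float(np.linalg.norm(np.asarray(upper_lip, float)
                                 - np.asarray(lower_lip, float)))
    return ArticulatoryMeasurement(ttcl=ttcl_px / resolution,
                                   tbcl=tbcl_px / resolution,
                                   la=la_px / resolution,
                                   frame_index=frame_index)


def summarize_frames(values, vowel: str, gender: str,
                     parameter: str) -> VowelSummary:
    """Mean, sample STD and sample variance of per-frame values (mm).

    A single frame yields zero spread and sets the ``degenerate`` flag.
    """
    vals = [float(v) for v in values]
    if not vals:
        raise ValueError("values must be non-empty")
    mean = float(np.mean(vals))
    if len(vals) == 1:
        warnings.warn("single-frame summary: std/variance reported as 0",
                      stacklevel=2)
        return VowelSummary(vowel, gender, parameter, vals, mean, 0.0, 0.0,
                            degenerate=True)
    variance = float(np.var(vals, ddof=1))
    return VowelSummary(vowel, gender, parameter, vals, mean,
                        float(np.sqrt(variance)), variance)


def rank_vowels(summaries, parameter: str):
    """Vowel labels sorted by ascending mean of ``parameter``.

    Requires exactly one summary per vowel for the given parameter
    (pre-filter by gender). Ties are broken by vowel label.
    """
    subset = [s for s in summaries if s.parameter == parameter]
    seen = {s.vowel for s in subset}
    if len(subset) != len(VOWELS) or seen != set(VOWELS):
        missing = sorted(set(VOWELS) - seen)
        raise ValueError(f"need one summary per vowel; missing/duplicated: {missing or seen}")
    return [s.vowel for s in sorted(subset, key=lambda s: (s.mean, s.vowel))]
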