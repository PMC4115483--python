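"""Morphological preprocessing: cavity extraction and snake initial points.

Oral cavities appear in midsagittal MR frames as dark regions; a threshold
close to the intensity floor separates them from tissue. The threshold is

    th_I = 0.06 * (IM_max - IM_min) + IM_min

where IM_max and IM_min are the frame's extreme intensities. The thresholded
mask is cleaned by morphological opening with a disc, segmented into
connected components, filtered by size and by proximity to the (dilated) jaw
segment, and the selected oral-cavity component yields the snake's initial
points: movable points on the upper boundary and fixed points on the lower
boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from .frame import Frame

_SQUARE3 = np.ones((3, 3), dtype=bool)
# 8-connectivity for component labelling
_STRUCT8 = np.ones((3, 3), dtype=int)


@dataclass
class PreprocessConfig:
    """Tunable preprocessing parameters (all lengths in pixels).

    threshold_factor
        Fraction of the intensity range added to the frame minimum to form
        the cavity threshold (default 0.06).
    denoise_sigma
        Std of an optional Gaussian smoothing applied before thresholding;
        either a scalar or a (row, col) pair. The default is anisotropic,
        gentle across rows and stronger along columns, matched to the
        elongated shape of the oral airway so that heavy noise is
        suppressed without erasing the thin airway of high vowels.
        0 disables it; the threshold is computed on the smoothed image so
        the operation reduces exactly to the plain threshold when disabled.
    expand_factor, expand_sigma
        The strict threshold deliberately under-segments blurred cavities
        (their smoothed edges rise above it), so it is used as a *seed*
        threshold: the mask grows by hysteresis into pixels below
        ``expand_factor`` of the intensity range (on a lightly smoothed
        copy, std ``expand_sigma``) that are 8-connected to a seed.
        ``expand_factor=0`` disables the expansion and leaves the plain
        thresholded mask.
    consolidate_radius
        Disc radius of a closing applied to the thresholded mask before the
        opening; it fuses the speckle that per-pixel thresholding leaves in
        noisy airways so the opening does not fragment the cavity.
    open_radius, close_radius
        Disc radii for the opening that cleans the thresholded mask and the
        closing applied to the selected cavity before boundary extraction.
    min_size
        Minimum surviving component size in pixels.
    jaw_radius
        Disc radius used to dilate the jaw segment when discarding
        components that touch it.
    n_upper, n_lower
        Number of movable (upper-boundary) and fixed (lower-boundary)
        initial points.
    """

    threshold_factor: float = 0.06
    denoise_sigma: float | tuple = (0.7, 4.0)
    expand_factor: float = 0.3
    expand_sigma: float = 0.7
    consolidate_radius: int = 1
    open_radius: int = 1
    close_radius: int = 3
    min_size: int = 50
    jaw_radius: int = 5
    n_upper: int = 30
    n_lower: int = 15


@dataclass
class SegmentSet:
    """Connected components of a binary mask (label 0 = background)."""

    labels: np.ndarray
    sizes: dict[int, int]

    def mask_of(self, label: int) -> np.ndarray:
        return self.labels == label


@dataclass
class InitialPoints:
    """Seed points for the active contour, as integer (row, col) pixels.

    ``upper`` points (smaller row index along the cavity boundary) are
    movable; ``lower`` points are fixed throughout tracking. Both lists are
    ordered anterior (small column) to posterior.
    """

    upper: np.ndarray
    lower: np.ndarray

    def __post_init__(self) -> None:
        self.upper = np.atleast_2d(np.asarray(self.upper, dtype=int))
        self.lower = np.atleast_2d(np.asarray(self.lower, dtype=int))
        if len(self.upper) < 3 or len(self.lower) < 3:
            raise ValueError("need at least 3 upper and 3 lower points")


def compute_threshold(frame: Frame, factor: float = 0.06) -> float:
    """Cavity threshold: ``factor * (IM_max - IM_min) + IM_min``."""
    px = frame.pixels
    im_min = float(px.min())
    im_max = float(px.max())
    return factor * (im_max - im_min) + im_min


def extract_cavity_mask(frame: Frame, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Threshold dark cavities and clean the mask by disc opening.

    With ``denoise_sigma > 0`` the threshold is computed on (and applied to)
    a Gaussian-smoothed copy of the frame; with 0 the raw frame is used.
    Returns a boolean mask containing only the components that survive the
    opening; it may be empty.
    """
    cfg = cfg or PreprocessConfig()
    img = frame.pixels
    sigma = cfg.denoise_sigma
    if np.any(np.asarray(sigma) > 0):
        img = ndimage.gaussian_filter(img, sigma)
    im_min, im_max = float(img.min()), float(img.max())
    if im_max == im_min:
        return np.zeros(frame.shape, dtype=bool)  # no contrast, no cavities
    th = cfg.threshold_factor * (im_max - im_min) + im_min
    mask = img <= th
    if cfg.expand_factor > 0 and mask.any():
        light = frame.pixels
        if cfg.expand_sigma > 0:
            light = ndimage.gaussian_filter(light, cfg.expand_sigma)
        lo, hi = float(light.min()), float(light.max())
        extended = light <= cfg.expand_factor * (hi - lo) + lo
        mask = ndimage.binary_propagation(mask, mask=extended | mask,
                                          structure=_STRUCT8)
    if cfg.consolidate_radius > 0:
        mask = ndimage.binary_closing(mask, structure=disk(cfg.consolidate_radius))
    if cfg.open_radius > 0:
        mask = ndimage.binary_opening(mask, structure=disk(cfg.open_radius))
    return mask


def label_segments(mask: np.ndarray) -> SegmentSet:
    """8-connected component labelling of a binary mask."""
    labels, n = ndimage.label(np.asarray(mask, bool), structure=_STRUCT8)
    counts = np.bincount(labels.ravel(), minlength=n + 1)
    sizes = {lab: int(counts[lab]) for lab in range(1, n + 1)}
    return SegmentSet(labels=labels, sizes=sizes)


def filter_segments(segs: SegmentSet, jaw_mask: np.ndarray,
                    cfg: PreprocessConfig | None = None) -> SegmentSet:
    """Drop segments that are too small or touch the dilated jaw segment.

    Surviving segments keep their labels and pixel sets unchanged.
    """
    cfg = cfg or PreprocessConfig()
    jaw = np.asarray(jaw_mask, bool)
    if jaw.shape != segs.labels.shape:
        raise ValueError("jaw mask shape must match the label image")
    if cfg.jaw_radius > 0:
        jaw = ndimage.binary_dilation(jaw, structure=disk(cfg.jaw_radius))
    out = segs.labels.copy()
    sizes: dict[int, int] = {}
    for lab, size in segs.sizes.items():
        seg = segs.labels == lab
        if size < cfg.min_size or bool(np.any(seg & jaw)):
            out[seg] = 0
        else:
            sizes[lab] = size
    return SegmentSet(labels=out, sizes=sizes)


def segment_contours(mask: np.ndarray) -> np.ndarray:
    """Contours as (dilation − erosion) of the mask with a 3x3 element.

    The result is a one-to-two-pixel-wide ring around every segment.
    """
    m = np.asarray(mask, bool)
    return (ndimage.binary_dilation(m, structure=_SQUARE3)
            & ~ndimage.binary_erosion(m, structure=_SQUARE3))


def _boundary_polyline(component: np.ndarray, side: str) -> np.ndarray:
    """Per-column extreme-row boundary of a component, anterior→posterior."""
    rows, cols = np.nonzero(component)
    pts = []
    for c in np.unique(cols):
        r = rows[cols == c]
        pts.append((r.min() if side == "upper" else r.max(), c))
    return np.asarray(pts, dtype=int)


def _resample_polyline(poly: np.ndarray, n: int) -> np.ndarray:
    """Pick ``n`` polyline vertices at approximately equal arc length."""
    if n > len(poly):
        raise ValueError(f"cannot sample {n} points from a {len(poly)}-vertex boundary")
    deltas = np.linalg.norm(np.diff(poly.astype(float), axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(deltas)])
    targets = np.linspace(0.0, s[-1], n)
    idx = np.searchsorted(s, targets)
    idx = np.clip(idx, 0, len(poly) - 1)
    # enforce strictly increasing indices so points stay distinct
    for k in range(1, n):
        if idx[k] <= idx[k - 1]:
            idx[k] = idx[k - 1] + 1
    idx = np.clip(idx, 0, len(poly) - 1)
    return poly[idx]


def select_initial_points(cavity: np.ndarray, n_upper: int = 30,
                          n_lower: int = 15,
                          close_radius: int = 3) -> InitialPoints:
    """Sample snake seed points from the boundary of the cavity component.

    The mask must contain exactly one 8-connected foreground component
    (the caller picks the oral cavity, preferring the frame with the
    largest cavity). The component is closed with a disc of
    ``close_radius`` to smooth its boundary, then the upper boundary
    (minimum row per column) yields the movable points and the lower
    boundary (maximum row per column) the fixed points, each resampled to
    the requested count at approximately equal arc length.
    """
    m = np.asarray(cavity, bool)
    if not m.any():
        raise ValueError("cavity mask is empty")
    labels, n = ndimage.label(m, structure=_STRUCT8)
    if n != 1:
        raise ValueError(f"cavity mask must contain exactly one component, found {n}")
    if close_radius > 0:
        m = ndimage.binary_closing(m, structure=disk(close_radius))
    upper = _resample_polyline(_boundary_polyline(m, "upper"), n_upper)
    lower = _resample_polyline(_boundary_polyline(m, "lower"), n_lower)
    return InitialPoints(upper=upper, lower=lower)


def largest_segment_mask(segs: SegmentSet) -> np.ndarray:
    """Mask of the largest surviving segment (the oral-cavity candidate)."""
    if not segs.sizes:
        raise ValueError("no segments left to choose from")
    lab = max(segs.sizes, key=lambda k: (segs.sizes[k], -k))
    return segs.mask_of(lab)


def preprocess_frame(frame: Frame, jaw_mask: np.ndarray | None = None,
                     cfg: PreprocessConfig | None = None) -> InitialPoints:
    """Full preprocessing chain: threshold → open → filter → seed points."""
    cfg = cfg or PreprocessConfig()
    mask = extract_cavity_mask(frame, cfg)
    segs = label_segments(mask)
    if jaw_mask is not None:
        segs = filter_segments(segs, jaw_mask, cfg)
    else:
        segs = filter_segments(segs, np.zeros(frame.shape, bool), cfg)
    cavity = largest_segment_mask(segs)
    return select_initial_points(cavity, cfg.n_upper, cfg.n_lower, cfg.close_radius)


def cavity_area(frame: Frame, jaw_mask: np.ndarray | None = None,
                cfg: PreprocessConfig | None = None) -> int:
    """Pixel area of the largest surviving cavity segment (0 if none)."""
    cfg = cfg or PreprocessConfig()
    mask = extract_cavity_mask(frame, cfg)
    segs = label_segments(mask)
    segs = filter_segments(segs, jaw_mask if jaw_mask is not None
                           else np.zeros(frame.shape, bool), cfg)
    return max(segs.sizes.values(), default=0)
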