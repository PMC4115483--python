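"""Greedy active contour for tongue-surface tracking.

The contour is a polyline of control points v(s_i) = (x_i, y_i). At each
iteration every movable point is moved to the pixel in its neighbourhood
that minimises the combined energy

    E_comb(x, y) = alpha * E_ela(x, y) + beta * E_curv(x, y) + gamma * E_img(x, y)

with

    E_ela  = d_bar - |v(s_i) - v(s_{i-1})|          (d_bar: mean inter-point
                                                     distance of the polyline,
                                                     recomputed each iteration)
    E_curv = |v(s_{i+1}) - 2 v(s_i) + v(s_{i-1})|^2
    E_img  = -|grad(G_sigma * I)|^2                  (Gaussian-blurred image
                                                     gradient, squared, negated)

Iteration stops when fewer than ``stop_fraction * n`` points moved in a
step (n = total control points) or when ``max_iter`` is reached. The lower
(fixed) points never move; they pin the contour where the boundary is
already known from preprocessing.

Energy terms are used literally as written above. The per-neighbourhood
min–max normalisation of the classic greedy formulation is available behind
``normalize_neighborhood`` (default off).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .frame import Frame
from .preprocess import InitialPoints


@dataclass
class EnergyWeights:
    """Energy weights and the image-blur scale (defaults as tuned for
    1.5 T midsagittal frames at 1.057 px/mm)."""

    alpha: float = 1.2
    beta: float = 1.0
    gamma: float = 5.2
    sigma: float = 5.0

    def __post_init__(self) -> None:
        if min(self.alpha, self.beta, self.gamma, self.sigma) <= 0:
            raise ValueError("all energy weights and sigma must be positive")


@dataclass
class SnakeConfig:
    weights: EnergyWeights = field(default_factory=EnergyWeights)
    max_iter: int = 200
    #: stop when moved points < stop_fraction * n ("count" metric), or when
    #: mean per-point displacement < stop_fraction px ("displacement" metric)
    stop_fraction: float = 0.1
    neighborhood_radius: int = 1
    stop_metric: str = "count"
    normalize_neighborhood: bool = False

    def __post_init__(self) -> None:
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not 0 < self.stop_fraction <= 1:
            raise ValueError("stop_fraction must be in (0, 1]")
        if self.stop_metric not in ("count", "displacement"):
            raise ValueError("stop_metric must be 'count' or 'displacement'")


@dataclass
class SnakeState:
    """Contour state: ordered (row, col) points with movability flags.

    Storage order is anterior→posterior along the fixed lower boundary,
    then posterior→anterior along the movable upper boundary, so that the
    points form a single open polyline and every movable point has a
    predecessor.
    """

    points: np.ndarray
    movable: np.ndarray
    iteration: int = 0
    moved_last: int = 0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=int)
        self.movable = np.asarray(self.movable, dtype=bool)
        if len(self.points) != len(self.movable) or len(self.points) < 3:
            raise ValueError("points/movable must be parallel lists of length >= 3")


@dataclass
class SnakeResult:
    state: SnakeState
    iterations: int
    converged: bool
    moved_history: list[int]
    states: list[SnakeState] | None = None


def elasticity_energy(prev, cand, d_bar: float) -> float:
    """``d_bar - |cand - prev|`` (may be negative)."""
    if d_bar < 0:
        raise ValueError("d_bar must be non-negative")
    d = float(np.hypot(cand[0] - prev[0], cand[1] - prev[1]))
    return d_bar - d


def curvature_energy(prev, cur, nxt) -> float:
    """Squared norm of the discrete second difference ``next - 2 cur + prev``."""
    dr = nxt[0] - 2.0 * cur[0] + prev[0]
    dc = nxt[1] - 2.0 * cur[1] + prev[1]
    return float(dr * dr + dc * dc)


def image_energy_field(frame: Frame, sigma: float) -> np.ndarray:
    """Edge-attraction field ``-|grad(G_sigma * I)|^2`` (everywhere <= 0)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    sm = ndimage.gaussian_filter(frame.pixels, sigma)
    gr, gc = np.gradient(sm)
    return -(gr * gr + gc * gc)


def combined_energy(e_ela: float, e_curv: float, e_img: float,
                    w: EnergyWeights) -> float:
    return w.alpha * e_ela + w.beta * e_curv + w.gamma * e_img


def mean_point_distance(points: np.ndarray) -> float:
    """Mean Euclidean distance between consecutive polyline points."""
    diffs = np.diff(np.asarray(points, dtype=float), axis=0)
    return float(np.linalg.norm(diffs, axis=1).mean())


def state_from_initial_points(init: InitialPoints) -> SnakeState:
    """Build the snake polyline: fixed lower points then reversed upper."""
    points = np.vstack([init.lower, init.upper[::-1]])
    movable = np.concatenate([np.zeros(len(init.lower), bool),
                              np.ones(len(init.upper), bool)])
    return SnakeState(points=points, movable=movable)


def _candidates(pt: np.ndarray, radius: int, shape: tuple[int, int]) -> np.ndarray:
    """In-bounds neighbourhood pixels, current position first then row-major."""
    r0, c0 = int(pt[0]), int(pt[1])
    cands = [(r0, c0)]
    for r in range(r0 - radius, r0 + radius + 1):
        for c in range(c0 - radius, c0 + radius + 1):
            if (r, c) != (r0, c0) and 0 <= r < shape[0] and 0 <= c < shape[1]:
                cands.append((r, c))
    return np.asarray(cands, dtype=int)


def _normalize(values: np.ndarray) -> np.ndarray:
    lo, hi = values.min(), values.max()
    if hi - lo < 1e-12:
        return np.zeros_like(values)
    return (values - lo) / (hi - lo)


def snake_step(state: SnakeState, field: np.ndarray,
               cfg: SnakeConfig | None = None) -> SnakeState:
    """One greedy update sweep over all movable points.

    d_bar is recomputed from the state at the start of the step. Movable
    points are visited anterior→posterior (reverse storage order, since
    upper points are stored posterior→anterior) and each update sees the
    moves already made in this sweep. Ties in the neighbourhood argmin are
    broken in candidate order, the current position first.
    """
    cfg = cfg or SnakeConfig()
    w = cfg.weights
    pts = state.points.copy()
    n = len(pts)
    d_bar = mean_point_distance(pts)
    moved = 0
    movable_idx = [i for i in range(n - 1, -1, -1) if state.movable[i]]
    for i in movable_idx:
        prev = pts[i - 1] if i > 0 else pts[i + 1]
        nxt = pts[i + 1] if i + 1 < n else pts[i - 1]
        cands = _candidates(pts[i], cfg.neighborhood_radius, field.shape)
        e_ela = np.array([elasticity_energy(prev, c, d_bar) for c in cands])
        e_curv = np.array([curvature_energy(prev, c, nxt) for c in cands])
        e_img = field[cands[:, 0], cands[:, 1]]
        if cfg.normalize_neighborhood:
            e_ela, e_curv, e_img = map(_normalize, (e_ela, e_curv, e_img))
        e = w.alpha * e_ela + w.beta * e_curv + w.gamma * e_img
        best = int(np.argmin(e))
        if best != 0:
            pts[i] = cands[best]
            moved += 1
    return SnakeState(points=pts, movable=state.movable.copy(),
                      iteration=state.iteration + 1, moved_last=moved)


def run_snake(frame: Frame, init: InitialPoints,
              cfg: SnakeConfig | None = None,
              record_states: bool = False) -> SnakeResult:
    """Iterate greedy steps until the stopping rule fires or max_iter.

    Deterministic: identical inputs yield identical point trajectories.
    """
    cfg = cfg or SnakeConfig()
    field = image_energy_field(frame, cfg.weights.sigma)
    state = state_from_initial_points(init)
    shape = frame.shape
    if (np.any(state.points < 0)
            or np.any(state.points[:, 0] >= shape[0])
            or np.any(state.points[:, 1] >= shape[1])):
        raise ValueError("initial points fall outside the frame")
    n = len(state.points)
    history: list[int] = []
    states = [state] if record_states else None
    converged = False
    for _ in range(cfg.max_iter):
        prev_pts = state.points
        state = snake_step(state, field, cfg)
        history.append(state.moved_last)
        if states is not None:
            states.append(state)
        if cfg.stop_metric == "count":
            stop = state.moved_last < cfg.stop_fraction * n
        else:
            disp = np.linalg.norm(state.points - prev_pts)
            stop = disp / n < cfg.stop_fraction
        if stop:
            converged = True
            break
    return SnakeResult(state=state, iterations=state.iteration,
                       converged=converged, moved_history=history,
                       states=states)


def movable_points(state: SnakeState) -> np.ndarray:
    """The movable (upper-boundary) points, anterior→posterior."""
    return state.points[state.movable][::-1]
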