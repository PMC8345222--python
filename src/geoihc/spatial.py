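"""Spatial point-pattern statistics for marked-cell ROIs.

Implements the second-order clustering statistic used downstream: the
bivariate Ripley's K function with isotropic (arc-fraction) edge correction,
normalized as nK(r) = K(r) / (pi r^2) so that complete spatial randomness
(CSR) has expectation 1.0; values above 1 indicate clustering of the "to"
type around the "from" type, values below 1 dispersion.  Also provides the
eligibility rule (>= 10 positive cells per pattern), directed nearest-
neighbor distances, and scaled 2D kernel density summaries of joint
nearest-neighbor distances.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .types import Intensity, Marker, PointPattern, ROI, Window

log = logging.getLogger(__name__)

#: Minimum positive-cell count for a pattern to enter spatial analysis.
DEFAULT_MIN_CELLS = 10
#: Search radii (µm): local (~2x a tumor-cell radius) and global views.
DEFAULT_RADII = (25.0, 125.0)


# ---------------------------------------------------------------------------
# Isotropic edge correction
# ---------------------------------------------------------------------------

def _arc_fractions(px: np.ndarray, py: np.ndarray, d: np.ndarray,
                   window: Window) -> np.ndarray:
    """Fraction of each circle's circumference lying inside the window.

    Closed-form arc arithmetic for an axis-aligned rectangle: each edge
    closer than ``d`` removes an arc of half-angle ``arccos(e/d)``; where the
    circle encloses a corner the two adjacent edge arcs overlap and the
    overlap (``arccos(e1/d) + arccos(e2/d) - pi/2``) is restored once.

    Parameters are parallel arrays: circle centers ``(px, py)`` (must lie in
    the window) and radii ``d > 0``.
    """
    px = np.asarray(px, dtype=float)
    py = np.asarray(py, dtype=float)
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ValueError("circle radius d must be positive")
    if not window.contains(px, py).all():
        raise ValueError("circle centers must lie inside the window")

    left = px
    right = window.width - px
    bottom = py
    top = window.height - py

    def half_angle(e: np.ndarray) -> np.ndarray:
        # arccos clipped to [0,1]: edges farther than d contribute 0
        return np.arccos(np.clip(e / d, 0.0, 1.0))

    a_l, a_r, a_b, a_t = (half_angle(e) for e in (left, right, bottom, top))
    exterior = 2.0 * (a_l + a_r + a_b + a_t)

    for a1, a2, e1, e2 in ((a_l, a_b, left, bottom), (a_l, a_t, left, top),
                           (a_r, a_b, right, bottom), (a_r, a_t, right, top)):
        overlap = np.where(e1 * e1 + e2 * e2 < d * d, a1 + a2 - 0.5 * np.pi, 0.0)
        exterior = exterior - overlap

    frac = 1.0 - exterior / (2.0 * np.pi)
    if np.any(frac <= 0):
        raise ValueError("circle has no arc inside the window (radius too large)")
    return frac


def arc_fraction_inside(center: tuple[float, float], d: float, window: Window) -> float:
    """Scalar convenience wrapper around :func:`_arc_fractions`.

    Returns the proportion of the circle of radius ``d`` centered at
    ``center`` that lies inside the rectangle; 1.0 for interior circles,
    0.5 on an edge, 0.25 at a corner.
    """
    x, y = center
    return float(_arc_fractions(np.array([x]), np.array([y]), np.array([d]), window)[0])


# ---------------------------------------------------------------------------
# Ripley's K
# ---------------------------------------------------------------------------

@dataclass
class KEstimate:
    """Edge-corrected Ripley's K at one radius, with its normalization."""

    r: float
    k_hat: float       # µm²
    nk: float          # K / (pi r^2); 1.0 under CSR
    n_from: int
    n_to: int
    pair_count: int

    @property
    def is_univariate(self) -> bool:
        return self.n_from == self.n_to and self.pair_count >= 0  # informational only


def _same_pattern(pp_a: PointPattern, pp_b: PointPattern) -> bool:
    if pp_a is pp_b:
        return True
    return (pp_a.marker == pp_b.marker and pp_a.n == pp_b.n
            and np.array_equal(pp_a.points, pp_b.points))


def pair_weights(pp_from: PointPattern, pp_to: PointPattern, r: float) -> np.ndarray:
    """Isotropic-correction weight matrix for pairs with d <= r.

    Entry (i, j) is 1/arc_fraction at (from_i, d_ij) for counted pairs and 0
    otherwise.  For the same pattern, self-pairs and coincident duplicates
    (d = 0) are excluded; cross-type coincident pairs count with weight 1
    (the limiting interior fraction as d -> 0).
    """
    if r <= 0:
        raise ValueError("r must be positive")
    if pp_from.window != pp_to.window:
        raise ValueError("point patterns must share the same window")
    d = cdist(pp_from.points, pp_to.points)
    same = _same_pattern(pp_from, pp_to)
    if same:
        mask = (d <= r) & (d > 0)
    else:
        mask = d <= r
    weights = np.zeros_like(d)
    ii, jj = np.nonzero(mask)
    dv = d[ii, jj]
    w = np.ones_like(dv)
    pos = dv > 0
    if pos.any():
        w[pos] = 1.0 / _arc_fractions(pp_from.points[ii[pos], 0],
                                      pp_from.points[ii[pos], 1],
                                      dv[pos], pp_from.window)
    weights[ii, jj] = w
    return weights


def bivariate_k(pp_from: PointPattern, pp_to: PointPattern, r: float) -> KEstimate:
    """Edge-corrected (bivariate) Ripley's K estimate at radius ``r``.

    K_hat(r) = A / (n_from n_to) * sum over ordered pairs with 0 < d_ij <= r
    of 1/w_ij, where w_ij is the fraction of the circle through j centered at
    i that lies inside the window and A the window area.  When both patterns
    are the same, self-pairs are excluded and the denominator is n(n-1),
    giving the standard unbiased univariate estimator.
    """
    if pp_from.n < 1 or pp_to.n < 1:
        raise ValueError("both patterns must contain at least one point")
    window = pp_from.window
    if r > min(window.width, window.height) / 4.0:
        log.warning("radius %.1f µm is large relative to window %0.f x %0.f µm; "
                    "edge-correction weights may be unstable", r, window.width,
                    window.height)
    weights = pair_weights(pp_from, pp_to, r)
    same = _same_pattern(pp_from, pp_to)
    n_from, n_to = pp_from.n, pp_to.n
    denom = n_from * (n_to - 1) if same else n_from * n_to
    if denom == 0:
        raise ValueError("univariate K needs at least two points")
    k_hat = window.area * float(np.sum(weights)) / denom
    return KEstimate(r=r, k_hat=k_hat, nk=normalize_k(k_hat, r),
                     n_from=n_from, n_to=n_to,
                     pair_count=int(np.count_nonzero(weights)))


def normalize_k(k_hat: float, r: float) -> float:
    """nK(r) = K(r) / (pi r^2): observed-over-expected neighbor ratio.

    Under CSR the expectation is 1.0; e.g. nK(25) = 1.30 means 30% more "to"
    cells within 25 µm of a typical "from" cell than expected at random.
    """
    if r <= 0:
        raise ValueError("r must be positive")
    if k_hat < 0:
        raise ValueError("k_hat must be >= 0")
    return k_hat / (math.pi * r * r)


# ---------------------------------------------------------------------------
# Eligibility and positivity
# ---------------------------------------------------------------------------

def eligibility(pp: PointPattern, min_cells: int = DEFAULT_MIN_CELLS) -> bool:
    """A pattern enters spatial analysis only with >= ``min_cells`` points.

    Bivariate statistics require both patterns to be eligible; ineligible
    metrics are recorded as missing rather than computed on sparse patterns.
    """
    return pp.n >= min_cells


def spatial_positivity(roi: ROI, marker: Marker) -> PointPattern:
    """Cells counted as positive for spatial analysis: strong intensity only."""
    return roi.point_pattern(marker, intensities=(Intensity.STRONG,))


# ---------------------------------------------------------------------------
# Nearest-neighbor distances
# ---------------------------------------------------------------------------

@dataclass
class NNDistanceSet:
    """Directed nearest-neighbor distances from each source cell to a target type."""

    from_marker: Marker
    to_marker: Marker
    distances: np.ndarray  # one distance (µm) per source cell

    @property
    def median(self) -> float:
        return float(np.median(self.distances)) if len(self.distances) else math.nan


def nn_distances(pp_from: PointPattern, pp_to: PointPattern) -> NNDistanceSet:
    """Euclidean distance from each "from" point to its nearest "to" point.

    When both patterns are the same, each point's self-match is excluded.
    """
    if pp_to.n < 1:
        raise ValueError("to-pattern is empty: nearest-neighbor distance undefined")
    same = _same_pattern(pp_from, pp_to)
    if same and pp_to.n < 2:
        raise ValueError("same-pattern NN distances need at least two points")
    tree = cKDTree(pp_to.points)
    if same:
        dist, _ = tree.query(pp_from.points, k=2)
        out = dist[:, 1]
    else:
        dist, _ = tree.query(pp_from.points, k=1)
        out = np.atleast_1d(dist)
    return NNDistanceSet(from_marker=pp_from.marker, to_marker=pp_to.marker,
                         distances=np.asarray(out, dtype=float))


# ---------------------------------------------------------------------------
# Scaled 2D kernel density
# ---------------------------------------------------------------------------

@dataclass
class KDEGrid:
    """Product-Gaussian KDE of joint NN distances, scaled so max = 1.0.

    x is conventionally the distance to the nearest proliferating (Ki67+)
    cell and y the distance to the nearest apoptotic (Casp3+) cell.
    """

    x_grid: np.ndarray
    y_grid: np.ndarray
    density: np.ndarray    # (grid_n, grid_n), density[i, j] at (x_grid[j], y_grid[i])
    bandwidth_x: float
    bandwidth_y: float
    x_median: float
    y_median: float


def _scott_bandwidth(v: np.ndarray) -> float:
    # Normal-reference rule for a 2D product kernel: sigma * n^(-1/6).
    s = float(np.std(v, ddof=1))
    if s <= 0:
        # degenerate axis: fall back to a nominal 1% of scale so the density
        # concentrates at the observed value instead of failing
        s = max(1e-3, 0.01 * max(abs(float(np.mean(v))), 1.0))
        return s
    return s * len(v) ** (-1.0 / 6.0)


def kde2d_scaled(x: np.ndarray, y: np.ndarray, grid_n: int = 128) -> KDEGrid:
    """Gaussian-product KDE on a square grid over [0, max] per axis.

    The grid is divided by its maximum so the peak is exactly 1.0, matching
    the scaled-density presentation of joint NN-distance plots; per-axis
    medians are carried along for annotation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must be paired")
    if len(x) < 2:
        raise ValueError("kde2d_scaled requires at least 2 paired observations")
    hx = _scott_bandwidth(x)
    hy = _scott_bandwidth(y)
    gx = np.linspace(0.0, max(float(x.max()), 1e-9), grid_n)
    gy = np.linspace(0.0, max(float(y.max()), 1e-9), grid_n)
    # separable kernel: density = Kx @ Ky.T up to constants
    ex = np.exp(-0.5 * ((gx[:, None] - x[None, :]) / hx) ** 2)
    ey = np.exp(-0.5 * ((gy[:, None] - y[None, :]) / hy) ** 2)
    dens = (ey @ ex.T) / (2.0 * np.pi * hx * hy * len(x))
    peak = dens.max()
    if peak > 0:
        dens = dens / peak
    return KDEGrid(x_grid=gx, y_grid=gy, density=dens,
                   bandwidth_x=hx, bandwidth_y=hy,
                   x_median=float(np.median(x)), y_median=float(np.median(y)))
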