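"""The 27-value border-irregularity descriptor.

A lesion is summarized by [FD, C, ZM1..ZM25]:

* FD — box-counting fractal dimension of the border trace, the slope of
  log N(eps) against log(1/eps), where N(eps) is the number of eps-sized
  grid cells touched by the border.  Smooth borders sit near 1, highly
  indented borders drift toward 2.
* C — convexity, the perimeter of the convex hull divided by the lesion
  perimeter (both as 8-connected polygonal arc lengths, diagonal steps
  counting sqrt(2)).  Convex shapes score 1; indentations push C below 1.
* ZM1..ZM25 — magnitudes of the Zernike moments up to order n = 8
  (all repetitions m >= 0 with n - m even), computed on the filled mask
  mapped to the unit disc at its centroid and normalized to unit mass.
  Magnitudes are rotation invariant, and the unit-mass normalization
  pins |Z_00| at 1/pi ~= 0.3183 for every nonzero mask, which makes ZM1
  a useful built-in sanity check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import factorial

import numpy as np

from .border import BorderTrace, arc_length, trace_boundary

#: (n, m) pairs for order 8, sorted by n then m — exactly 25 of them.
ZERNIKE_PAIRS: tuple[tuple[int, int], ...] = tuple(
    (n, m) for n in range(9) for m in range(n % 2, n + 1, 2)
)

FEATURE_NAMES: tuple[str, ...] = ("FD", "C") + tuple(
    f"ZM{i + 1}" for i in range(len(ZERNIKE_PAIRS))
)


@dataclass
class BoxCountCurve:
    eps: np.ndarray      # box sides, pixels
    counts: np.ndarray   # occupied boxes N(eps)
    dimension: float     # least-squares slope of log N vs log(1/eps)


def _trace_points(trace) -> np.ndarray:
    if isinstance(trace, BorderTrace):
        return trace.points
    pts = np.asarray(trace)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("trace must be a BorderTrace or an (n, 2) point array")
    return pts


def box_count(trace, eps: int) -> int:
    """Number of eps x eps grid cells (anchored at the bounding-box
    origin) containing at least one border pixel."""
    if eps < 1:
        raise ValueError("eps must be >= 1")
    pts = _trace_points(trace)
    if len(pts) == 0:
        raise ValueError("empty trace")
    cells = (pts - pts.min(axis=0)) // int(eps)
    return int(np.unique(cells, axis=0).shape[0])


def box_count_curve(trace) -> BoxCountCurve:
    """Dyadic box-counting curve and its fitted slope.

    Box sides run through powers of two from 1 to half the shorter
    bounding-box side; scales where the border fits in a single box
    carry no slope information and are dropped from the fit.
    """
    pts = _trace_points(trace)
    span = pts.max(axis=0) - pts.min(axis=0) + 1
    if span.max() < 8:
        raise ValueError(
            f"trace spans only {tuple(span)} pixels; too small for a box-count fit"
        )
    # ladder to a quarter of the long side: beyond that nearly everything
    # fits in one box and the log-log points carry no slope
    sizes = []
    e = 1
    while e <= max(2, span.max() // 4):
        sizes.append(e)
        e *= 2
    eps = np.array(sizes)
    counts = np.array([box_count(pts, int(e)) for e in eps])
    use = counts > 1
    if use.sum() < 2:
        raise ValueError("too few informative scales for a box-counting fit")
    slope = np.polyfit(np.log(1.0 / eps[use]), np.log(counts[use]), 1)[0]
    return BoxCountCurve(eps=eps, counts=counts, dimension=float(slope))


def fractal_dimension(trace) -> float:
    """Box-counting fractal dimension of a border trace.

    Values are expected in [1, 2]; estimates outside that range (which
    can happen for degenerate traces) trigger a warning but are
    returned unclamped.
    """
    d = box_count_curve(trace).dimension
    if not 0.9 <= d <= 2.1:
        warnings.warn(
            f"fractal dimension estimate {d:.3f} is outside the expected [1, 2] range",
            stacklevel=2,
        )
    return d


def zernike_radial(n: int, m: int, rho) -> np.ndarray | float:
    """Radial Zernike polynomial R_nm(rho) as the exact finite sum."""
    m = abs(int(m))
    n = int(n)
    if m > n:
        raise ValueError(f"need |m| <= n, got n={n}, m={m}")
    if (n - m) % 2:
        raise ValueError(f"n - |m| must be even, got n={n}, m={m}")
    rho = np.asarray(rho, dtype=float)
    out = np.zeros_like(rho)
    for a in range((n - m) // 2 + 1):
        coef = (
            (-1) ** a
            * factorial(n - a)
            / (factorial(a) * factorial((n + m) // 2 - a) * factorial((n - m) // 2 - a))
        )
        out = out + coef * rho ** (n - 2 * a)
    return float(out) if out.ndim == 0 else out


def zernike_vector(mask: np.ndarray, order: int = 8) -> np.ndarray:
    """Zernike moment magnitudes |Z_nm| of a binary mask.

    The foreground is mapped to the unit disc centred at its centroid
    and scaled by the largest centroid-to-pixel distance; the indicator
    is normalized to unit mass, and

        Z_nm = (n + 1)/pi * sum_px conj(V_nm(rho, theta)) f(px)

    is evaluated for every parity-valid (n, m >= 0) pair up to
    ``order``.  At order 8 that is 25 magnitudes.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    rr, cc = np.nonzero(mask)
    r0, c0 = rr.mean(), cc.mean()
    dr, dc = rr - r0, cc - c0
    radius = np.hypot(dr, dc).max()
    if radius == 0:
        radius = 1.0
    rho = np.hypot(dr, dc) / radius
    theta = np.arctan2(dr, dc)
    f = 1.0 / rr.size  # unit-mass normalization
    pairs = [(n, m) for n in range(order + 1) for m in range(n % 2, n + 1, 2)]
    mags = np.empty(len(pairs))
    for k, (n, m) in enumerate(pairs):
        radial = zernike_radial(n, m, rho)
        z = (n + 1) / np.pi * np.sum(radial * np.exp(-1j * m * theta) * f)
        mags[k] = abs(z)
    return mags


def convexity(mask: np.ndarray) -> float:
    """Convex-hull perimeter over lesion perimeter, capped at 1.

    Both perimeters are polygonal arc lengths of Moore-traced
    boundaries with sqrt(2) diagonal steps, which keeps the ratio at or
    below 1 up to discretization error; the cap absorbs that error for
    convex shapes.
    """
    from skimage.morphology import convex_hull_image

    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    perim = trace_boundary(mask).perimeter
    if perim == 0:
        return 1.0
    hull_perim = trace_boundary(convex_hull_image(mask)).perimeter
    return min(hull_perim / perim, 1.0)


def irregularity_vector(mask: np.ndarray, trace=None) -> np.ndarray:
    """The full 27-value descriptor [FD, C, ZM1..ZM25].

    When no border trace is supplied the mask's own Moore boundary is
    used, so the descriptor can be computed from a segmentation alone.
    """
    if trace is None:
        trace = trace_boundary(mask)
    vec = np.empty(27)
    vec[0] = fractal_dimension(trace)
    vec[1] = convexity(mask)
    vec[2:] = zernike_vector(mask, order=8)
    return vec


def features_to_csv(path, vectors: np.ndarray, labels=None, ids=None) -> None:
    """Write feature rows as CSV with the standard FD, C, ZM1..ZM25[, L] layout."""
    import pandas as pd

    vectors = np.atleast_2d(vectors)
    df = pd.DataFrame(vectors, columns=list(FEATURE_NAMES))
    if ids is not None:
        df.insert(0, "id", list(ids))
    if labels is not None:
        df["L"] = list(labels)
    df.to_csv(path, index=False)
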