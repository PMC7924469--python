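"""Four-step Canny edge detection and closed border tracing.

The detector follows the classical four stages — separable Gaussian
smoothing, gradient estimation, non-maximum suppression, and two-level
hysteresis linking — but with the gradient taken on a 2x2 stencil
(a Roberts-like operator averaged over the cell) rather than the more
common 3x3 Sobel:

    R_x = (-S1 + S2 - S3 + S4) / 2
    R_y = ( S1 + S2 - S3 - S4) / 2

with S1..S4 the samples at (r, c), (r, c+1), (r+1, c), (r+1, c+1).
Magnitude is sqrt(R_x^2 + R_y^2) and direction a quadrant-aware
arctangent (which also covers R_x = 0, where a plain ratio is
undefined).  The final lesion border is returned as an ordered,
8-connected closed trace obtained by Moore-neighbor boundary following.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

EIGHT = np.ones((3, 3), dtype=bool)  # 8-connectivity structuring element


@dataclass
class GradientField:
    magnitude: np.ndarray
    direction: np.ndarray  # radians, quadrant-aware
    rx: np.ndarray
    ry: np.ndarray


@dataclass
class CannyParams:
    """sigma in pixels; low/high hysteresis thresholds in magnitude units.

    When ``high`` is None it is set per image to the 90th percentile of
    nonzero thinned magnitudes, and ``low`` to 0.4 * high.
    """

    sigma: float = 1.4
    low: float | None = None
    high: float | None = None

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.low is not None and self.high is not None:
            if not (0 <= self.low < self.high):
                raise ValueError("need 0 <= low < high")


@dataclass
class BorderTrace:
    """Ordered border coordinates plus the binary edge map they came from."""

    points: np.ndarray  # (n, 2) int array of (row, col), ordered
    closed: bool
    edge_map: np.ndarray | None = None
    perimeter: float = field(init=False)

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=int)
        self.perimeter = arc_length(self.points, closed=self.closed)


def arc_length(points: np.ndarray, closed: bool = True) -> float:
    """Polygonal 8-connected arc length: unit steps count 1, diagonals sqrt(2)."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        return 0.0
    if closed:
        pts = np.vstack([pts, pts[:1]])
    steps = np.diff(pts, axis=0)
    return float(np.hypot(steps[:, 0], steps[:, 1]).sum())


def rasterize_polyline(vertices: np.ndarray, closed: bool = False) -> BorderTrace:
    """Rasterize float (row, col) vertices into an ordered pixel chain."""
    from skimage.draw import line

    verts = np.asarray(vertices, dtype=float)
    verts = verts - verts.min(axis=0)  # nonnegative pixel coordinates
    vi = np.rint(verts).astype(int)
    if closed:
        vi = np.vstack([vi, vi[:1]])
    pts: list[tuple[int, int]] = []
    for p, q in zip(vi[:-1], vi[1:]):
        rr, cc = line(p[0], p[1], q[0], q[1])
        seg = list(zip(rr.tolist(), cc.tolist()))
        if pts and seg and seg[0] == pts[-1]:
            seg = seg[1:]
        pts.extend(seg)
    if closed and len(pts) > 1 and pts[-1] == pts[0]:
        pts = pts[:-1]
    return BorderTrace(points=np.asarray(pts, dtype=int), closed=closed)


def gaussian_smooth(image: np.ndarray, sigma: float) -> np.ndarray:
    """Separable 1-D Gaussian on rows then columns.

    The kernel is truncated at +/- 4 sigma and renormalized to unit sum,
    so constant regions pass through unchanged.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    img = np.asarray(image, dtype=float)
    radius = max(1, int(np.ceil(4 * sigma)))
    x = np.arange(-radius, radius + 1, dtype=float)
    kernel = np.exp(-(x**2) / (2 * sigma**2))
    kernel /= kernel.sum()
    out = ndimage.convolve1d(img, kernel, axis=0, mode="nearest")
    out = ndimage.convolve1d(out, kernel, axis=1, mode="nearest")
    return out


def gradient_2x2(image: np.ndarray) -> GradientField:
    """2x2-stencil gradient; the last row/column is edge-replicated."""
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.shape[0] < 2 or img.shape[1] < 2:
        raise ValueError("image must be 2-D and at least 2x2")
    padded = np.pad(img, ((0, 1), (0, 1)), mode="edge")
    s1 = padded[:-1, :-1]
    s2 = padded[:-1, 1:]
    s3 = padded[1:, :-1]
    s4 = padded[1:, 1:]
    rx = (-s1 + s2 - s3 + s4) / 2.0
    ry = (s1 + s2 - s3 - s4) / 2.0
    mag = np.hypot(rx, ry)
    direction = np.arctan2(ry, rx)
    return GradientField(magnitude=mag, direction=direction, rx=rx, ry=ry)


def nonmax_suppress(fieldg: GradientField) -> np.ndarray:
    """Keep pixels strictly larger than both 3x3 neighbors along the
    gradient direction (quantized to 0/45/90/135-degree sectors)."""
    mag = fieldg.magnitude
    # direction in array coordinates: d(row) = -ry, d(col) = rx
    phi = np.rad2deg(np.arctan2(-fieldg.ry, fieldg.rx)) % 180.0
    padded = np.pad(mag, 1, mode="constant")
    center = padded[1:-1, 1:-1]

    def shifted(dr, dc):
        return padded[1 + dr : padded.shape[0] - 1 + dr, 1 + dc : padded.shape[1] - 1 + dc]

    sector0 = (phi < 22.5) | (phi >= 157.5)   # gradient along columns
    sector45 = (phi >= 22.5) & (phi < 67.5)   # down-right / up-left
    sector90 = (phi >= 67.5) & (phi < 112.5)  # gradient along rows
    sector135 = (phi >= 112.5) & (phi < 157.5)
    keep = np.zeros_like(mag, dtype=bool)
    keep |= sector0 & (center > shifted(0, 1)) & (center > shifted(0, -1))
    keep |= sector45 & (center > shifted(1, 1)) & (center > shifted(-1, -1))
    keep |= sector90 & (center > shifted(1, 0)) & (center > shifted(-1, 0))
    keep |= sector135 & (center > shifted(1, -1)) & (center > shifted(-1, 1))
    return np.where(keep & (mag > 0), mag, 0.0)


def hysteresis_link(thinned: np.ndarray, low: float, high: float) -> np.ndarray:
    """Two-level edge linking.

    Pixels above ``high`` are edges; pixels in (low, high] survive only
    when 8-connected (transitively) to a strong pixel; pixels at or
    below ``low`` never do.
    """
    if not 0 <= low < high:
        raise ValueError("need 0 <= low < high")
    strong = thinned > high
    candidate = thinned > low
    labels, n = ndimage.label(candidate, structure=EIGHT)
    if n == 0:
        return np.zeros_like(candidate)
    keep = np.zeros(n + 1, dtype=bool)
    keep[np.unique(labels[strong])] = True
    keep[0] = False
    return keep[labels]


def trace_boundary(mask: np.ndarray) -> BorderTrace:
    """Ordered closed boundary of a binary region (Moore-neighbor tracing).

    Returns foreground pixels adjacent to the background, chained so
    consecutive points (and the last/first pair) are 8-neighbors.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask has no boundary")
    padded = np.pad(mask, 1)
    rs, cs = np.nonzero(padded)
    start = (rs[0], cs[0])  # topmost, then leftmost foreground pixel
    # clockwise Moore neighborhood starting west
    nbrs = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]
    trace = [start]
    prev_dir = 3  # primes the first clockwise scan to begin at west
    cur = start
    max_steps = 4 * padded.size
    for _ in range(max_steps):
        found = False
        # resume clockwise scan just past the backtrack direction
        for k in range(8):
            d = (prev_dir + 5 + k) % 8
            dr, dc = nbrs[d]
            r, c = cur[0] + dr, cur[1] + dc
            if padded[r, c]:
                if (r, c) == start and len(trace) > 1:
                    pts = np.asarray(trace, dtype=int) - 1  # undo padding
                    return BorderTrace(points=pts, closed=True)
                trace.append((r, c))
                cur = (r, c)
                prev_dir = d
                found = True
                break
        if not found:  # isolated pixel
            pts = np.asarray(trace, dtype=int) - 1
            return BorderTrace(points=pts, closed=True)
    raise RuntimeError("boundary tracing failed to close")


def canny_border(
    image: np.ndarray, params: CannyParams | None = None
) -> BorderTrace:
    """Full Canny pass plus extraction of the longest closed contour.

    Accepts either a binary mask or a smoothed grayscale image.  The
    edge map's 8-connected components are scanned from largest to
    smallest; the first one that encloses an area is boundary-traced
    into the ordered lesion border.
    """
    params = params or CannyParams()
    img = np.asarray(image, dtype=float)
    if img.max() == img.min():
        raise ValueError("constant image has no edges")
    smoothed = gaussian_smooth(img, params.sigma)
    fieldg = gradient_2x2(smoothed)
    thinned = nonmax_suppress(fieldg)
    high = params.high
    if high is None:
        nz = thinned[thinned > 0]
        if nz.size == 0:
            raise ValueError("no gradient response; cannot pick thresholds")
        high = float(np.percentile(nz, 90))
        low = 0.4 * high
    else:
        low = params.low if params.low is not None else 0.4 * high
    edges = hysteresis_link(thinned, low, high)
    labels, n = ndimage.label(edges, structure=EIGHT)
    if n == 0:
        raise ValueError("no closed contour found (0 edge pixels kept)")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    order = np.argsort(sizes)[::-1] + 1
    best = None
    for lab in order:
        component = labels == lab
        filled = ndimage.binary_fill_holes(component)
        enclosed = filled.sum() - component.sum()
        if enclosed > component.sum():  # a genuine loop, not a pixel pocket
            best = filled
            break
    if best is None:
        # strict non-maximum suppression can nick small gaps into an
        # otherwise closed contour; bridge them (dilate, fill, erode back)
        # with growing radius before giving up
        for it in (1, 2, 3):
            dil = ndimage.binary_dilation(edges, structure=EIGHT, iterations=it)
            filled = ndimage.binary_fill_holes(dil)
            if filled.sum() > dil.sum():
                shrunk = ndimage.binary_erosion(
                    filled, structure=EIGHT, iterations=it, border_value=1
                )
                if not shrunk.any():
                    continue
                comp, k = ndimage.label(shrunk, structure=EIGHT)
                areas = ndimage.sum_labels(
                    np.ones_like(comp), comp, index=np.arange(1, k + 1)
                )
                best = comp == (1 + int(np.argmax(areas)))
                break
    if best is None:
        raise ValueError(
            f"no closed contour found ({int(edges.sum())} edge pixels, "
            f"{n} open components)"
        )
    trace = trace_boundary(best)
    trace.edge_map = edges
    return trace
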