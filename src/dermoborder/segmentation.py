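"""Lesion extraction by fuzzy clustering with a type-II fuzzy threshold.

The segmentation treats a grayscale lesion image as a mixture of two
intensity populations (pigmented lesion vs. surrounding skin) and
proceeds in four stages:

1. fuzzy c-means (FCM) assigns each pixel graded memberships u_ij to
   c clusters by minimizing J = sum_j sum_i u_ij^m ||x_j - v_i||^2;
2. an *ambiguity threshold* tau is found by sliding an S-shaped
   membership function across the gray range and maximizing the
   *ultrafuzziness* — the histogram-weighted width of the band between
   the type-II lower/upper memberships mu^alpha and mu^(1/alpha);
3. *gradual-focusing defuzzification*: pixels whose best membership
   clears tau are committed immediately (the coarse image structure);
   the remaining ambiguous ("weak") pixels are swept in raster order
   and joined to the majority cluster of their already-committed
   neighbors, ties reverting to the pixel's own argmax cluster;
4. the darker cluster is kept as the lesion, cleaned up (largest
   8-connected component, holes filled) and smoothed with an
   edge-preserving filter.

Because step 2 is a histogram computation, it is run on the lesion
cluster's membership map rescaled to [0, 255]; the maximizing position
g_pos therefore converts directly to a membership threshold
tau = g_pos / 255.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .border import EIGHT

L_GRAY = 256


class DegenerateImageError(ValueError):
    """Raised for constant images where clustering/thresholding is undefined."""


class NoLesionError(ValueError):
    """Raised when segmentation cleanup leaves no foreground."""


@dataclass
class FuzzyPartition:
    """FCM result: memberships (c, n), one column per pixel."""

    memberships: np.ndarray
    centroids: np.ndarray
    m: float
    shape: tuple[int, int] | None = None  # image shape for reshaping
    objective: list[float] = field(default_factory=list)

    def membership_image(self, cluster: int) -> np.ndarray:
        if self.shape is None:
            raise ValueError("partition was not built from an image")
        return self.memberships[cluster].reshape(self.shape)


@dataclass
class UltrafuzzinessScan:
    gamma: np.ndarray  # ultrafuzziness at each candidate position g
    g_pos: int         # maximizing position (lowest on ties)
    tau: float         # threshold: tau = g_pos on the scanned scale


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Luminance conversion (ITU-R 601 weights); grayscale passes through."""
    arr = np.asarray(image)
    if arr.ndim == 2:
        return arr.astype(np.uint8, copy=True) if arr.dtype == np.uint8 else np.clip(
            np.rint(arr), 0, L_GRAY - 1
        ).astype(np.uint8)
    if arr.ndim == 3 and arr.shape[2] == 3:
        lum = arr[..., 0] * 0.299 + arr[..., 1] * 0.587 + arr[..., 2] * 0.114
        return np.clip(np.rint(lum), 0, L_GRAY - 1).astype(np.uint8)
    raise ValueError(f"expected 1- or 3-channel image, got shape {arr.shape}")


def fcm_objective(values: np.ndarray, memberships: np.ndarray, centroids: np.ndarray, m: float) -> float:
    """Direct evaluation of J = sum_j sum_i u_ij^m (x_j - v_i)^2."""
    d2 = (values[None, :] - centroids[:, None]) ** 2
    return float(np.sum(memberships**m * d2))


def fcm_cluster(
    image: np.ndarray,
    c: int = 2,
    m: float = 2.0,
    tol: float = 1e-5,
    max_iter: int = 300,
    seed: int = 0,
) -> FuzzyPartition:
    """Fuzzy c-means on pixel intensities.

    Memberships follow u_ij = 1 / sum_k (d_ij / d_kj)^(2/(m-1)) and
    centroids are the u^m-weighted means; iteration stops when the
    largest centroid move falls below ``tol`` (identical centroids being
    the limiting case) or after ``max_iter`` rounds.  Centroids start at
    evenly spread percentiles of the intensity range, which makes the
    fit deterministic; ``seed`` only matters for the jitter applied if
    percentile initialization collapses.
    """
    if c < 2:
        raise ValueError("c must be >= 2")
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")
    arr = np.asarray(image, dtype=float)
    shape = arr.shape if arr.ndim == 2 else None
    x = arr.ravel()
    if np.unique(x).size < c:
        raise DegenerateImageError(
            f"image has fewer than c={c} distinct gray values; clustering is degenerate"
        )
    centroids = np.percentile(x, np.linspace(25, 75, c))
    if np.unique(centroids).size < c:
        rng = np.random.default_rng(seed)
        centroids = np.sort(centroids + rng.uniform(-0.5, 0.5, size=c))
    exponent = 2.0 / (m - 1.0)
    objective: list[float] = []
    memberships = None
    for _ in range(max_iter):
        d = np.abs(x[None, :] - centroids[:, None])
        d = np.maximum(d, 1e-12)  # pixels sitting on a centroid
        inv = d ** (-exponent)
        memberships = inv / inv.sum(axis=0, keepdims=True)
        objective.append(fcm_objective(x, memberships, centroids, m))
        um = memberships**m
        new_centroids = (um @ x) / um.sum(axis=1)
        if np.max(np.abs(new_centroids - centroids)) < tol:
            centroids = new_centroids
            break
        centroids = new_centroids
    d = np.maximum(np.abs(x[None, :] - centroids[:, None]), 1e-12)
    inv = d ** (-exponent)
    memberships = inv / inv.sum(axis=0, keepdims=True)
    return FuzzyPartition(
        memberships=memberships, centroids=centroids, m=m, shape=shape, objective=objective
    )


def s_membership(g, a: float, b: float, c: float):
    """Piecewise-quadratic S-function with knots a < b < c.

    0 below a, rises quadratically to 1/2 at the crossover b, then
    mirrors up to 1 at c; monotone non-decreasing.
    """
    if not a < b < c:
        raise ValueError(f"knots must satisfy a < b < c, got {(a, b, c)}")
    scalar = np.isscalar(g) or np.ndim(g) == 0
    g = np.atleast_1d(np.asarray(g, dtype=float))
    out = np.zeros_like(g)
    rising = (g > a) & (g <= b)
    out[rising] = 0.5 * ((g[rising] - a) / (b - a)) ** 2
    upper = (g > b) & (g <= c)
    out[upper] = 1.0 - 0.5 * ((g[upper] - c) / (c - b)) ** 2
    out[g > c] = 1.0
    return float(out[0]) if scalar else out


def type2_bounds(mu, alpha: float = 2.0):
    """Lower/upper type-II memberships (mu^alpha, mu^(1/alpha)).

    alpha in (1, 2] is the recommended range for image data; the band
    mu_U - mu_L is the footprint of uncertainty.
    """
    if not 1.0 < alpha <= 2.0:
        raise ValueError(
            f"alpha must lie in (1, 2] (recommended range for image data), got {alpha}"
        )
    mu = np.asarray(mu, dtype=float)
    if np.any(mu < 0) or np.any(mu > 1):
        raise ValueError("memberships must lie in [0, 1]")
    return mu**alpha, mu ** (1.0 / alpha)


def ultrafuzziness(histogram: np.ndarray, mu: np.ndarray, alpha: float = 2.0) -> float:
    """gamma~ = (1/MN) sum_g h(g) * [mu_U(g) - mu_L(g)] over gray levels."""
    h = np.asarray(histogram, dtype=float)
    mu_l, mu_u = type2_bounds(mu, alpha)
    total = h.sum()
    if total <= 0:
        raise ValueError("histogram is empty")
    return float(np.sum(h * (mu_u - mu_l)) / total)


def ambiguity_threshold(
    image: np.ndarray, alpha: float = 2.0, bandwidth: float = (L_GRAY - 1) / 4.0
) -> UltrafuzzinessScan:
    """Slide an S-function over the gray range; tau is the position of
    maximum ultrafuzziness (lowest position on ties).

    At each candidate position g the S-function knots are a = g - bw,
    b = g, c = g + bw, clipped to [0, 255] (with a half-level epsilon so
    the knots stay strictly ordered at the range ends).
    """
    arr = np.asarray(image)
    if arr.min() == arr.max():
        raise DegenerateImageError("constant image: ultrafuzziness has no maximum")
    hist = np.bincount(
        np.clip(np.rint(arr.ravel()), 0, L_GRAY - 1).astype(int), minlength=L_GRAY
    )
    levels = np.arange(L_GRAY, dtype=float)
    gamma = np.empty(L_GRAY)
    for g in range(L_GRAY):
        a = max(0.0, g - bandwidth)
        cc = min(float(L_GRAY - 1), g + bandwidth)
        a = min(a, g - 0.5)
        cc = max(cc, g + 0.5)
        mu = s_membership(levels, a, float(g), cc)
        gamma[g] = ultrafuzziness(hist, mu, alpha)
    g_pos = int(np.argmax(gamma))  # argmax returns the lowest index on ties
    return UltrafuzzinessScan(gamma=gamma, g_pos=g_pos, tau=float(g_pos))


def gradual_focus_defuzzify(
    partition: FuzzyPartition, tau: float, window: int = 3
) -> np.ndarray:
    """Resolve ambiguous pixels by neighborhood majority (gradual focusing).

    Pixels whose maximum membership reaches ``tau`` take their argmax
    cluster outright.  The remaining weak pixels are swept in raster
    order and assigned to the majority cluster among the
    already-assigned pixels of their ``window`` x ``window``
    neighborhood; when the neighborhood frequencies tie, the pixel keeps
    its own argmax cluster.  Sweeps repeat until no weak pixel remains;
    a sweep that makes no progress falls back to argmax for the rest
    (this covers the all-weak start, e.g. tau = 1).

    Returns the integer cluster-label image.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    if not 0.0 <= tau <= 1.0:
        raise ValueError("tau must lie in [0, 1]")
    if partition.shape is None:
        raise ValueError("partition must come from a 2-D image")
    h, w = partition.shape
    u = partition.memberships.reshape(-1, h, w)
    best = np.argmax(u, axis=0)  # ties -> lower cluster index
    strength = np.max(u, axis=0)
    labels = np.where(strength >= tau, best, -1)
    half = window // 2
    n_clusters = u.shape[0]
    while True:
        weak = np.argwhere(labels < 0)
        if weak.size == 0:
            break
        assigned_any = False
        for r, c in weak:
            r0, r1 = max(0, r - half), min(h, r + half + 1)
            c0, c1 = max(0, c - half), min(w, c + half + 1)
            patch = labels[r0:r1, c0:c1]
            counts = np.bincount(patch[patch >= 0], minlength=n_clusters)
            if counts.sum() == 0:
                continue  # no committed neighbors yet; next sweep
            top = counts.max()
            winners = np.flatnonzero(counts == top)
            labels[r, c] = winners[0] if winners.size == 1 else best[r, c]
            assigned_any = True
        if not assigned_any:
            # isolated all-weak region: seed with the FCM argmax (tie rule)
            labels[labels < 0] = best[labels < 0]
    return labels


def smooth_edges(image: np.ndarray, scale: int = 1) -> np.ndarray:
    """Edge-preserving smoothing: median filter with window 2*scale + 1.

    Removes speckle/texture below ``scale`` while moving ideal step
    edges by at most one pixel; ``scale = 0`` is the identity.
    """
    if scale < 0:
        raise ValueError("scale must be >= 0")
    if scale == 0:
        return np.asarray(image).copy()
    arr = np.asarray(image)
    if arr.dtype == bool:
        return ndimage.median_filter(arr.astype(np.uint8), size=2 * scale + 1) > 0
    return ndimage.median_filter(arr, size=2 * scale + 1)


def extract_lesion_mask(
    image: np.ndarray,
    c: int = 2,
    m: float = 2.0,
    alpha: float = 2.0,
    bandwidth: float = (L_GRAY - 1) / 4.0,
    window: int = 3,
    smoothing_scale: int = 2,
    seed: int = 0,
    darker_is_lesion: bool = True,
    threshold_on: str = "membership",
) -> np.ndarray:
    """Full segmentation: FCM -> ambiguity threshold -> gradual focusing
    -> cluster selection -> cleanup -> edge-preserving smoothing.

    The lesion cluster is the one with the darker centroid (pigmented
    lesions; pass ``darker_is_lesion=False`` for inverted contrast).
    The ambiguity scan runs on the lesion cluster's membership map
    rescaled to [0, 255] by default, or on the raw gray image with
    ``threshold_on='image'``.
    """
    gray = to_grayscale(image)
    partition = fcm_cluster(gray, c=c, m=m, seed=seed)
    lesion_cluster = int(
        np.argmin(partition.centroids) if darker_is_lesion else np.argmax(partition.centroids)
    )
    if threshold_on == "membership":
        mu_img = partition.membership_image(lesion_cluster)
        scan = ambiguity_threshold(
            np.rint(mu_img * (L_GRAY - 1)), alpha=alpha, bandwidth=bandwidth
        )
    elif threshold_on == "image":
        scan = ambiguity_threshold(gray, alpha=alpha, bandwidth=bandwidth)
    else:
        raise ValueError("threshold_on must be 'membership' or 'image'")
    tau = scan.g_pos / (L_GRAY - 1)
    labels = gradual_focus_defuzzify(partition, tau=tau, window=window)
    mask = labels == lesion_cluster
    if not mask.any():
        raise NoLesionError("no lesion found: lesion cluster is empty")
    comp, n = ndimage.label(mask, structure=EIGHT)
    sizes = ndimage.sum_labels(np.ones_like(comp), comp, index=np.arange(1, n + 1))
    mask = comp == (1 + int(np.argmax(sizes)))
    mask = ndimage.binary_fill_holes(mask)
    mask = smooth_edges(mask, smoothing_scale)
    if not mask.any():
        raise NoLesionError("no lesion found after cleanup")
    return mask
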