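"""Seeded synthetic lesions with controllable border roughness.

Real dermoscopy images provide a roughly centred pigmented (dark) lesion
on lighter skin, a ground-truth mask, and a clinical regular/irregular
label.  The generators here emulate exactly that at a parametric level:
smooth elliptical lesions are labelled regular (1) and fractally
perturbed star-convex blobs are labelled irregular (0), following the
convention used throughout the package (label 1 = regular,
0 = irregular).  Every generator is a pure function of its parameters
and seed, so downstream stages can be tested bit-reproducibly without
any external data.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from PIL import Image

from .border import BorderTrace, rasterize_polyline

L_GRAY = 256  #: number of gray levels
DEFAULT_SIZE = 256
DEFAULT_BACKGROUND = 200


@dataclass(frozen=True)
class SyntheticLesion:
    """A synthetic lesion image with its ground truth.

    Attributes
    ----------
    image : uint8 array, shape (size, size)
        Grayscale image: dark lesion on a lighter background plus
        additive Gaussian noise clipped to [0, 255].
    mask : bool array, shape (size, size)
        Noise-free ground-truth mask, True = lesion.
    label : int
        1 = regular border, 0 = irregular border.
    roughness : float
        Radial perturbation amplitude used to draw the outline
        (0 for exact ellipses).
    seed : int
    """

    image: np.ndarray
    mask: np.ndarray
    label: int
    roughness: float
    seed: int


def _rng_pair(seed: int) -> tuple[np.random.Generator, np.random.Generator]:
    # independent shape / noise streams so the roughness -> 0 limit of an
    # irregular lesion matches the disc of the same radius bit for bit
    return (
        np.random.default_rng([int(seed), 0]),
        np.random.default_rng([int(seed), 1]),
    )


def _fill_polar_outline(size: int, radii: np.ndarray, thetas: np.ndarray) -> np.ndarray:
    """Rasterize a star-convex outline r(theta) centred in the canvas."""
    from skimage.draw import polygon

    c0 = (size - 1) / 2.0
    rr = c0 + radii * np.sin(thetas)
    cc = c0 + radii * np.cos(thetas)
    mask = np.zeros((size, size), dtype=bool)
    pr, pc = polygon(rr, cc, shape=mask.shape)
    mask[pr, pc] = True
    return mask


def _render(
    mask: np.ndarray,
    contrast: float,
    noise_sd: float,
    noise_rng: np.random.Generator,
    background: float = DEFAULT_BACKGROUND,
) -> np.ndarray:
    img = np.full(mask.shape, float(background))
    img[mask] = background - contrast
    if noise_sd > 0:
        img = img + noise_rng.normal(0.0, noise_sd, size=mask.shape)
    return np.clip(np.rint(img), 0, L_GRAY - 1).astype(np.uint8)


def make_regular_lesion(
    size: int = DEFAULT_SIZE,
    axes: tuple[float, float] = (60.0, 40.0),
    contrast: float = 120.0,
    noise_sd: float = 8.0,
    seed: int = 0,
) -> SyntheticLesion:
    """Dark filled ellipse on a lighter background; label = regular (1).

    ``axes`` are the two semi-axes in pixels and must fit in the canvas
    with an 8-pixel margin.  The ground-truth mask is the noise-free
    ellipse.
    """
    if size < 64:
        raise ValueError(f"size must be >= 64, got {size}")
    if contrast <= 0:
        raise ValueError("contrast must be > 0")
    a, b = float(axes[0]), float(axes[1])
    if a <= 0 or b <= 0 or max(a, b) > size / 2 - 8:
        raise ValueError(
            f"axes {axes} must be positive and fit inside a {size}x{size} "
            "image with an 8-pixel margin"
        )
    _, noise_rng = _rng_pair(seed)
    thetas = np.linspace(0.0, 2 * np.pi, 720, endpoint=False)
    radii = a * b / np.sqrt((b * np.cos(thetas)) ** 2 + (a * np.sin(thetas)) ** 2)
    mask = _fill_polar_outline(size, radii, thetas)
    image = _render(mask, contrast, noise_sd, noise_rng)
    return SyntheticLesion(image=image, mask=mask, label=1, roughness=0.0, seed=int(seed))


def make_irregular_lesion(
    size: int = DEFAULT_SIZE,
    base_radius: float = 60.0,
    roughness: float = 0.35,
    harmonics: int = 24,
    contrast: float = 120.0,
    noise_sd: float = 8.0,
    seed: int = 0,
) -> SyntheticLesion:
    """Star-convex blob with a 1/f-perturbed radius; label = irregular (0).

    The outline is r(theta) = R * (1 + roughness * p(theta)) where p is a
    zero-mean sum of sinusoidal harmonics (orders 2..``harmonics``) with
    seeded random amplitudes and phases, weighted 1/k so low-frequency
    lobes dominate and higher orders add fractal detail; p is scaled to
    peak amplitude 1, so ``roughness`` is the peak relative radial
    deviation and any value below 1 keeps the radius positive.
    ``roughness = 0`` reproduces the disc of radius R exactly.
    """
    if size < 64:
        raise ValueError(f"size must be >= 64, got {size}")
    if roughness < 0:
        raise ValueError("roughness must be >= 0")
    if harmonics < 2:
        raise ValueError("harmonics must be >= 2")
    shape_rng, noise_rng = _rng_pair(seed)
    thetas = np.linspace(0.0, 2 * np.pi, 720, endpoint=False)
    orders = np.arange(2, harmonics + 1)
    amp = shape_rng.normal(size=orders.size) / orders
    phase = shape_rng.uniform(0, 2 * np.pi, size=orders.size)
    p = np.sum(amp[:, None] * np.cos(orders[:, None] * thetas[None, :] + phase[:, None]), axis=0)
    p = p - p.mean()
    peak = np.abs(p).max()
    if peak > 0:
        p = p / peak  # roughness is then the peak relative radial deviation
    radii = base_radius * (1.0 + roughness * p)
    if np.any(radii <= 0):
        raise ValueError(
            f"roughness {roughness} drives the radius non-positive; reduce it"
        )
    if radii.max() > size / 2 - 8:
        raise ValueError("perturbed outline exceeds the canvas margin")
    mask = _fill_polar_outline(size, radii, thetas)
    label = 1 if roughness == 0 else 0
    image = _render(mask, contrast, noise_sd, noise_rng)
    return SyntheticLesion(
        image=image, mask=mask, label=label, roughness=float(roughness), seed=int(seed)
    )


def koch_vertices(iterations: int, length: float = 729.0) -> np.ndarray:
    """Vertices of the Koch construction after ``iterations`` steps.

    Each segment is split in three and the middle third replaced by the
    two sides of an outward equilateral bump; iteration 0 is the straight
    line.  Returns (4^k + 1) points, i.e. 4^k segments.
    """
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    pts = np.array([[0.0, 0.0], [0.0, float(length)]])  # (row, col)
    rot60 = np.array(
        [[np.cos(-np.pi / 3), -np.sin(-np.pi / 3)], [np.sin(-np.pi / 3), np.cos(-np.pi / 3)]]
    )
    for _ in range(iterations):
        out = [pts[0]]
        for p, q in zip(pts[:-1], pts[1:]):
            d = (q - p) / 3.0
            a, b = p + d, p + 2 * d
            peak = a + d @ rot60.T
            out.extend([a, peak, b, q])
        pts = np.asarray(out)
    return pts


def koch_border(iterations: int, length: float = 729.0) -> BorderTrace:
    """Rasterized Koch curve as an (open) border trace."""
    verts = koch_vertices(iterations, length)
    return rasterize_polyline(verts, closed=False)


_TRANSFORMS = (
    ("identity", lambda a: a),
    ("rot90", lambda a: np.rot90(a, 1)),
    ("rot180", lambda a: np.rot90(a, 2)),
    ("rot270", lambda a: np.rot90(a, 3)),
    ("fliplr", lambda a: np.fliplr(a)),
    ("flipud", lambda a: np.flipud(a)),
)


def augment_flip_rotate(samples: list[SyntheticLesion]) -> list[SyntheticLesion]:
    """Originals plus 90/180/270-degree rotations and both axis flips.

    One input yields six outputs; labels are preserved and masks are
    transformed identically to images.
    """
    if not samples:
        raise ValueError("augment_flip_rotate requires a nonempty input")
    out = []
    for s in samples:
        for _, fn in _TRANSFORMS:
            out.append(replace(s, image=np.ascontiguousarray(fn(s.image)),
                               mask=np.ascontiguousarray(fn(s.mask))))
    return out


def make_dataset(
    n_regular: int,
    n_irregular: int,
    seed: int = 0,
    balance: bool = False,
    size: int = DEFAULT_SIZE,
    roughness_range: tuple[float, float] = (0.35, 0.5),
) -> list[SyntheticLesion]:
    """Seeded, parameter-jittered lesion collection.

    Regular lesions draw semi-axes in [30, 70] px, irregular ones a base
    radius in [40, 70] px and a roughness in ``roughness_range``; both
    jitter contrast in [100, 140] gray levels and noise in [5, 10].
    With ``balance`` the minority class is topped up to parity with
    flip/rotate augmentations (at most a factor 6).
    """
    if n_regular < 0 or n_irregular < 0 or n_regular + n_irregular == 0:
        raise ValueError("need a nonnegative, nonzero total sample count")
    rng = np.random.default_rng(seed)
    samples: list[SyntheticLesion] = []
    for _ in range(n_regular):
        sub = int(rng.integers(0, 2**31 - 1))
        major = rng.uniform(30, min(70, size / 2 - 9))
        minor = major * rng.uniform(0.6, 1.0)
        samples.append(
            make_regular_lesion(
                size=size,
                axes=(major, minor),
                contrast=rng.uniform(100, 140),
                noise_sd=rng.uniform(5, 10),
                seed=sub,
            )
        )
    for _ in range(n_irregular):
        sub = int(rng.integers(0, 2**31 - 1))
        samples.append(
            make_irregular_lesion(
                size=size,
                base_radius=rng.uniform(40, min(70, size / 2 - 9) / 1.6),
                roughness=rng.uniform(*roughness_range),
                harmonics=int(rng.integers(16, 33)),
                contrast=rng.uniform(100, 140),
                noise_sd=rng.uniform(5, 10),
                seed=sub,
            )
        )
    if balance and n_regular != n_irregular and min(n_regular, n_irregular) > 0:
        minority = 1 if n_regular < n_irregular else 0
        target = max(n_regular, n_irregular)
        pool = [s for s in samples if s.label == minority]
        # augment_flip_rotate emits each original first; skip those copies
        extras = [s for i, s in enumerate(augment_flip_rotate(pool)) if i % 6 != 0]
        need = target - len(pool)
        if need > len(extras):
            raise ValueError(
                "flip/rotate augmentation (x6) cannot reach class parity; "
                "generate more minority samples"
            )
        samples.extend(extras[:need])
    return samples


# ---------------------------------------------------------------------------
# disk I/O: 8-bit grayscale PNGs, labels CSV, JSON manifest

def write_dataset(samples: list[SyntheticLesion], out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, s in enumerate(samples):
        stem = f"lesion_{i:04d}"
        Image.fromarray(s.image, mode="L").save(out / f"{stem}.png")
        Image.fromarray((s.mask.astype(np.uint8) * 255), mode="L").save(
            out / f"{stem}_mask.png"
        )
        rows.append(
            {"id": stem, "label": s.label, "roughness": s.roughness, "seed": s.seed}
        )
    with open(out / "labels.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["id", "label"])
        writer.writeheader()
        for r in rows:
            writer.writerow({"id": r["id"], "label": r["label"]})
    with open(out / "manifest.json", "w") as fh:
        json.dump({"n_samples": len(samples), "samples": rows}, fh, indent=2)
    return out
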