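"""Synthetic MRI-like phantom generation.

Produces artifact-free 2-D grayscale images that emulate a T1-weighted
brain slice: a bright, roughly elliptical "head" with internal elliptical
structures on an exactly-zero background. The exact-zero background is a
hard contract — the wrap-around simulator derives the anatomical support
pattern F from strict positivity, so the phantom never injects an epsilon
floor outside the head.

Intensities live in (0, 1]; foreground noise is clamped back into the
configured intensity range so the support of the image never changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["PhantomSpec", "generate_phantom", "generate_dataset"]

#: smallest image side the generator accepts
MIN_SIDE = 16

#: vertical extent of the head ellipse as a fraction of image height;
#: kept larger than the horizontal fraction so the head is taller than
#: wide, as in an axial/sagittal brain slice
HEAD_HEIGHT_FRACTION = 0.9


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic phantom.

    Attributes
    ----------
    height, width:
        Image size in pixels, each >= 16.
    n_ellipses:
        Number of internal elliptical structures drawn inside the head.
    foreground_fraction:
        Fraction of the frame *width* spanned by the head ellipse, in
        (0, 1). Kept < 1 so a horizontal shift wraps both background and
        anatomy, but high (default 0.9, like a brain filling a clinical
        FOV): a wrap of d columns corrupts anatomy only where d exceeds
        twice the background margin, so a narrow head would make minor
        distortion levels artifact-free.
    intensity_range:
        (lo, hi] range of foreground tissue values, lo > 0.
    noise_sigma:
        Std of additive Gaussian noise applied to foreground pixels only.
    seed:
        RNG seed; the same spec is bit-reproducible.
    """

    height: int = 128
    width: int = 128
    n_ellipses: int = 6
    foreground_fraction: float = 0.9
    intensity_range: tuple[float, float] = (0.2, 1.0)
    noise_sigma: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if self.height < MIN_SIDE:
            raise ValueError(f"height must be >= {MIN_SIDE}, got {self.height}")
        if self.width < MIN_SIDE:
            raise ValueError(f"width must be >= {MIN_SIDE}, got {self.width}")
        if self.n_ellipses < 0:
            raise ValueError(f"n_ellipses must be >= 0, got {self.n_ellipses}")
        if not (0.0 < self.foreground_fraction < 1.0):
            raise ValueError(
                "foreground_fraction must lie in (0, 1), got "
                f"{self.foreground_fraction}"
            )
        lo, hi = self.intensity_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError(
                f"intensity_range must satisfy 0 < lo <= hi <= 1, got {self.intensity_range}"
            )
        if self.noise_sigma < 0:
            raise ValueError(f"noise_sigma must be >= 0, got {self.noise_sigma}")


def _ellipse_mask(
    h: int, w: int, cy: float, cx: float, ry: float, rx: float, angle: float = 0.0
) -> np.ndarray:
    """Boolean raster of an axis-rotated ellipse on an h-by-w grid."""
    yy, xx = np.mgrid[0:h, 0:w]
    y = yy - cy
    x = xx - cx
    ca, sa = np.cos(angle), np.sin(angle)
    u = ca * x + sa * y
    v = -sa * x + ca * y
    return (u / rx) ** 2 + (v / ry) ** 2 <= 1.0


def generate_phantom(spec: PhantomSpec) -> np.ndarray:
    """Render one phantom image as a float64 array of shape (height, width).

    Background outside the head ellipse is exactly 0; every foreground
    pixel is strictly positive and within ``spec.intensity_range``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    lo, hi = spec.intensity_range

    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    rx = spec.foreground_fraction * w / 2.0
    ry = HEAD_HEIGHT_FRACTION * h / 2.0
    head = _ellipse_mask(h, w, cy, cx, ry, rx)

    img = np.zeros((h, w), dtype=np.float64)
    base = lo + 0.5 * (hi - lo)  # mid-range base tissue intensity
    img[head] = base

    for _ in range(spec.n_ellipses):
        # centers confined to the inner part of the head so the structure
        # stays (mostly) inside; clipped to the head mask regardless
        ecy = cy + rng.uniform(-0.5, 0.5) * ry
        ecx = cx + rng.uniform(-0.5, 0.5) * rx
        ery = rng.uniform(0.08, 0.35) * ry
        erx = rng.uniform(0.08, 0.35) * rx
        ang = rng.uniform(0.0, np.pi)
        val = rng.uniform(lo, hi)
        e = _ellipse_mask(h, w, ecy, ecx, ery, erx, ang) & head
        img[e] = val

    if spec.noise_sigma > 0:
        noise = rng.normal(0.0, spec.noise_sigma, size=img.shape)
        img[head] = np.clip(img[head] + noise[head], lo, hi)

    return img


def generate_dataset(
    spec: PhantomSpec, n_images: int, seed: int | None = None
) -> list[np.ndarray]:
    """Generate ``n_images`` distinct phantoms with per-image derived seeds.

    Seeds are spawned deterministically from ``seed`` (defaults to
    ``spec.seed``), so a fixed seed reproduces the corpus bit-exactly while
    every image differs from the others.
    """
    if n_images < 1:
        raise ValueError(f"n_images must be >= 1, got {n_images}")
    root = spec.seed if seed is None else seed
    child_seeds = derive_seeds(root, n_images)
    return [generate_phantom(replace(spec, seed=s)) for s in child_seeds]


def derive_seeds(seed: int, n: int) -> list[int]:
    """Deterministically derive ``n`` 31-bit child seeds from one seed."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint64)
    return [int(s & 0x7FFFFFFF) for s in state]
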