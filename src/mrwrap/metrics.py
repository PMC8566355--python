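"""Full-reference image quality metrics: PSNR and SSIM.

PSNR is 10·log10(MAX² / MSE) in decibels; identical images yield the
+infinity sentinel rather than an exception.

SSIM follows the standard windowed formulation (Wang et al.): an 11×11
Gaussian window with σ = 1.5, stabilisers C1 = (0.01·L)² and
C2 = (0.03·L)² where L is the dynamic range, population (not sample)
local variances, and the mean taken over the valid interior (the
half-window border is cropped). The dynamic range defaults to 1.0 because
the rest of the package works in the normalized [0, 1] intensity domain.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

__all__ = ["psnr", "ssim", "evaluate_benchmark"]

SSIM_SIGMA = 1.5
SSIM_TRUNCATE = 3.5  # 2·int(3.5·1.5 + 0.5) + 1 = 11-pixel window
SSIM_WIN = 2 * int(SSIM_TRUNCATE * SSIM_SIGMA + 0.5) + 1
SSIM_K1 = 0.01
SSIM_K2 = 0.03


def _as_pair(reference: np.ndarray, test: np.ndarray):
    a = np.asarray(reference, dtype=np.float64)
    b = np.asarray(test, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def psnr(reference: np.ndarray, test: np.ndarray, max_value: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB; +inf for identical images."""
    if max_value <= 0:
        raise ValueError(f"max_value must be > 0, got {max_value}")
    a, b = _as_pair(reference, test)
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        return float("inf")
    return 10.0 * np.log10(max_value**2 / mse)


def ssim(reference: np.ndarray, test: np.ndarray, data_range: float = 1.0) -> float:
    """Mean local structural similarity between two same-shape 2-D images."""
    a, b = _as_pair(reference, test)
    if min(a.shape) < SSIM_WIN:
        raise ValueError(
            f"image sides must be >= {SSIM_WIN} for an {SSIM_WIN}x{SSIM_WIN} window, "
            f"got shape {a.shape}"
        )
    if data_range <= 0:
        raise ValueError(f"data_range must be > 0, got {data_range}")

    filt = dict(sigma=SSIM_SIGMA, truncate=SSIM_TRUNCATE, mode="reflect")
    ux = gaussian_filter(a, **filt)
    uy = gaussian_filter(b, **filt)
    uxx = gaussian_filter(a * a, **filt)
    uyy = gaussian_filter(b * b, **filt)
    uxy = gaussian_filter(a * b, **filt)
    vx = uxx - ux * ux
    vy = uyy - uy * uy
    vxy = uxy - ux * uy

    c1 = (SSIM_K1 * data_range) ** 2
    c2 = (SSIM_K2 * data_range) ** 2
    s = ((2 * ux * uy + c1) * (2 * vxy + c2)) / (
        (ux**2 + uy**2 + c1) * (vx + vy + c2)
    )
    pad = (SSIM_WIN - 1) // 2
    return float(s[pad:-pad, pad:-pad].mean())


def evaluate_benchmark(samples, data_range: float = 1.0) -> pd.DataFrame:
    """Aggregate image quality per distortion level and overall.

    Parameters
    ----------
    samples:
        Iterable of ``(clean, artifacted, restored, level)`` tuples;
        ``restored`` may be None when only the simulation is evaluated.

    Returns
    -------
    DataFrame with one row per distortion level present plus an
    ``overall`` row, columns ``level, n, psnr_artifacted, ssim_artifacted,
    psnr_restored, ssim_restored``.
    """
    samples = list(samples)
    if not samples:
        raise ValueError("no samples to evaluate")
    rows = []
    for clean, artifacted, restored, level in samples:
        row = {
            "level": level,
            "psnr_artifacted": psnr(clean, artifacted, data_range),
            "ssim_artifacted": ssim(clean, artifacted, data_range),
            "psnr_restored": np.nan,
            "ssim_restored": np.nan,
        }
        if restored is not None:
            row["psnr_restored"] = psnr(clean, restored, data_range)
            row["ssim_restored"] = ssim(clean, restored, data_range)
        rows.append(row)
    df = pd.DataFrame(rows)
    per_level = (
        df.groupby("level", as_index=False)
        .agg(
            n=("level", "size"),
            psnr_artifacted=("psnr_artifacted", "mean"),
            ssim_artifacted=("ssim_artifacted", "mean"),
            psnr_restored=("psnr_restored", "mean"),
            ssim_restored=("ssim_restored", "mean"),
        )
        .sort_values("level")
    )
    overall = {
        "level": "overall",
        "n": len(df),
        "psnr_artifacted": df["psnr_artifacted"].mean(),
        "ssim_artifacted": df["ssim_artifacted"].mean(),
        "psnr_restored": df["psnr_restored"].mean(),
        "ssim_restored": df["ssim_restored"].mean(),
    }
    return pd.concat([per_level, pd.DataFrame([overall])], ignore_index=True)
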