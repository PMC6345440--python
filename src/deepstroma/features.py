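"""Texture/color feature extraction for tissue patches.

A compact, nearly flip-invariant descriptor (color statistics, intensity
quantiles, thresholded-fraction morphology, multi-scale gradient energy)
computed per 224x224 RGB patch.  The nine procedural tissue archetypes
are separable in this space; the classifier is a standard multilayer
perceptron on top of it.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

FEATURE_NAMES = (
    "mean_r", "mean_g", "mean_b",
    "std_r", "std_g", "std_b",
    "q05", "q25", "q50", "q75", "q95",
    "dark_frac", "bright_frac",
    "dark_frac_erode1", "dark_frac_erode3",
    "bright_frac_erode2",
    "grad_full", "grad_coarse",
    "block_std",
    "blue_minus_red", "chroma_spread",
)

N_FEATURES = len(FEATURE_NAMES)

_DARK_T = 100.0
_BRIGHT_T = 230.0


def _block_reduce_mean(a: np.ndarray, f: int) -> np.ndarray:
    h = (a.shape[0] // f) * f
    w = (a.shape[1] // f) * f
    return a[:h, :w].reshape(h // f, f, w // f, f).mean(axis=(1, 3))


def patch_features(img: np.ndarray) -> np.ndarray:
    """Feature vector of one RGB patch (H, W, 3), values 0-255."""
    arr = np.asarray(img, dtype=float)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("patch must be (H, W, 3)")
    gray = arr.mean(axis=2)

    means = arr.mean(axis=(0, 1))
    stds = arr.std(axis=(0, 1))
    quantiles = np.percentile(gray, [5, 25, 50, 75, 95])

    dark = gray < _DARK_T
    bright = gray > _BRIGHT_T
    dark_frac = dark.mean()
    bright_frac = bright.mean()
    dark_e1 = ndimage.binary_erosion(dark, iterations=1).mean() if dark_frac else 0.0
    dark_e3 = ndimage.binary_erosion(dark, iterations=3).mean() if dark_frac else 0.0
    bright_e2 = ndimage.binary_erosion(bright, iterations=2).mean() if bright_frac else 0.0

    gx = np.abs(np.diff(gray, axis=1)).mean()
    gy = np.abs(np.diff(gray, axis=0)).mean()
    grad_full = gx + gy

    coarse = _block_reduce_mean(gray, 4)
    grad_coarse = (
        np.abs(np.diff(coarse, axis=1)).mean() + np.abs(np.diff(coarse, axis=0)).mean()
    )

    block_std = _block_reduce_mean(gray, 16).std()

    blue_minus_red = (arr[..., 2] - arr[..., 0]).mean()
    chroma_spread = (arr.max(axis=2) - arr.min(axis=2)).mean()

    return np.array([
        *means, *stds, *quantiles,
        dark_frac, bright_frac, dark_e1, dark_e3, bright_e2,
        grad_full, grad_coarse, block_std,
        blue_minus_red, chroma_spread,
    ])


def batch_features(patches) -> np.ndarray:
    """Feature matrix (n, N_FEATURES) for a stack or list of patches."""
    return np.stack([patch_features(p) for p in patches])
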