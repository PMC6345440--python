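"""Macenko stain normalization for H&E images.

Stain mixing is approximately linear in optical density (OD): every
pixel's OD vector is a nonnegative combination of a hematoxylin and an
eosin OD direction.  The Macenko estimator finds those directions as
extreme percentile angles of the OD point cloud projected onto its top
two singular directions, then normalization rescales per-stain
concentrations to a reference profile and reconstructs the image.

The estimator is exposed both as plain functions and as a scikit-learn
style transformer (`MacenkoNormalizer`) whose ``fit`` learns the target
profile from a reference image and whose ``transform`` normalizes
images to it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

DEFAULT_ALPHA = 1.0
DEFAULT_BETA = 0.15
DEFAULT_I0 = 255.0
_MIN_STAINED_PIXELS = 100


class StainEstimationError(ValueError):
    """Raised when a stain profile cannot be estimated from an image."""


@dataclass
class StainProfile:
    """Estimated H&E stain geometry of an image.

    ``stain_matrix`` is 3x2 with unit-norm columns (hematoxylin, eosin)
    in OD space; ``max_concentrations`` holds the per-stain 99th
    percentile concentration used for intensity rescaling.
    """

    stain_matrix: np.ndarray
    max_concentrations: np.ndarray
    alpha: float = DEFAULT_ALPHA
    beta: float = DEFAULT_BETA
    I0: float = DEFAULT_I0

    def __post_init__(self):
        self.stain_matrix = np.asarray(self.stain_matrix, dtype=float)
        self.max_concentrations = np.asarray(self.max_concentrations, dtype=float)
        if self.stain_matrix.shape != (3, 2):
            raise ValueError("stain_matrix must be 3x2")
        norms = np.linalg.norm(self.stain_matrix, axis=0)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("stain_matrix columns must have unit norm")
        if np.any(self.stain_matrix < -1e-12):
            raise ValueError("stain_matrix entries must be nonnegative")
        if np.any(self.max_concentrations <= 0):
            raise ValueError("max_concentrations must be > 0")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "M": self.stain_matrix.tolist(),
            "maxC": self.max_concentrations.tolist(),
            "alpha": self.alpha,
            "beta": self.beta,
            "I0": self.I0,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "StainProfile":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        return cls(
            stain_matrix=np.asarray(d["M"]),
            max_concentrations=np.asarray(d["maxC"]),
            alpha=d.get("alpha", DEFAULT_ALPHA),
            beta=d.get("beta", DEFAULT_BETA),
            I0=d.get("I0", DEFAULT_I0),
        )


def default_target_profile() -> StainProfile:
    """The package's bundled reference profile.

    Estimated once from a synthetic mixed-tissue reference patch and
    frozen as JSON package data, so normalization is reproducible
    without any external image.
    """
    text = resources.files("deepstroma").joinpath("data/target_stain_profile.json").read_text()
    d = json.loads(text)
    return StainProfile(
        stain_matrix=np.asarray(d["M"]),
        max_concentrations=np.asarray(d["maxC"]),
        alpha=d.get("alpha", DEFAULT_ALPHA),
        beta=d.get("beta", DEFAULT_BETA),
        I0=d.get("I0", DEFAULT_I0),
    )


def rgb_to_od(image: np.ndarray, I0: float = DEFAULT_I0) -> np.ndarray:
    """Convert intensities to optical density: OD = -log10(max(I,1)/I0)."""
    if I0 <= 0:
        raise ValueError("I0 must be > 0")
    arr = np.asarray(image, dtype=float)
    return -np.log10(np.maximum(arr, 1.0) / I0)


def od_to_rgb(od: np.ndarray, I0: float = DEFAULT_I0) -> np.ndarray:
    """Invert `rgb_to_od` (up to the intensity clamp), returning uint8."""
    if I0 <= 0:
        raise ValueError("I0 must be > 0")
    return np.clip(np.round(I0 * 10.0 ** (-np.asarray(od, float))), 0, I0).astype(np.uint8)


def _stain_concentrations(od_pixels: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Per-pixel stain concentrations: exact two-column nonnegative
    least squares, vectorized over pixels.

    Solves the unconstrained 2x2 normal equations; where a coefficient
    goes negative, falls back to the better of the two single-stain
    projections (the exact NNLS solution for two columns).  Stable even
    when the stain directions are nearly collinear.
    """
    B = od_pixels.T  # (3, n)
    G = M.T @ M
    rhs = M.T @ B    # (2, n)
    det = G[0, 0] * G[1, 1] - G[0, 1] ** 2
    det = max(det, 1e-12)
    c0 = (G[1, 1] * rhs[0] - G[0, 1] * rhs[1]) / det
    c1 = (G[0, 0] * rhs[1] - G[0, 1] * rhs[0]) / det
    C = np.stack([c0, c1])

    neg = (C < 0).any(axis=0)
    if np.any(neg):
        # candidate a: only stain 0; candidate b: only stain 1
        a = np.clip(rhs[0, neg] / G[0, 0], 0, None)
        b = np.clip(rhs[1, neg] / G[1, 1], 0, None)
        # residual^2 = |B|^2 - 2 c r + c^2 g ; compare the data-dependent part
        loss_a = -2 * a * rhs[0, neg] + a**2 * G[0, 0]
        loss_b = -2 * b * rhs[1, neg] + b**2 * G[1, 1]
        use_a = loss_a <= loss_b
        C[0, neg] = np.where(use_a, a, 0.0)
        C[1, neg] = np.where(use_a, 0.0, b)
    return C  # (2, n)


def _exposure_offset(tissue_od: np.ndarray) -> float:
    """Estimate a global exposure offset in OD space.

    Multiplying all intensities by a constant c shifts every OD vector
    by -log10(c) * (1,1,1): the stain plane becomes affine instead of
    passing through the origin.  Fitting the affine plane (centered PCA)
    and solving for the isotropic offset that returns it through the
    origin recovers -log10(c); for an undimmed two-stain image the
    cloud already contains the origin direction and the estimate is ~0.
    """
    mu = tissue_od.mean(axis=0)
    _, s, Vt = np.linalg.svd(tissue_od - mu, full_matrices=False)
    if s[1] <= 1e-3 * s[0]:  # cloud is a line; offset unidentifiable
        return 0.0
    normal = Vt[2]
    denom = normal.sum()
    if abs(denom) < 1e-6:
        return 0.0
    return float(normal @ mu / denom)


def estimate_stain_profile(
    image: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    beta: float = DEFAULT_BETA,
    I0: float = DEFAULT_I0,
) -> StainProfile:
    """Estimate an H&E stain profile with the Macenko method.

    Tissue pixels (max-channel OD > ``beta``) are projected onto the
    plane of the top two singular directions of the OD cloud; the
    ``alpha``-th and (100-``alpha``)-th percentile angles define the two
    stain directions.  The column with the larger blue-channel OD
    component is taken as hematoxylin.  A global exposure offset is
    estimated and removed first, so the directions do not drift when
    the whole image is uniformly dimmed or brightened.
    """
    od = rgb_to_od(image, I0).reshape(-1, 3)
    tissue = od[od.max(axis=1) > beta]
    if tissue.shape[0] < _MIN_STAINED_PIXELS:
        raise StainEstimationError(
            f"insufficient stained pixels: {tissue.shape[0]} < {_MIN_STAINED_PIXELS}"
        )

    # Correct only clear exposure shifts (>~10% intensity): small fitted
    # offsets arise spuriously from texture curvature in the OD cloud.
    delta = _exposure_offset(tissue)
    if abs(delta) > 0.04:
        od = np.clip(od - delta, 0.0, None)
        tissue = od[od.max(axis=1) > beta]
        if tissue.shape[0] < _MIN_STAINED_PIXELS:
            raise StainEstimationError(
                "insufficient stained pixels after exposure correction"
            )

    # plane of the top two right-singular vectors of the centered-free cloud
    _, s, Vt = np.linalg.svd(tissue, full_matrices=False)
    if s[1] <= 1e-3 * s[0]:
        raise StainEstimationError(
            "degenerate stain geometry: OD cloud spans a single stain direction"
        )
    basis = Vt[:2]  # (2, 3)
    # orient basis so projections land in a consistent half-plane
    if basis[0].sum() < 0:
        basis[0] = -basis[0]
    if basis[1].sum() < 0:
        basis[1] = -basis[1]

    proj = tissue @ basis.T  # (n, 2)
    angles = np.arctan2(proj[:, 1], proj[:, 0])
    lo, hi = np.percentile(angles, [alpha, 100.0 - alpha])

    def direction(angle):
        v = np.cos(angle) * basis[0] + np.sin(angle) * basis[1]
        v = np.clip(v, 0.0, None)
        n = np.linalg.norm(v)
        if n == 0:
            raise StainEstimationError("degenerate stain geometry: null direction")
        return v / n

    v1, v2 = direction(lo), direction(hi)
    # hematoxylin = larger blue-channel OD component
    if v1[2] >= v2[2]:
        M = np.stack([v1, v2], axis=1)
    else:
        M = np.stack([v2, v1], axis=1)

    C = _stain_concentrations(od, M)
    max_c = np.percentile(C, 99, axis=1)
    max_c = np.maximum(max_c, 1e-6)
    return StainProfile(stain_matrix=M, max_concentrations=max_c,
                        alpha=alpha, beta=beta, I0=I0)


def normalize(
    image: np.ndarray,
    target: StainProfile,
    source: StainProfile | None = None,
) -> np.ndarray:
    """Normalize an RGB image to the target stain profile.

    The image's stain concentrations (under its own profile, estimated
    if not given) are rescaled per stain by target/source maximum
    concentration and reconstructed through the target stain matrix.
    """
    if source is None:
        source = estimate_stain_profile(
            image, alpha=target.alpha, beta=target.beta, I0=target.I0
        )
    shape = np.asarray(image).shape
    od = rgb_to_od(image, target.I0).reshape(-1, 3)
    C = _stain_concentrations(od, source.stain_matrix)
    scale = target.max_concentrations / source.max_concentrations
    od_out = (target.stain_matrix @ (C * scale[:, None])).T
    return od_to_rgb(od_out.reshape(shape), target.I0)


class MacenkoNormalizer(BaseEstimator, TransformerMixin):
    """Scikit-learn style Macenko stain normalizer.

    ``fit(reference_image)`` learns the target profile; ``transform``
    maps each image to that profile.  Without ``fit`` the bundled
    default target profile is used.

    Parameters
    ----------
    alpha : percentile angle parameter of the Macenko estimator.
    beta : OD transparency threshold below which pixels are background.
    I0 : transmitted-light reference intensity.
    """

    def __init__(self, alpha: float = DEFAULT_ALPHA, beta: float = DEFAULT_BETA,
                 I0: float = DEFAULT_I0):
        self.alpha = alpha
        self.beta = beta
        self.I0 = I0

    def fit(self, X, y=None):
        """Learn the target profile from a reference image (H, W, 3)."""
        X = np.asarray(X)
        if X.ndim == 4:  # a stack: use the first image as reference
            X = X[0]
        self.target_profile_ = estimate_stain_profile(
            X, alpha=self.alpha, beta=self.beta, I0=self.I0
        )
        return self

    def _target(self) -> StainProfile:
        if hasattr(self, "target_profile_"):
            return self.target_profile_
        return default_target_profile()

    def transform(self, X):
        """Normalize one image (H, W, 3) or a stack (N, H, W, 3)."""
        X = np.asarray(X)
        target = self._target()
        if X.ndim == 3:
            return normalize(X, target)
        return np.stack([normalize(img, target) for img in X])
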