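"""Procedural H&E-like texture synthesis for the nine tissue classes.

Each class has a visual archetype built from hematoxylin/eosin
"concentration" fields rendered through the Beer-Lambert law, so the
patches live in the same optical-density geometry that Macenko stain
normalization assumes.  The archetypes are deliberately cartoonish: the
goal is nine mutually separable textures with a documented separating
statistic per class, not photorealistic histology.

Separating statistics (each class vs. the rest):

========  ==========================================================
ADI       bright vacuoles with thin membranes: bright fraction > 0.6
          yet nonzero edge density (unlike BACK, which has none)
BACK      mean intensity > 230 on every channel (near-white)
DEB       single-pixel speckle: highest high-frequency gradient
          energy, no orientation, speckles vanish under erosion
LYM       dense small dark blobs: dark-pixel fraction (< 100) > 0.25
          with blobs that survive one erosion step
MUC       smooth pale mucin: lowest gradient energy of the stained
          classes, mid-range intensity
MUS       wide fibers (wavelength ~ 36 px): oriented low-frequency
          stripe energy
NORM      regular gland rings: bright lumina on a stained field with
          periodic ring spacing
STR       thin fibers (wavelength ~ 9 px): oriented high-frequency
          stripe energy, ~4x the stripe frequency of MUS
TUM       large solid dark blobs (radius ~ 11 px): dark fraction that
          survives repeated erosion, unlike LYM's small blobs
========  ==========================================================
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, zoom

from .tissue import CLASS_CODES, TissueClass

PATCH_SIZE = 224
REGION_SIZE = 1500

#: Rendered RGB of a unit concentration of each stain (Beer-Lambert).
DEFAULT_HEMATOXYLIN_RGB = (57, 51, 131)
DEFAULT_EOSIN_RGB = (217, 26, 198)


@dataclass
class TextureParams:
    """Knobs of the procedural texture generator.

    Radii and spacings are in pixels at the nominal 0.5 um/px scale.
    """

    lym_blob_radius: float = 4.0
    lym_blob_density: float = 4e-3   # blobs per px^2
    tum_blob_radius: float = 11.0
    tum_blob_density: float = 8e-4
    adi_vacuole_radius: float = 28.0
    norm_gland_spacing: float = 26.0
    mus_fiber_width: float = 18.0    # half-wavelength of the stripe field
    mus_fiber_orientation: float | None = None   # radians; None = random
    str_fiber_width: float = 4.5
    str_fiber_orientation: float | None = None
    deb_speckle_density: float = 0.22
    muc_base_chroma: float = 0.28    # eosin concentration of mucin pools
    back_intensity: float = 245.0
    hematoxylin_rgb: tuple[int, int, int] = DEFAULT_HEMATOXYLIN_RGB
    eosin_rgb: tuple[int, int, int] = DEFAULT_EOSIN_RGB
    noise_scale: float = 2.0         # additive intensity noise, sigma
    seed: int = 0

    def validate(self) -> None:
        positive = {
            "lym_blob_radius": self.lym_blob_radius,
            "lym_blob_density": self.lym_blob_density,
            "tum_blob_radius": self.tum_blob_radius,
            "tum_blob_density": self.tum_blob_density,
            "adi_vacuole_radius": self.adi_vacuole_radius,
            "norm_gland_spacing": self.norm_gland_spacing,
            "mus_fiber_width": self.mus_fiber_width,
            "str_fiber_width": self.str_fiber_width,
            "deb_speckle_density": self.deb_speckle_density,
            "muc_base_chroma": self.muc_base_chroma,
        }
        for name, value in positive.items():
            if not value > 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if not 0.0 <= self.back_intensity <= 255.0:
            raise ValueError("back_intensity must lie in [0, 255]")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be nonnegative")

    def stain_od_vectors(self) -> tuple[np.ndarray, np.ndarray]:
        """Optical-density vectors of the two stains at unit concentration."""
        def od(rgb):
            arr = np.clip(np.asarray(rgb, dtype=float), 1.0, 255.0)
            return -np.log10(arr / 255.0)
        return od(self.hematoxylin_rgb), od(self.eosin_rgb)


# ---------------------------------------------------------------------------
# field primitives

def _stamp_disks(shape, centers, radius, value=1.0):
    """Add disks of `value` at integer centers into a float field."""
    h, w = shape
    out = np.zeros(shape, dtype=float)
    r = int(np.ceil(radius))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    stamp = (yy**2 + xx**2 <= radius**2).astype(float) * value
    for cy, cx in centers:
        y0, y1 = cy - r, cy + r + 1
        x0, x1 = cx - r, cx + r + 1
        sy0, sx0 = max(0, -y0), max(0, -x0)
        sy1 = stamp.shape[0] - max(0, y1 - h)
        sx1 = stamp.shape[1] - max(0, x1 - w)
        out[max(0, y0) : min(h, y1), max(0, x0) : min(w, x1)] = np.maximum(
            out[max(0, y0) : min(h, y1), max(0, x0) : min(w, x1)],
            stamp[sy0:sy1, sx0:sx1],
        )
    return out


def _stamp_rings(shape, centers, r_outer, r_inner):
    h, w = shape
    out = np.zeros(shape, dtype=float)
    r = int(np.ceil(r_outer))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    d2 = yy**2 + xx**2
    stamp = ((d2 <= r_outer**2) & (d2 >= r_inner**2)).astype(float)
    lumen = (d2 < r_inner**2).astype(float)
    lum = np.zeros(shape, dtype=float)
    for cy, cx in centers:
        y0, y1 = cy - r, cy + r + 1
        x0, x1 = cx - r, cx + r + 1
        sy0, sx0 = max(0, -y0), max(0, -x0)
        sy1 = stamp.shape[0] - max(0, y1 - h)
        sx1 = stamp.shape[1] - max(0, x1 - w)
        sl = (slice(max(0, y0), min(h, y1)), slice(max(0, x0), min(w, x1)))
        out[sl] = np.maximum(out[sl], stamp[sy0:sy1, sx0:sx1])
        lum[sl] = np.maximum(lum[sl], lumen[sy0:sy1, sx0:sx1])
    return out, lum


def _stripe_field(shape, wavelength, orientation, rng, duty=0.45):
    """Binary-ish fiber field: stripes of the given wavelength/orientation."""
    h, w = shape
    theta = rng.uniform(0, np.pi) if orientation is None else float(orientation)
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    phase = rng.uniform(0, 2 * np.pi)
    s = np.sin(2 * np.pi * (xx * np.cos(theta) + yy * np.sin(theta)) / wavelength + phase)
    # soft threshold keeps fiber edges slightly ragged
    wobble = 0.15 * rng.standard_normal(shape)
    return np.clip((s + wobble) > (1 - 2 * duty), 0, 1).astype(float)


def _poisson_centers(shape, density, rng):
    h, w = shape
    n = rng.poisson(density * h * w)
    if n == 0:
        return np.empty((0, 2), dtype=int)
    cy = rng.integers(0, h, size=n)
    cx = rng.integers(0, w, size=n)
    return np.stack([cy, cx], axis=1)


# ---------------------------------------------------------------------------
# per-class concentration fields

def _fields_back(shape, p, rng):
    lvl = -np.log10(max(p.back_intensity, 1.0) / 255.0)
    h_f = np.full(shape, lvl * 0.4)
    e_f = np.full(shape, lvl * 0.4)
    return h_f, e_f


def _fields_adi(shape, p, rng):
    # vacuole membranes: ridges of a nearest-vs-second-nearest center field
    h, w = shape
    n = max(4, int(h * w / (np.pi * p.adi_vacuole_radius**2)))
    cy = rng.uniform(0, h, n)
    cx = rng.uniform(0, w, n)
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    d = np.sqrt((yy[..., None] - cy) ** 2 + (xx[..., None] - cx) ** 2)
    d.sort(axis=-1)
    membrane = (d[..., 1] - d[..., 0]) < 1.6
    e_f = membrane * 0.55 + 0.015
    h_f = membrane * 0.25 + 0.01
    return h_f, e_f


def _fields_deb(shape, p, rng):
    speck = (rng.random(shape) < p.deb_speckle_density).astype(float)
    h_f = speck * rng.uniform(0.5, 1.1, shape) + 0.06
    e_f = speck * rng.uniform(0.3, 0.8, shape) + 0.22
    return h_f, e_f


def _fields_lym(shape, p, rng):
    centers = _poisson_centers(shape, p.lym_blob_density, rng)
    blobs = _stamp_disks(shape, centers, p.lym_blob_radius)
    h_f = blobs * 1.25 + 0.05
    e_f = (1 - blobs) * 0.18 + 0.05
    return h_f, e_f


def _fields_muc(shape, p, rng):
    # smooth pools of mucin: very low-frequency eosin modulation
    h, w = shape
    gy = rng.standard_normal((h // 28 + 2, w // 28 + 2))
    low = zoom(gy, (h / gy.shape[0], w / gy.shape[1]), order=1)[:h, :w]
    low = gaussian_filter(low, 6)
    e_f = p.muc_base_chroma + 0.06 * low
    h_f = np.full(shape, 0.05)
    return np.clip(h_f, 0, None), np.clip(e_f, 0.05, None)


def _fields_mus(shape, p, rng):
    fibers = _stripe_field(shape, 2 * p.mus_fiber_width, p.mus_fiber_orientation, rng)
    e_f = fibers * 0.55 + 0.18
    h_f = fibers * 0.12 + 0.08
    return h_f, e_f


def _fields_norm(shape, p, rng):
    h, w = shape
    sp = p.norm_gland_spacing
    cys = np.arange(sp / 2, h, sp)
    cxs = np.arange(sp / 2, w, sp)
    centers = [
        (int(cy + rng.uniform(-2, 2)), int(cx + rng.uniform(-2, 2)))
        for cy in cys
        for cx in cxs
    ]
    rings, lumen = _stamp_rings(shape, centers, sp * 0.38, sp * 0.22)
    h_f = rings * 0.95 + 0.05
    e_f = (1 - rings - lumen).clip(0, 1) * 0.35 + lumen * 0.02 + 0.05
    return h_f, e_f


def _fields_str(shape, p, rng):
    fibers = _stripe_field(shape, 2 * p.str_fiber_width, p.str_fiber_orientation, rng)
    e_f = fibers * 0.5 + 0.14
    h_f = fibers * 0.18 + 0.06
    return h_f, e_f


def _fields_tum(shape, p, rng):
    centers = _poisson_centers(shape, p.tum_blob_density, rng)
    blobs = _stamp_disks(shape, centers, p.tum_blob_radius)
    h_f = blobs * 0.95 + 0.10
    e_f = (1 - blobs) * 0.30 + 0.10
    return h_f, e_f


_FIELD_FUNCS = {
    "ADI": _fields_adi,
    "BACK": _fields_back,
    "DEB": _fields_deb,
    "LYM": _fields_lym,
    "MUC": _fields_muc,
    "MUS": _fields_mus,
    "NORM": _fields_norm,
    "STR": _fields_str,
    "TUM": _fields_tum,
}


def _render(h_field, e_field, params, rng):
    """Beer-Lambert rendering of concentration fields to 8-bit RGB."""
    od_h, od_e = params.stain_od_vectors()
    od = h_field[..., None] * od_h + e_field[..., None] * od_e
    img = 255.0 * 10.0 ** (-od)
    if params.noise_scale > 0:
        img = img + rng.normal(0, params.noise_scale, img.shape)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def _class_rng(cls: TissueClass, params: TextureParams, index: int) -> np.random.Generator:
    return np.random.default_rng([params.seed & 0x7FFFFFFF, cls.index, index])


def generate_patch(
    cls: TissueClass | str,
    params: TextureParams | None = None,
    index: int = 0,
) -> np.ndarray:
    """Generate one 224x224 RGB patch of the given tissue class.

    Deterministic given (class, ``params.seed``, ``index``); ``index``
    selects independent patches within the same seeded stream.
    """
    cls = TissueClass.from_code(cls if isinstance(cls, str) else cls.value)
    params = params or TextureParams()
    params.validate()
    rng = _class_rng(cls, params, index)
    h_f, e_f = _FIELD_FUNCS[cls.value]((PATCH_SIZE, PATCH_SIZE), params, rng)
    return _render(h_f, e_f, params, rng)


def generate_patch_set(
    n_per_class: int, params: TextureParams | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Generate a balanced labeled patch set.

    Returns (patches, labels): patches of shape (9*n, 224, 224, 3) uint8 and
    integer labels in the fixed class order.
    """
    params = params or TextureParams()
    patches, labels = [], []
    for ci, code in enumerate(CLASS_CODES):
        for i in range(n_per_class):
            patches.append(generate_patch(code, params, index=i))
            labels.append(ci)
    return np.stack(patches), np.asarray(labels)


# ---------------------------------------------------------------------------
# composite regions

def _apportion(fractions: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder apportionment of `total` pixels to fractions."""
    raw = fractions * total
    base = np.floor(raw).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(raw - base))
    base[order[:rem]] += 1
    return base


def generate_region(
    composition: dict[TissueClass | str, float],
    params: TextureParams | None = None,
    index: int = 0,
    size: int = REGION_SIZE,
) -> tuple[np.ndarray, np.ndarray]:
    """Generate a multitissue region and its ground-truth label mask.

    The region is partitioned into 2-3 horizontal bands, each split into
    vertical strips whose widths honor the requested area fractions; strip
    order is shuffled per band.  Returns ``(image, mask)`` with ``image``
    of shape (size, size, 3) uint8 and ``mask`` (size, size) uint8 holding
    the class index of each pixel.
    """
    params = params or TextureParams()
    params.validate()
    comp = {TissueClass.from_code(str(getattr(k, "value", k))): float(v)
            for k, v in composition.items()}
    fracs = np.array([v for v in comp.values()], dtype=float)
    if np.any(fracs < 0):
        raise ValueError("area fractions must be nonnegative")
    if abs(fracs.sum() - 1.0) > 1e-6:
        raise ValueError(f"area fractions must sum to 1, got {fracs.sum():.6f}")

    classes = list(comp.keys())
    rng = np.random.default_rng(
        [params.seed & 0x7FFFFFFF, 101, index, len(classes)]
    )
    image = np.zeros((size, size, 3), dtype=np.uint8)
    mask = np.zeros((size, size), dtype=np.uint8)

    n_bands = int(rng.integers(2, 4))
    band_edges = np.linspace(0, size, n_bands + 1).round().astype(int)
    for b in range(n_bands):
        y0, y1 = band_edges[b], band_edges[b + 1]
        widths = _apportion(fracs, size)
        order = rng.permutation(len(classes))
        x0 = 0
        for j in order:
            w = widths[j]
            if w == 0:
                continue
            cls = classes[j]
            sub_rng = np.random.default_rng(
                [params.seed & 0x7FFFFFFF, 103, index, b, int(j)]
            )
            h_f, e_f = _FIELD_FUNCS[cls.value]((y1 - y0, w), params, sub_rng)
            image[y0:y1, x0 : x0 + w] = _render(h_f, e_f, params, sub_rng)
            mask[y0:y1, x0 : x0 + w] = cls.index
            x0 += w
    return image, mask
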