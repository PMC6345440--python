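"""Sliding-window tissue decomposition of multitissue regions.

Large images are tiled with a partially overlapping sliding window;
each tile is classified, the per-tile softmax activations are averaged
into a region-level activation vector, and per-patient vectors are
obtained by elementwise max pooling over a patient's regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tissue import N_CLASSES, palette_matrix

DEFAULT_TILE = 224
DEFAULT_STRIDE = 112


def tile_offsets(length: int, tile: int, stride: int) -> np.ndarray:
    """Sliding-window offsets along one axis: 0, stride, ... plus a
    flush-to-edge offset when the last regular tile misses the border."""
    if length < tile:
        raise ValueError(f"axis length {length} smaller than tile size {tile}")
    offs = list(range(0, length - tile + 1, stride))
    if offs[-1] != length - tile:
        offs.append(length - tile)
    return np.asarray(offs)


def tile_region(region: np.ndarray, tile: int = DEFAULT_TILE,
                stride: int = DEFAULT_STRIDE):
    """Extract overlapping tiles covering every pixel of the region.

    Returns (tiles, offsets): a (n, tile, tile, 3) view-stack and an
    (n, 2) array of (row, col) offsets.
    """
    region = np.asarray(region)
    ys = tile_offsets(region.shape[0], tile, stride)
    xs = tile_offsets(region.shape[1], tile, stride)
    tiles, offsets = [], []
    for y in ys:
        for x in xs:
            tiles.append(region[y : y + tile, x : x + tile])
            offsets.append((y, x))
    return np.stack(tiles), np.asarray(offsets)


@dataclass
class ActivationMap:
    """Per-tile activation vectors with their offsets in the region."""

    activations: np.ndarray  # (n_tiles, 9)
    offsets: np.ndarray      # (n_tiles, 2) row/col
    tile: int
    shape: tuple[int, int]   # region height, width

    def __post_init__(self):
        if np.any(self.offsets < 0):
            raise ValueError("tile offsets must be nonnegative")
        if np.any(self.offsets[:, 0] + self.tile > self.shape[0]) or np.any(
            self.offsets[:, 1] + self.tile > self.shape[1]
        ):
            raise ValueError("tile offsets exceed image bounds")

    @property
    def mean_activation(self) -> np.ndarray:
        return self.activations.mean(axis=0)


def decompose_region(model, region: np.ndarray, tile: int = DEFAULT_TILE,
                     stride: int = DEFAULT_STRIDE) -> ActivationMap:
    """Classify all sliding-window tiles of a region."""
    tiles, offsets = tile_region(region, tile, stride)
    activations = np.asarray(model.predict_proba(tiles))
    return ActivationMap(activations=activations, offsets=offsets,
                         tile=tile, shape=region.shape[:2])


def region_activation(model, region: np.ndarray, tile: int = DEFAULT_TILE,
                      stride: int = DEFAULT_STRIDE) -> np.ndarray:
    """Region-level activation vector: mean over all tile activations."""
    return decompose_region(model, region, tile, stride).mean_activation


def render_map(amap: ActivationMap, palette=None) -> np.ndarray:
    """Render an activation map as an RGB overlay.

    Each pixel's color is sum_c palette_c * w_c, where w_c averages the
    class-c activations of every tile covering that pixel.
    """
    pal = palette_matrix(palette)  # (9, 3)
    h, w = amap.shape
    acc = np.zeros((h, w, N_CLASSES))
    cnt = np.zeros((h, w, 1))
    t = amap.tile
    for (y, x), vec in zip(amap.offsets, amap.activations):
        acc[y : y + t, x : x + t] += vec
        cnt[y : y + t, x : x + t] += 1.0
    if np.any(cnt == 0):
        raise ValueError("activation map does not cover the full region")
    weights = acc / cnt
    return np.clip(np.round(weights @ pal), 0, 255).astype(np.uint8)


def pool_patient(region_vectors) -> np.ndarray:
    """Per-patient activation vector: elementwise max over regions."""
    vecs = np.asarray(list(region_vectors), dtype=float)
    if vecs.size == 0:
        raise ValueError("patient has no region activation vectors")
    if vecs.ndim != 2 or vecs.shape[1] != N_CLASSES:
        raise ValueError("region vectors must have 9 components")
    return vecs.max(axis=0)
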