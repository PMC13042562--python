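"""Tile extraction, background filtering and stain standardization.

Large H&E images are cut into non-overlapping 512x512 tiles, predominantly
white tiles are discarded, and staining is standardized in two steps:
Macenko color normalization (optical-density SVD with angular-percentile
stain-vector estimation) to map every tile into a common stain basis, and
per-channel Z-scoring for model input. Training-time augmentation is random
cropping plus independent horizontal/vertical flips.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

__all__ = [
    "TileGridSpec",
    "StainNormParams",
    "Tile",
    "NormalizationError",
    "tile_image",
    "is_background",
    "fit_macenko",
    "apply_macenko",
    "zscore_tile",
    "augment_tile",
]

DEFAULT_TILE_SIZE = 512
# crop side used by augment_tile on a 512 tile; scaled for other tile sizes
DEFAULT_CROP = 448
MIN_TISSUE_PIXELS = 100


class NormalizationError(ValueError):
    """Raised when stain normalization cannot be fitted (e.g. no tissue)."""


@dataclass(frozen=True)
class TileGridSpec:
    tile_size: int = DEFAULT_TILE_SIZE
    origin: tuple[int, int] = (0, 0)
    stride: int | None = None  # None -> tile_size (non-overlapping)

    def __post_init__(self) -> None:
        if self.tile_size <= 0:
            raise ValueError("tile_size must be positive")
        if self.stride is not None and self.stride <= 0:
            raise ValueError("stride must be positive")

    @property
    def step(self) -> int:
        return self.stride if self.stride is not None else self.tile_size


@dataclass
class Tile:
    pixels: np.ndarray  # H x W x 3 uint8
    slide_id: str = "slide"
    grid_position: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3 or px.shape[0] != px.shape[1]:
            raise ValueError("tile pixels must be a square H x W x 3 array")


@dataclass
class StainNormParams:
    """Fitted Macenko parameters: stain basis and concentration scaling."""

    stain_matrix: np.ndarray        # 3 x 2 OD matrix, columns (H, E), unit-norm
    max_concentrations: np.ndarray  # length-2, 99th-percentile concentrations
    od_threshold: float = 0.15
    percentile_alpha: float = 1.0

    def __post_init__(self) -> None:
        m = np.asarray(self.stain_matrix, dtype=float)
        if m.shape != (3, 2) or np.any(m < -1e-9):
            raise ValueError("stain_matrix must be a nonnegative 3x2 matrix")
        if not np.allclose(np.linalg.norm(m, axis=0), 1.0, atol=1e-6):
            raise ValueError("stain_matrix columns must be unit-norm")
        if np.any(np.asarray(self.max_concentrations) <= 0):
            raise ValueError("max_concentrations must be positive")


# ---------------------------------------------------------------------------
# tiling and background removal
# ---------------------------------------------------------------------------

def tile_image(image: np.ndarray, grid: TileGridSpec, slide_id: str = "slide") -> list[Tile]:
    """Cut an image into tiles on a regular grid; partial edge tiles are discarded.

    Tiles are returned in row-major order of their (row_idx, col_idx) grid
    position; pixel intervals are half-open and 0-based from ``grid.origin``.
    """
    img = np.asarray(image)
    ts, step = grid.tile_size, grid.step
    r0, c0 = grid.origin
    h, w = img.shape[0] - r0, img.shape[1] - c0
    if h < ts or w < ts:
        warnings.warn("image smaller than one tile; returning empty list")
        return []
    tiles = []
    for ri, r in enumerate(range(r0, img.shape[0] - ts + 1, step)):
        for ci, c in enumerate(range(c0, img.shape[1] - ts + 1, step)):
            tiles.append(Tile(img[r : r + ts, c : c + ts].copy(), slide_id, (ri, ci)))
    return tiles


def is_background(
    tile: Tile, white_threshold: int = 220, max_white_fraction: float = 0.5
) -> bool:
    """True iff the fraction of near-white pixels strictly exceeds the cutoff.

    A pixel counts as white when its darkest channel exceeds
    ``white_threshold``; tiles that are predominantly white background carry
    no tissue and are excluded from analysis.
    """
    px = np.asarray(tile.pixels)
    white = px.min(axis=2) > white_threshold
    return bool(white.mean() > max_white_fraction)


# ---------------------------------------------------------------------------
# Macenko stain normalization
# ---------------------------------------------------------------------------

def _rgb_to_od(px: np.ndarray) -> np.ndarray:
    # +1 guard keeps zero-intensity pixels at finite optical density
    return -np.log((px.astype(float) + 1.0) / 256.0)


def _od_to_rgb(od: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(256.0 * np.exp(-od) - 1.0), 0, 255).astype(np.uint8)


def fit_macenko(
    reference_tile: Tile | np.ndarray,
    od_threshold: float = 0.15,
    percentile_alpha: float = 1.0,
) -> StainNormParams:
    """Estimate the H&E stain basis of a tile by the Macenko procedure.

    Optical densities OD = -log((I+1)/256) of tissue pixels (all channels
    above ``od_threshold``) are projected onto the plane of their top two
    singular vectors; the stain vectors are taken at the alpha and 100-alpha
    angular percentiles within that plane, sign-fixed nonnegative, with
    hematoxylin ordered before eosin by red-channel OD. Maximum
    concentrations are the 99th percentiles of the projected concentrations.
    """
    px = reference_tile.pixels if isinstance(reference_tile, Tile) else np.asarray(reference_tile)
    od = _rgb_to_od(px).reshape(-1, 3)
    tissue = od[np.all(od > od_threshold, axis=1)]
    if tissue.shape[0] < MIN_TISSUE_PIXELS:
        raise NormalizationError(
            f"too few tissue pixels above OD {od_threshold} ({tissue.shape[0]} < {MIN_TISSUE_PIXELS})"
        )

    # plane of the top-2 right singular vectors of the tissue ODs
    _, _, vt = np.linalg.svd(tissue, full_matrices=False)
    basis = vt[:2].T  # 3 x 2
    for j in range(2):
        if basis[:, j].sum() < 0:
            basis[:, j] = -basis[:, j]

    proj = tissue @ basis
    phi = np.arctan2(proj[:, 1], proj[:, 0])
    lo, hi = np.percentile(phi, (percentile_alpha, 100.0 - percentile_alpha))
    v1 = basis @ np.array([np.cos(lo), np.sin(lo)])
    v2 = basis @ np.array([np.cos(hi), np.sin(hi)])
    stains = []
    for v in (v1, v2):
        if v.sum() < 0:
            v = -v
        v = np.clip(v, 0.0, None)
        stains.append(v / np.linalg.norm(v))
    # hematoxylin absorbs red more strongly: larger red-channel OD first
    if stains[0][0] < stains[1][0]:
        stains = stains[::-1]
    stain_matrix = np.column_stack(stains)

    conc, *_ = np.linalg.lstsq(stain_matrix, tissue.T, rcond=None)
    max_c = np.percentile(np.clip(conc, 0.0, None), 99.0, axis=1)
    max_c = np.maximum(max_c, 1e-8)
    return StainNormParams(stain_matrix, max_c, od_threshold, percentile_alpha)


def apply_macenko(
    tile: Tile | np.ndarray, source_params: StainNormParams, target_params: StainNormParams
) -> Tile:
    """Re-express a tile's stain concentrations in a target stain basis.

    Concentrations under the source basis are rescaled by the ratio of target
    to source maximum concentrations and recomposited with the target stain
    matrix; output is clipped to 8 bit.
    """
    is_tile = isinstance(tile, Tile)
    px = tile.pixels if is_tile else np.asarray(tile)
    h, w = px.shape[:2]
    od = _rgb_to_od(px).reshape(-1, 3)
    conc, *_ = np.linalg.lstsq(source_params.stain_matrix, od.T, rcond=None)
    conc *= (target_params.max_concentrations / source_params.max_concentrations)[:, None]
    out = _od_to_rgb((target_params.stain_matrix @ conc).T.reshape(h, w, 3))
    if is_tile:
        return Tile(out, tile.slide_id, tile.grid_position)
    return Tile(out)


# ---------------------------------------------------------------------------
# model-input standardization and augmentation
# ---------------------------------------------------------------------------

def zscore_tile(tile: Tile | np.ndarray) -> np.ndarray:
    """Per-channel (x - mean) / sd using per-tile statistics; constant channels map to zeros."""
    px = (tile.pixels if isinstance(tile, Tile) else np.asarray(tile)).astype(float)
    mean = px.mean(axis=(0, 1))
    sd = px.std(axis=(0, 1))
    out = np.zeros_like(px)
    nz = sd > 0
    out[..., nz] = (px[..., nz] - mean[nz]) / sd[nz]
    return out


def augment_tile(tile: Tile | np.ndarray, seed: int, crop_size: int | None = None) -> Tile:
    """Random crop (448/512 of the side by default, resized back) plus
    independent horizontal/vertical flips with probability 1/2 each.

    Deterministic under ``seed``; output dimensions equal input dimensions.
    """
    is_tile = isinstance(tile, Tile)
    px = tile.pixels if is_tile else np.asarray(tile)
    rng = np.random.default_rng(seed)
    ts = px.shape[0]
    cs = crop_size if crop_size is not None else max(1, round(ts * DEFAULT_CROP / DEFAULT_TILE_SIZE))
    cs = min(cs, ts)
    r = int(rng.integers(0, ts - cs + 1))
    c = int(rng.integers(0, ts - cs + 1))
    out = px[r : r + cs, c : c + cs]
    if cs != ts:
        out = resize(out.astype(float), (ts, ts, 3), order=1, anti_aliasing=False)
        out = np.clip(np.rint(out), 0, 255).astype(np.uint8)
    if rng.uniform() < 0.5:
        out = out[:, ::-1]
    if rng.uniform() < 0.5:
        out = out[::-1, :]
    out = np.ascontiguousarray(out)
    if is_tile:
        return Tile(out, tile.slide_id, tile.grid_position)
    return Tile(out)
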