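"""Denoising and contrast enhancement (pipeline stages producing I and J).

Fluorescence frames carry mixed Poisson-Gaussian noise which, at moderate
photon counts, is well approximated as Gaussian; a plain Gaussian filter is
therefore used for denoising. Empty (unoccupied) droplets are only weakly
luminescent, so contrast-limited adaptive histogram equalization (CLAHE)
follows to lift them out of the background before segmentation.

The CLAHE here is the classic tile-based variant: the image is partitioned
into ``tiles x tiles`` blocks, each block's 256-bin histogram is clipped at
``clip`` times the block pixel count with the excess redistributed uniformly
over all bins (iterated until the residual excess is below one count), each
block's equalization map is the normalized cumulative histogram, and every
pixel is mapped by bilinear interpolation between the four nearest block
centers (nearest block at the borders).
"""

from __future__ import annotations

import math

import numpy as np
from scipy import ndimage

_NBINS = 256


def gaussian_denoise(image: np.ndarray, sigma: float = 1.0) -> np.ndarray:
    """Isotropic Gaussian filter, kernel truncated at 3*sigma, reflect borders."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    image = np.asarray(image, dtype=np.float64)
    radius = math.ceil(3 * sigma)
    out = ndimage.gaussian_filter(image, sigma=sigma, mode="reflect", radius=radius)
    return np.clip(out, 0.0, 1.0)


def estimate_snr(image: np.ndarray, foreground: np.ndarray) -> float:
    """Signal-to-noise ratio: foreground mean over background standard deviation.

    A diagnostic only. Returns ``inf`` for a noise-free background.
    """
    image = np.asarray(image, dtype=np.float64)
    foreground = np.asarray(foreground, dtype=bool)
    if image.shape != foreground.shape:
        raise ValueError("image and foreground mask shapes differ")
    if not foreground.any() or foreground.all():
        raise ValueError("foreground must be non-empty and not cover the image")
    noise = float(np.std(image[~foreground]))
    signal = float(np.mean(image[foreground]))
    if noise == 0.0:
        return math.inf
    return signal / noise


def _block_edges(extent: int, n: int) -> np.ndarray:
    """Block boundaries: n equal blocks, the last absorbing the remainder."""
    size = extent // n
    edges = np.arange(n + 1) * size
    edges[-1] = extent
    return edges


def _clip_redistribute(hist: np.ndarray, clip_counts: np.ndarray) -> np.ndarray:
    """Clip histograms at clip_counts and spread the excess over all bins.

    ``hist`` is (..., 256) float, ``clip_counts`` broadcastable against it.
    Iterates because redistribution can push bins back over the limit; total
    mass is conserved throughout.
    """
    hist = hist.astype(np.float64).copy()
    for _ in range(64):
        excess = np.clip(hist - clip_counts, 0.0, None).sum(axis=-1, keepdims=True)
        if float(excess.max()) < 1.0:
            break
        hist = np.minimum(hist, clip_counts)
        hist += excess / _NBINS
    return hist


def clahe_enhance(
    image: np.ndarray, tiles: int = 8, clip: float = 0.05
) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization on a [0, 1] image.

    ``tiles=1, clip=1`` degenerates to plain global histogram equalization.
    """
    if tiles < 1:
        raise ValueError("tiles must be >= 1")
    if not 0 < clip <= 1:
        raise ValueError("clip must be in (0, 1]")
    image = np.asarray(image, dtype=np.float64)
    h, w = image.shape
    if h // tiles < 2 or w // tiles < 2:
        raise ValueError(
            f"image {h}x{w} too small for {tiles}x{tiles} blocks of >= 2x2 px"
        )

    bins = np.minimum((image * _NBINS).astype(np.int64), _NBINS - 1)
    row_edges = _block_edges(h, tiles)
    col_edges = _block_edges(w, tiles)

    hist = np.empty((tiles, tiles, _NBINS))
    npix = np.empty((tiles, tiles, 1))
    for i in range(tiles):
        for j in range(tiles):
            block = bins[row_edges[i] : row_edges[i + 1], col_edges[j] : col_edges[j + 1]]
            hist[i, j] = np.bincount(block.ravel(), minlength=_NBINS)
            npix[i, j, 0] = block.size

    hist = _clip_redistribute(hist, clip * npix)
    # per-block equalization map: normalized cumulative histogram
    maps = np.cumsum(hist, axis=-1) / npix

    # fractional tile coordinates of every pixel relative to block centers
    centers_r = (row_edges[:-1] + row_edges[1:] - 1) / 2.0
    centers_c = (col_edges[:-1] + col_edges[1:] - 1) / 2.0
    pos_r = np.interp(np.arange(h), centers_r, np.arange(tiles))
    pos_c = np.interp(np.arange(w), centers_c, np.arange(tiles))
    r0 = np.floor(pos_r).astype(np.int64)
    c0 = np.floor(pos_c).astype(np.int64)
    r1 = np.minimum(r0 + 1, tiles - 1)
    c1 = np.minimum(c0 + 1, tiles - 1)
    fr = (pos_r - r0)[:, None]
    fc = (pos_c - c0)[None, :]

    r0g, r1g = r0[:, None], r1[:, None]
    c0g, c1g = c0[None, :], c1[None, :]
    out = (
        (1 - fr) * (1 - fc) * maps[r0g, c0g, bins]
        + (1 - fr) * fc * maps[r0g, c1g, bins]
        + fr * (1 - fc) * maps[r1g, c0g, bins]
        + fr * fc * maps[r1g, c1g, bins]
    )
    return np.clip(out, 0.0, 1.0)
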