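"""Binary segmentation of the enhanced image (stage producing map K).

Otsu's criterion picks the global threshold maximizing the between-class
variance of the 256-bin intensity histogram; a morphological opening with a
disk element then deletes bright speckles and vesicles that are far smaller
than any droplet.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

_NBINS = 256


def otsu_threshold(image: np.ndarray) -> float:
    """Between-class-variance-maximizing threshold on a 256-bin histogram.

    Returns the bin edge b/256 (b in 1..255) maximizing
    ``w0*w1*(mu0-mu1)**2``; ties broken toward the smallest threshold.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.min() == image.max():
        raise ValueError("constant image: no two classes to separate")
    bins = np.minimum((image * _NBINS).astype(np.int64), _NBINS - 1)
    hist = np.bincount(bins.ravel(), minlength=_NBINS).astype(np.float64)
    centers = (np.arange(_NBINS) + 0.5) / _NBINS

    # cumulative class weights/means for every candidate split b = 1..255:
    # class 0 holds bins < b, class 1 holds bins >= b
    w0 = np.cumsum(hist)[:-1]
    w1 = hist.sum() - w0
    m0 = np.cumsum(hist * centers)[:-1]
    m1 = (hist * centers).sum() - m0
    valid = (w0 > 0) & (w1 > 0)
    var_between = np.zeros(_NBINS - 1)
    var_between[valid] = (
        w0[valid] * w1[valid] * (m0[valid] / w0[valid] - m1[valid] / w1[valid]) ** 2
    )
    b = int(np.argmax(var_between)) + 1  # argmax takes the first (smallest) tie
    return b / _NBINS


def binarize(image: np.ndarray, t: float) -> np.ndarray:
    """Pixelwise ``value > t`` (ties on the threshold go to background)."""
    if not 0 <= t <= 1:
        raise ValueError("threshold must be in [0, 1]")
    return np.asarray(image, dtype=np.float64) > t


def morphological_open(mask: np.ndarray, radius: int = 5) -> np.ndarray:
    """Opening (erosion then dilation) with a discrete disk element.

    Radius 0 is the identity. Anti-extensive and idempotent; objects that
    cannot contain the disk vanish, which is what removes the small bright
    speckles surviving thresholding.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    mask = np.asarray(mask, dtype=bool)
    if radius == 0:
        return mask.copy()
    return ndimage.binary_opening(mask, structure=disk(radius))
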