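"""Classic segmentation baselines: thresholding and region growing.

Both methods work on a greyscale rendering of the three visible
channels, apply Gaussian smoothing first and a morphological
close-then-open afterwards.  Thresholding binarises at the modal pixel
value plus an offset of 15 (on a 0-255 integer scale) and keeps the
uppermost connected component, exploiting the layout in which the
specimen always sits above the grey standards.  Region growing admits
4-neighbours whose grey value lies within an asymmetric window around
the original seed value (default lower 6, upper 30).

Chan-Vese and graph cut are not implemented here (library algorithms;
see README for the initialisation conventions used alongside them).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi
from skimage import measure, morphology

from .errors import BoundsError, EmptySegmentation, SeedError
from .specimen import SpecimenImage

MODE_OFFSET = 15
GROW_LOWER, GROW_UPPER = 6, 30


def _as_channels(image) -> np.ndarray:
    if isinstance(image, SpecimenImage):
        return image.channels
    return np.asarray(image, dtype=float)


def to_greyscale(image) -> np.ndarray:
    """Unweighted mean of the three visible channels, rescaled to 0-255 ints."""
    channels = _as_channels(image)
    grey = channels[:3].mean(axis=0)
    lo, hi = grey.min(), grey.max()
    if hi <= lo:
        return np.zeros(grey.shape, dtype=np.uint8)
    return np.rint((grey - lo) / (hi - lo) * 255.0).astype(np.uint8)


def gaussian_smooth(channel: np.ndarray, sigma: float) -> np.ndarray:
    """2-D Gaussian smoothing with reflective borders (mean-preserving)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return ndi.gaussian_filter(np.asarray(channel, dtype=float), sigma, mode="reflect")


def morph_open_close(mask: np.ndarray, radius: int = 1) -> np.ndarray:
    """Morphological closing then opening with a (2r+1)-square element."""
    if radius < 1:
        raise ValueError("radius must be >= 1")
    footprint = np.ones((2 * radius + 1, 2 * radius + 1), dtype=bool)
    closed = morphology.closing(mask.astype(bool), footprint)
    return morphology.opening(closed, footprint).astype(bool)


def _modal_value(grey_u8: np.ndarray) -> int:
    # ties broken toward the smaller (darker) value by argmax order
    return int(np.bincount(grey_u8.ravel(), minlength=256).argmax())


def threshold_segment(image, sigma: float = 1.0, radius: int = 1) -> np.ndarray:
    """Modal+offset thresholding keeping the uppermost connected component.

    Greyscale > mode + 15, morphological close/open, then among
    8-connected components keep the one whose topmost pixel has the
    smallest row index (ties broken toward larger area).
    """
    grey = to_greyscale(image).astype(float)
    grey = gaussian_smooth(grey, sigma)
    grey_u8 = np.clip(np.rint(grey), 0, 255).astype(np.uint8)
    binary = grey_u8 > _modal_value(grey_u8) + MODE_OFFSET
    if not binary.any():
        raise EmptySegmentation("no pixel above modal threshold")
    binary = morph_open_close(binary, radius)
    if not binary.any():
        raise EmptySegmentation("morphology removed all foreground")
    labels = measure.label(binary, connectivity=2)
    best, best_key = None, None
    for lab in range(1, labels.max() + 1):
        rows = np.nonzero(labels == lab)[0]
        key = (rows.min(), -rows.size)  # uppermost first, then larger area
        if best_key is None or key < best_key:
            best, best_key = lab, key
    return labels == best


def region_grow(
    image,
    seeds,
    lower: int = GROW_LOWER,
    upper: int = GROW_UPPER,
    sigma: float = 1.0,
    radius: int = 1,
) -> np.ndarray:
    """Seeded region growing on the greyscale image.

    From each seed, 4-connected pixels whose grey value lies in
    [seed_grey - lower, seed_grey + upper] are grown breadth-first; the
    similarity window is anchored at the original seed value, so the
    grown region equals the seed's connected component of the
    eligibility mask.  The union over seeds is post-processed with
    close/open morphology.
    """
    if lower < 0 or upper < 0:
        raise ValueError("boundaries must be non-negative")
    seeds = [tuple(map(int, s)) for s in seeds]
    if not seeds:
        raise SeedError("empty seed list")
    grey = to_greyscale(image).astype(float)
    grey = gaussian_smooth(grey, sigma)
    h, w = grey.shape
    for r, c in seeds:
        if not (0 <= r < h and 0 <= c < w):
            raise BoundsError(f"seed {(r, c)} outside image bounds")

    union = np.zeros(grey.shape, dtype=bool)
    for r, c in seeds:
        seed_val = grey[r, c]
        eligible = (grey >= seed_val - lower) & (grey <= seed_val + upper)
        labels = measure.label(eligible, connectivity=1)
        union |= labels == labels[r, c]
    return morph_open_close(union, radius)
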