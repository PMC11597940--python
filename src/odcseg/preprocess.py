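"""Preprocessing: disc-centred ROI crop, CLAHE and label encoding.

The crop takes the tight bounding box of the optic-disc mask, expands it
by a margin (200 px on full-resolution fundus images) on all four sides
and clamps to the image bounds; coordinates are 0-based with half-open
boxes.  Contrast-limited adaptive histogram equalization runs on the
luminance channel of CIELAB by default (chrominance preserved), with a
per-channel RGB switch.  Labels are encoded as mutually exclusive
one-hot {background, rim, cup} planes; the disc is reconstructed
downstream as rim | cup.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import color, exposure, transform

__all__ = [
    "RoiBox",
    "crop_roi",
    "equalize_contrast",
    "encode_labels",
    "decode_labels",
    "resize_sample",
]


@dataclass(frozen=True)
class RoiBox:
    """Half-open pixel box [row_min, row_max) x [col_min, col_max)."""

    row_min: int
    row_max: int
    col_min: int
    col_max: int

    def __post_init__(self):
        if not (self.row_min < self.row_max and self.col_min < self.col_max):
            raise ValueError("RoiBox must have positive extent")

    def slices(self) -> tuple[slice, slice]:
        return slice(self.row_min, self.row_max), slice(self.col_min, self.col_max)


def roi_box_from_mask(od_mask, margin: int, shape: tuple[int, int]) -> RoiBox:
    od = np.asarray(od_mask).astype(bool)
    if not od.any():
        raise ValueError("optic disc mask is empty; cannot locate the ROI")
    if margin < 0:
        raise ValueError("margin must be nonnegative")
    rows = np.flatnonzero(od.any(axis=1))
    cols = np.flatnonzero(od.any(axis=0))
    return RoiBox(
        row_min=max(int(rows[0]) - margin, 0),
        row_max=min(int(rows[-1]) + 1 + margin, shape[0]),
        col_min=max(int(cols[0]) - margin, 0),
        col_max=min(int(cols[-1]) + 1 + margin, shape[1]),
    )


def crop_roi(image, od_mask, oc_mask, margin: int = 200):
    """Crop image and masks to the disc bounding box expanded by ``margin``.

    Returns ``(image, od_mask, oc_mask, box)`` with all three arrays cut
    identically.
    """
    image = np.asarray(image)
    od = np.asarray(od_mask).astype(bool)
    oc = np.asarray(oc_mask).astype(bool)
    box = roi_box_from_mask(od, margin, od.shape)
    rs, cs = box.slices()
    return image[rs, cs], od[rs, cs], oc[rs, cs], box


def equalize_contrast(image, clip_limit: float = 2.0,
                      tile_grid: tuple[int, int] = (8, 8),
                      per_channel: bool = False) -> np.ndarray:
    """CLAHE on an 8-bit RGB image.

    ``clip_limit`` follows the counts-per-bin convention (default 2.0) and
    is converted to a normalised histogram-fraction clip internally.  By
    default the equalization runs on the CIELAB luminance channel only;
    ``per_channel=True`` equalizes each RGB channel independently.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 RGB image, got shape {image.shape}")
    kernel = (max(image.shape[0] // tile_grid[0], 1),
              max(image.shape[1] // tile_grid[1], 1))
    clip = min(max(clip_limit / 256.0, 1e-4), 1.0)
    if per_channel:
        out = np.stack([
            exposure.equalize_adapthist(image[..., c], kernel_size=kernel,
                                        clip_limit=clip)
            for c in range(3)
        ], axis=-1)
        return (out * 255).round().astype(np.uint8)
    lab = color.rgb2lab(image)
    lum = exposure.equalize_adapthist(lab[..., 0] / 100.0,
                                      kernel_size=kernel, clip_limit=clip)
    lab[..., 0] = lum * 100.0
    rgb = color.lab2rgb(lab)
    return (np.clip(rgb, 0, 1) * 255).round().astype(np.uint8)


def encode_labels(od_mask, oc_mask) -> np.ndarray:
    """One-hot (3, H, W) encoding {background, rim, cup}; exactly-one-hot."""
    od = np.asarray(od_mask).astype(bool)
    oc = np.asarray(oc_mask).astype(bool)
    if od.shape != oc.shape:
        raise ValueError(f"mask shape mismatch: {od.shape} vs {oc.shape}")
    violations = int(np.count_nonzero(oc & ~od))
    if violations:
        raise ValueError(
            f"cup mask extends outside disc mask at {violations} pixel(s)")
    onehot = np.zeros((3,) + od.shape, dtype=np.float32)
    onehot[0] = ~od
    onehot[1] = od & ~oc
    onehot[2] = oc
    return onehot


def decode_labels(onehot) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`encode_labels` via channel argmax."""
    labels = np.asarray(onehot).argmax(axis=0)
    return labels > 0, labels == 2


def resize_sample(image, od_mask, oc_mask, size: int):
    """Resample to ``size``x``size`` (image bilinear, masks nearest)."""
    img = transform.resize(np.asarray(image), (size, size),
                           order=1, preserve_range=True,
                           anti_aliasing=True).round().astype(np.uint8)
    od = transform.resize(np.asarray(od_mask).astype(float), (size, size),
                          order=0, preserve_range=True) > 0.5
    oc = transform.resize(np.asarray(oc_mask).astype(float), (size, size),
                          order=0, preserve_range=True) > 0.5
    return img, od, oc & od
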