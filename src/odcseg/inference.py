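"""Checkpoint I/O and the discriminator-free inference path."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from PIL import Image

from .metrics import decode_prediction
from .models import SegmenterSpec, UNetSegmenter

__all__ = ["save_checkpoint", "load_checkpoint", "predict", "write_label_png",
           "write_overlay_png"]

# paletted label colors: background, rim (orange), cup (yellow)
_PALETTE = [0, 0, 0, 230, 120, 30, 250, 230, 80]


def save_checkpoint(segmenter: UNetSegmenter, path) -> None:
    """Save weights as .npz with a JSON sidecar recording the spec."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **segmenter.state_dict())
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(segmenter.spec.to_dict(), indent=2))


def load_checkpoint(path) -> UNetSegmenter:
    path = Path(path)
    spec_dict = json.loads(path.with_suffix(".json").read_text())
    spec = SegmenterSpec(**spec_dict)
    segmenter = UNetSegmenter(spec, np.random.default_rng(0))
    with np.load(path) as data:
        segmenter.load_state_dict({k: data[k] for k in data.files})
    segmenter.eval()
    return segmenter


def write_label_png(od_mask, oc_mask, path) -> None:
    label = np.zeros(np.asarray(od_mask).shape, dtype=np.uint8)
    label[np.asarray(od_mask).astype(bool)] = 1
    label[np.asarray(oc_mask).astype(bool)] = 2
    img = Image.fromarray(label, mode="P")
    img.putpalette(_PALETTE)
    img.save(path)


def _contour(mask: np.ndarray) -> np.ndarray:
    from scipy import ndimage
    m = mask.astype(bool)
    return m & ~ndimage.binary_erosion(m)


def write_overlay_png(image, od_mask, oc_mask, path) -> None:
    overlay = np.asarray(image).copy()
    overlay[_contour(np.asarray(od_mask))] = (0, 255, 0)
    overlay[_contour(np.asarray(oc_mask))] = (0, 120, 255)
    Image.fromarray(overlay).save(path)


def predict(checkpoint_path, image_paths, out_dir) -> list[Path]:
    """Segment images with a saved checkpoint; no discriminator is loaded.

    Writes a 3-valued paletted label PNG plus a contour overlay per input
    and returns the label paths.  Predicted structures are cleaned to
    their largest connected component with the cup clipped to the disc.
    """
    segmenter = load_checkpoint(checkpoint_path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for image_path in map(Path, image_paths):
        image = np.asarray(Image.open(image_path).convert("RGB"))
        probs = segmenter.predict_probs(image)
        od, oc = decode_prediction(probs, clean=True)
        mask_path = out_dir / f"{image_path.stem}_mask.png"
        write_label_png(od, oc, mask_path)
        write_overlay_png(image, od, oc, out_dir / f"{image_path.stem}_overlay.png")
        written.append(mask_path)
    return written
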