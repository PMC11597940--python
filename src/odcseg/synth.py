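"""Seeded synthetic fundus-ROI generator.

Produces optic-disc/optic-cup scenes that emulate the two properties the
segmentation framework exploits: class-dependent *morphology* (glaucoma
samples have an enlarged cup relative to the disc) and class-dependent
*imaging style* (a mild colour cast, contrast and texture shift between
the normal and glaucoma pools).  Images are rendered directly at ROI
scale: a reddish background, a brighter elliptical disc, a brightest
elliptical cup nested inside it, dark curvilinear vessel strokes
(random quadratic Bezier curves), Gaussian texture noise and a small
blur.  Masks are the exact rasterised ellipses, so the ground truth is
noise-free by construction.

Everything is driven by named, per-split random streams derived from the
master seed, so a (seed, config) pair fully determines every pixel and
adding samples to one split never perturbs another.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage
from skimage.draw import ellipse as draw_ellipse

__all__ = [
    "DiscCupGeometry",
    "StyleParams",
    "SyntheticSample",
    "SynthConfig",
    "sample_geometry",
    "rasterize_geometry",
    "render_sample",
    "generate_split",
    "generate_dataset",
    "load_dataset",
    "GenerationError",
]

NORMAL, GLAUCOMA = 0, 1
_DOMAIN_NAMES = {NORMAL: "normal", GLAUCOMA: "glaucoma"}


class GenerationError(RuntimeError):
    """Raised when a valid geometry cannot be drawn within the retry budget."""


@dataclass(frozen=True)
class DiscCupGeometry:
    """Elliptical disc and cup in pixel coordinates (row, col)."""

    disc_center: tuple[float, float]
    disc_radii: tuple[float, float]     # (vertical, horizontal)
    cup_center: tuple[float, float]
    cup_radii: tuple[float, float]
    rotation: float = 0.0               # degrees


@dataclass(frozen=True)
class StyleParams:
    """Rendering style of one class."""

    rgb_gain: tuple[float, float, float] = (1.0, 1.0, 1.0)
    background_base: tuple[float, float, float] = (150.0, 75.0, 55.0)
    vessel_count: int = 6
    vessel_contrast: float = 0.45
    texture_sigma: float = 4.0          # Gaussian noise std, intensity units
    blur_sigma: float = 0.7             # pixels
    global_contrast: float = 1.0

    def __post_init__(self):
        if any(g <= 0 for g in self.rgb_gain):
            raise ValueError("rgb_gain entries must be strictly positive")
        if self.vessel_contrast < 0 or self.global_contrast <= 0:
            raise ValueError("contrasts must be positive")
        if self.texture_sigma < 0:
            raise ValueError("texture_sigma must be nonnegative")


#: shipped per-class styles: the glaucoma pool carries a mild red-shifted
#: colour cast and slightly different texture, emulating a vendor/style gap.
DEFAULT_STYLE_NORMAL = StyleParams()
DEFAULT_STYLE_GLAUCOMA = StyleParams(
    rgb_gain=(1.12, 0.92, 0.85),
    vessel_count=7,
    texture_sigma=5.0,
    blur_sigma=0.9,
)


@dataclass(frozen=True)
class SyntheticSample:
    image: np.ndarray          # H x W x 3 uint8
    od_mask: np.ndarray        # H x W bool
    oc_mask: np.ndarray        # H x W bool
    domain_label: int          # 0 = normal, 1 = glaucoma
    has_pixel_annotation: bool
    sample_id: str

    @property
    def domain(self) -> str:
        return _DOMAIN_NAMES[self.domain_label]


@dataclass(frozen=True)
class SynthConfig:
    """Generator configuration.

    Per-axis cup-to-disc ratios are drawn uniformly from the class range;
    the shipped ranges are disjoint, so the vertical CDR separates the
    classes perfectly.
    """

    image_size: int = 256
    n_normal: int = 20
    n_glaucoma: int = 12
    n_val_normal: int = 0
    n_val_glaucoma: int = 12
    cdr_range_normal: tuple[float, float] = (0.3, 0.5)
    cdr_range_glaucoma: tuple[float, float] = (0.6, 0.85)
    disc_radius_frac: tuple[float, float] = (0.28, 0.36)   # of half image size
    center_jitter_frac: float = 0.05                       # of image size
    cup_offset_frac: float = 0.15                          # of disc radius
    eccentricity_range: tuple[float, float] = (0.85, 1.0)
    max_rotation: float = 15.0
    style_normal: StyleParams = DEFAULT_STYLE_NORMAL
    style_glaucoma: StyleParams = DEFAULT_STYLE_GLAUCOMA
    glaucoma_annotated_fraction: float = 0.5               # Scenario 2 split
    seed: int = 0
    max_retries: int = 50

    def __post_init__(self):
        for lo, hi in (self.cdr_range_normal, self.cdr_range_glaucoma):
            if not (0.0 < lo < hi < 1.0):
                raise ValueError("CDR ranges must satisfy 0 < lo < hi < 1")

    def style_for(self, class_label: int) -> StyleParams:
        return self.style_glaucoma if class_label == GLAUCOMA else self.style_normal

    def cdr_range_for(self, class_label: int) -> tuple[float, float]:
        return (self.cdr_range_glaucoma if class_label == GLAUCOMA
                else self.cdr_range_normal)


def _ellipse_mask(center, radii, rotation, size) -> np.ndarray:
    mask = np.zeros((size, size), dtype=bool)
    rr, cc = draw_ellipse(center[0], center[1], radii[0], radii[1],
                          shape=(size, size),
                          rotation=np.deg2rad(rotation))
    mask[rr, cc] = True
    return mask


def rasterize_geometry(geometry: DiscCupGeometry,
                       size: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact (od_mask, oc_mask) rasterisation of a geometry."""
    od = _ellipse_mask(geometry.disc_center, geometry.disc_radii,
                       geometry.rotation, size)
    oc = _ellipse_mask(geometry.cup_center, geometry.cup_radii,
                       geometry.rotation, size)
    return od, oc


def sample_geometry(class_label: int, config: SynthConfig,
                    rng: np.random.Generator) -> DiscCupGeometry:
    """Draw a disc/cup geometry whose rasterised cup nests inside the disc."""
    if class_label not in (NORMAL, GLAUCOMA):
        raise ValueError(f"unknown class label {class_label!r}")
    size = config.image_size
    half = size / 2.0
    cdr_lo, cdr_hi = config.cdr_range_for(class_label)
    for _ in range(config.max_retries):
        r_v = half * rng.uniform(*config.disc_radius_frac)
        r_h = r_v * rng.uniform(*config.eccentricity_range)
        jitter = size * config.center_jitter_frac
        center = (half + rng.uniform(-jitter, jitter),
                  half + rng.uniform(-jitter, jitter))
        rotation = rng.uniform(-config.max_rotation, config.max_rotation)
        cup_ratio_v = rng.uniform(cdr_lo, cdr_hi)
        cup_ratio_h = rng.uniform(cdr_lo, cdr_hi)
        cup_radii = (r_v * cup_ratio_v, r_h * cup_ratio_h)
        max_offset = config.cup_offset_frac * min(r_v - cup_radii[0],
                                                  r_h - cup_radii[1])
        max_offset = max(max_offset, 0.0)
        cup_center = (center[0] + rng.uniform(-max_offset, max_offset),
                      center[1] + rng.uniform(-max_offset, max_offset))
        geom = DiscCupGeometry(disc_center=center, disc_radii=(r_v, r_h),
                               cup_center=cup_center, cup_radii=cup_radii,
                               rotation=rotation)
        od = _ellipse_mask(geom.disc_center, geom.disc_radii, geom.rotation, size)
        oc = _ellipse_mask(geom.cup_center, geom.cup_radii, geom.rotation, size)
        # disc fully on canvas (with a 2 px border) and cup nested in disc
        border = np.zeros((size, size), dtype=bool)
        border[:2, :] = border[-2:, :] = True
        border[:, :2] = border[:, -2:] = True
        if oc.any() and od.any() and not (oc & ~od).any() and not (od & border).any():
            return geom
    raise GenerationError(
        f"could not draw a valid geometry in {config.max_retries} attempts")


def _draw_vessels(image: np.ndarray, od_mask: np.ndarray,
                  style: StyleParams, rng: np.random.Generator) -> None:
    """Dark quadratic Bezier strokes radiating roughly from the disc."""
    size = image.shape[0]
    origin = np.array(ndimage.center_of_mass(od_mask))
    for _ in range(style.vessel_count):
        angle = rng.uniform(0, 2 * np.pi)
        end = origin + (size * 1.2) * np.array([np.sin(angle), np.cos(angle)])
        mid = (origin + end) / 2 + rng.normal(0, size * 0.12, 2)
        t = np.linspace(0.0, 1.0, 4 * size)[:, None]
        pts = ((1 - t) ** 2 * origin + 2 * (1 - t) * t * mid + t**2 * end)
        rr = np.clip(np.round(pts[:, 0]).astype(int), 0, size - 1)
        cc = np.clip(np.round(pts[:, 1]).astype(int), 0, size - 1)
        width = rng.integers(1, 3)
        stroke = np.zeros((size, size), dtype=bool)
        stroke[rr, cc] = True
        if width > 1:
            stroke = ndimage.binary_dilation(stroke, iterations=int(width) - 1)
        image[stroke] *= (1.0 - style.vessel_contrast)


def render_sample(geometry: DiscCupGeometry, style: StyleParams,
                  class_label: int, config: SynthConfig,
                  rng: np.random.Generator,
                  sample_id: str = "sample",
                  has_pixel_annotation: bool = True) -> SyntheticSample:
    """Rasterise a geometry into an 8-bit RGB image plus exact masks."""
    size = config.image_size
    od = _ellipse_mask(geometry.disc_center, geometry.disc_radii,
                       geometry.rotation, size)
    oc = _ellipse_mask(geometry.cup_center, geometry.cup_radii,
                       geometry.rotation, size)
    if (oc & ~od).any():
        raise ValueError("cup mask is not contained in disc mask")

    base = np.asarray(style.background_base, dtype=np.float64)
    image = np.ones((size, size, 3)) * base[None, None, :]
    # gentle radial vignette so the background is not perfectly flat
    yy, xx = np.mgrid[0:size, 0:size]
    r2 = ((yy - size / 2) ** 2 + (xx - size / 2) ** 2) / (size / 2) ** 2
    image *= (1.0 - 0.15 * r2)[..., None]
    # disc brighter, cup brightest (the clinical appearance in fundus photos)
    disc_color = np.array([1.45, 1.75, 1.9])
    cup_color = np.array([1.75, 2.4, 2.7])
    image[od & ~oc] = base * disc_color
    image[oc] = base * cup_color
    _draw_vessels(image, od, style, rng)
    if style.texture_sigma > 0:
        image += rng.normal(0.0, style.texture_sigma, image.shape)
    if style.blur_sigma > 0:
        image = ndimage.gaussian_filter(image, (style.blur_sigma,
                                                style.blur_sigma, 0))
    image *= np.asarray(style.rgb_gain)[None, None, :]
    if style.global_contrast != 1.0:
        mean = image.mean()
        image = (image - mean) * style.global_contrast + mean
    image = np.clip(image, 0, 255).astype(np.uint8)
    return SyntheticSample(image=image, od_mask=od, oc_mask=oc,
                           domain_label=class_label,
                           has_pixel_annotation=has_pixel_annotation,
                           sample_id=sample_id)


_SPLIT_STREAMS = {
    ("normal", "train"): 0,
    ("glaucoma", "train"): 1,
    ("normal", "validation"): 2,
    ("glaucoma", "validation"): 3,
}


def _split_rng(seed: int, class_name: str, split: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed,
                               spawn_key=(_SPLIT_STREAMS[(class_name, split)],)))


def generate_split(config: SynthConfig, class_label: int, split: str,
                   count: int, *, annotated: bool,
                   id_prefix: str) -> list[SyntheticSample]:
    """Generate ``count`` samples of one class from that split's RNG stream."""
    class_name = _DOMAIN_NAMES[class_label]
    rng = _split_rng(config.seed, class_name, split)
    samples = []
    for i in range(count):
        geom = sample_geometry(class_label, config, rng)
        samples.append(render_sample(
            geom, config.style_for(class_label), class_label, config, rng,
            sample_id=f"{id_prefix}{i:03d}",
            has_pixel_annotation=annotated))
    return samples


def generate_scenario(config: SynthConfig,
                      scenario: int = 1) -> dict[str, list[SyntheticSample]]:
    """In-memory dataset for one clinical scenario.

    Returns splits ``source`` (training samples carrying pixel
    annotations), ``target`` (unannotated training samples) and
    ``validation``.  Which class is annotated depends on the scenario:
    1 = normals only, 2 = a glaucoma subset only, 3 = both classes.
    """
    if scenario not in (1, 2, 3):
        raise ValueError(f"scenario must be 1, 2 or 3, got {scenario!r}")
    normals = generate_split(config, NORMAL, "train", config.n_normal,
                             annotated=scenario in (1, 3), id_prefix="n")
    glaucomas = generate_split(config, GLAUCOMA, "train", config.n_glaucoma,
                               annotated=scenario in (2, 3), id_prefix="g")
    if scenario == 2:
        n_annot = max(1, int(round(config.glaucoma_annotated_fraction
                                   * config.n_glaucoma)))
        glaucomas = (
            [dataclasses.replace(s, has_pixel_annotation=True)
             for s in glaucomas[:n_annot]]
            + [dataclasses.replace(s, has_pixel_annotation=False)
               for s in glaucomas[n_annot:]])
        source = glaucomas[:n_annot]
        target = glaucomas[n_annot:] + [
            dataclasses.replace(s, has_pixel_annotation=False) for s in normals]
    else:
        source = normals + (glaucomas if scenario == 3 else [])
        target = [] if scenario == 3 else glaucomas
    validation = (
        generate_split(config, GLAUCOMA, "validation", config.n_val_glaucoma,
                       annotated=False, id_prefix="vg")
        + generate_split(config, NORMAL, "validation", config.n_val_normal,
                         annotated=False, id_prefix="vn"))
    return {"source": source, "target": target, "validation": validation}


def _write_png(path: Path, array: np.ndarray) -> None:
    Image.fromarray(array).save(path)


def sample_to_label_image(sample: SyntheticSample) -> np.ndarray:
    """3-valued label image {0: background, 1: rim, 2: cup} as uint8."""
    label = np.zeros(sample.od_mask.shape, dtype=np.uint8)
    label[sample.od_mask & ~sample.oc_mask] = 1
    label[sample.oc_mask] = 2
    return label


def generate_dataset(config: SynthConfig, out_dir, scenario: int = 1,
                     overwrite: bool = False) -> pd.DataFrame:
    """Write a scenario dataset to disk and return its manifest.

    Layout: ``images/<id>.png``, ``masks/<id>.png`` (3-valued labels) and
    ``manifest.csv`` with columns
    ``sample_id,image_path,mask_path,domain,split,annotated``.
    """
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
        raise FileExistsError(
            f"output directory {out_dir} is not empty (pass overwrite=True)")
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    splits = generate_scenario(config, scenario)
    rows = []
    for split_name, samples in splits.items():
        for s in samples:
            image_path = f"images/{s.sample_id}.png"
            mask_path = f"masks/{s.sample_id}.png"
            _write_png(out_dir / image_path, s.image)
            _write_png(out_dir / mask_path, sample_to_label_image(s))
            rows.append({"sample_id": s.sample_id, "image_path": image_path,
                         "mask_path": mask_path, "domain": s.domain,
                         "split": split_name,
                         "annotated": s.has_pixel_annotation})
    manifest = pd.DataFrame(rows, columns=["sample_id", "image_path",
                                           "mask_path", "domain", "split",
                                           "annotated"])
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def load_dataset(manifest_path) -> dict[str, list[SyntheticSample]]:
    """Read a manifest written by :func:`generate_dataset` back into memory."""
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    manifest = pd.read_csv(manifest_path)
    splits: dict[str, list[SyntheticSample]] = {}
    domain_labels = {v: k for k, v in _DOMAIN_NAMES.items()}
    for row in manifest.itertuples():
        image = np.asarray(Image.open(root / row.image_path).convert("RGB"))
        label = np.asarray(Image.open(root / row.mask_path))
        sample = SyntheticSample(
            image=image, od_mask=label > 0, oc_mask=label == 2,
            domain_label=domain_labels[row.domain],
            has_pixel_annotation=bool(row.annotated),
            sample_id=str(row.sample_id))
        splits.setdefault(row.split, []).append(sample)
    return splits
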