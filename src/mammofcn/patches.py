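"""Patch dataset construction from images and ROI masks.

Three sampling schemes build the 5-class patch sets used to train patch
classifiers:

* S1  — one patch centered on each ROI plus one random background patch,
        patch size 224;
* S10 — ten patches sampled from around each ROI, each capturing at least a
        0.9 overlap ratio with the ROI, plus an equal number of background
        patches, patch size 224;
* S1g — like S1 but with a large 448-pixel patch that includes the
        surrounding area.

The overlap ratio is the fraction of ROI pixels captured by the patch; for
ROIs larger than the patch it falls back to the fraction of the patch
covered by ROI (the larger of the two is used), so that "overlap 0.9" keeps
meaning "the patch captures the informative region almost completely".
Background patches must not intersect any ROI mask at all.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from skimage.transform import AffineTransform, warp

from .synthetic import PIXEL_MAX, RoiAnnotation, ScreenImage

log = logging.getLogger(__name__)

PATCH_CLASSES = ["background", "benign_calc", "malignant_calc",
                 "benign_mass", "malignant_mass"]
CLASS_INDEX = {c: i for i, c in enumerate(PATCH_CLASSES)}

# Augmentation parameter ranges (degrees, ratio, raw pixel values).
ROTATION_RANGE = (-25.0, 25.0)
ZOOM_RANGE = (0.8, 1.2)
SHIFT_RANGE = (-20.0, 20.0)


class InvalidAnnotationError(ValueError):
    pass


class SamplingError(RuntimeError):
    pass


@dataclass
class PatchRecord:
    pixels: np.ndarray            # (p, q) float32
    patch_class: str
    source_image_id: str
    offset: tuple[int, int]       # 0-based top-left (row, col)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.patch_class not in CLASS_INDEX:
            raise InvalidAnnotationError(f"unknown class {self.patch_class!r}")

    @property
    def class_index(self) -> int:
        return CLASS_INDEX[self.patch_class]


@dataclass
class SamplingScheme:
    name: str
    patch_size: int
    roi_patches_per_roi: int
    min_overlap: float | None     # None -> ROI-centered placement
    background_patches_per_roi: int

    @classmethod
    def S1(cls, patch_size: int = 224) -> "SamplingScheme":
        return cls("S1", patch_size, 1, None, 1)

    @classmethod
    def S10(cls, patch_size: int = 224) -> "SamplingScheme":
        return cls("S10", patch_size, 10, 0.9, 10)

    @classmethod
    def S1g(cls, patch_size: int = 448) -> "SamplingScheme":
        return cls("S1g", patch_size, 1, None, 1)

    @classmethod
    def by_name(cls, name: str, patch_size: int | None = None) -> "SamplingScheme":
        factory = {"S1": cls.S1, "S10": cls.S10, "S1g": cls.S1g}[name]
        return factory() if patch_size is None else factory(patch_size)


# ---------------------------------------------------------------------------

def overlap_ratio(patch_box: tuple[int, int, int, int],
                  roi: RoiAnnotation) -> float:
    """Fraction of the ROI's mask pixels that fall inside the patch box
    (row, col, height, width, half-open). For ROIs with more pixels than the
    patch area, the fraction of the patch covered by ROI is also computed
    and the larger of the two returned."""
    mask = roi.mask
    n_roi = int(mask.sum())
    if n_roi == 0:
        raise InvalidAnnotationError("ROI mask is empty")
    r, c, h, w = patch_box
    r0, c0 = max(r, 0), max(c, 0)
    r1, c1 = min(r + h, mask.shape[0]), min(c + w, mask.shape[1])
    inter = int(mask[r0:r1, c0:c1].sum()) if (r1 > r0 and c1 > c0) else 0
    frac_roi = inter / n_roi
    if n_roi > h * w:
        return max(frac_roi, inter / (h * w))
    return frac_roi


def _clip_offset(r, c, p, shape):
    return (int(np.clip(r, 0, shape[0] - p)), int(np.clip(c, 0, shape[1] - p)))


def _centered_offset(roi: RoiAnnotation, p: int, shape) -> tuple[int, int]:
    br, bc, bh, bw = roi.bounding_box
    return _clip_offset(br + bh // 2 - p // 2, bc + bw // 2 - p // 2, p, shape)


def _crop(image: ScreenImage, offset, p) -> np.ndarray:
    r, c = offset
    return image.pixels[r:r + p, c:c + p].copy()


def sample_patches(image: ScreenImage, rois: list[RoiAnnotation],
                   scheme: SamplingScheme, rng: np.random.Generator,
                   max_tries: int = 2000) -> list[PatchRecord]:
    """Sample ROI and background patches from one image under a scheme.

    Centered schemes (S1/S1g) place the patch center on the ROI bounding-box
    center, shifted minimally to stay in bounds. S10 draws distinct offsets
    around each ROI until `roi_patches_per_roi` of them reach the minimum
    overlap ratio. Background patches never intersect any ROI mask. All
    patches lie fully inside the image.
    """
    p = scheme.patch_size
    h, w = image.pixels.shape
    if h < p or w < p:
        raise SamplingError(f"image {image.image_id} ({h}x{w}) smaller than "
                            f"patch size {p}")
    records: list[PatchRecord] = []
    n_background = 0
    for roi in rois:
        if scheme.min_overlap is None:
            off = _centered_offset(roi, p, (h, w))
            records.append(PatchRecord(_crop(image, off, p), roi.lesion_class,
                                       image.image_id, off))
        else:
            br, bc, bh, bw = roi.bounding_box
            cr, cc = br + bh // 2, bc + bw // 2
            seen: set[tuple[int, int]] = set()
            tries = 0
            while (len(seen) < scheme.roi_patches_per_roi
                   and tries < max_tries):
                tries += 1
                off = _clip_offset(cr - p // 2 + rng.integers(-p // 2, p // 2 + 1),
                                   cc - p // 2 + rng.integers(-p // 2, p // 2 + 1),
                                   p, (h, w))
                if off in seen:
                    continue
                if overlap_ratio((off[0], off[1], p, p), roi) >= scheme.min_overlap:
                    seen.add(off)
                    records.append(PatchRecord(_crop(image, off, p),
                                               roi.lesion_class,
                                               image.image_id, off))
            if len(seen) < scheme.roi_patches_per_roi:
                raise SamplingError(
                    f"could not find {scheme.roi_patches_per_roi} distinct "
                    f"offsets with overlap >= {scheme.min_overlap} for an ROI "
                    f"in image {image.image_id}")
        n_background += scheme.background_patches_per_roi

    for _ in range(n_background):
        for attempt in range(max_tries):
            off = (int(rng.integers(0, h - p + 1)), int(rng.integers(0, w - p + 1)))
            if all(int(roi.mask[off[0]:off[0] + p, off[1]:off[1] + p].sum()) == 0
                   for roi in rois):
                records.append(PatchRecord(_crop(image, off, p), "background",
                                           image.image_id, off))
                break
        else:
            raise SamplingError(
                f"no ROI-free background location found in image "
                f"{image.image_id} after {max_tries} tries")
    return records


# ---------------------------------------------------------------------------
# Augmentation

@dataclass
class AugmentParams:
    hflip: bool = False
    vflip: bool = False
    rotation_deg: float = 0.0
    zoom: float = 1.0
    intensity_shift: float = 0.0

    @property
    def is_identity(self) -> bool:
        return (not self.hflip and not self.vflip and self.rotation_deg == 0.0
                and self.zoom == 1.0 and self.intensity_shift == 0.0)


def draw_augment_params(rng: np.random.Generator) -> AugmentParams:
    """Transform parameters drawn uniformly from the published ranges:
    flips, rotation in [-25, 25] degrees, zoom in [0.8, 1.2], intensity
    shift in [-20, 20] pixel values."""
    return AugmentParams(hflip=bool(rng.uniform() < 0.5),
                         vflip=bool(rng.uniform() < 0.5),
                         rotation_deg=float(rng.uniform(*ROTATION_RANGE)),
                         zoom=float(rng.uniform(*ZOOM_RANGE)),
                         intensity_shift=float(rng.uniform(*SHIFT_RANGE)))


def augment(patch: PatchRecord, rng: np.random.Generator | None = None,
            params: AugmentParams | None = None) -> PatchRecord:
    """Random flip / rotation / zoom / intensity-shift augmentation.

    Geometric transforms use bilinear interpolation with reflective border
    fill; the intensity shift is applied afterwards and clipped to the valid
    pixel range. Shape and label are unchanged; identity parameters return
    the patch bit-exactly.
    """
    if params is None:
        if rng is None:
            raise ValueError("need an rng or explicit params")
        params = draw_augment_params(rng)
    px = patch.pixels
    if params.hflip:
        px = px[:, ::-1]
    if params.vflip:
        px = px[::-1, :]
    if params.rotation_deg != 0.0 or params.zoom != 1.0:
        center = (np.array(px.shape[::-1]) - 1) / 2.0
        tform = (AffineTransform(translation=center)
                 + AffineTransform(rotation=np.deg2rad(params.rotation_deg),
                                   scale=1.0 / params.zoom)
                 + AffineTransform(translation=-center))
        px = warp(px.astype(np.float64), tform.inverse, order=1,
                  mode="reflect", preserve_range=True)
    px = np.clip(px + params.intensity_shift, 0, PIXEL_MAX).astype(np.float32)
    return replace(patch, pixels=px)


# ---------------------------------------------------------------------------

def class_balance_weights(batch_labels) -> np.ndarray:
    """Per-sample weights equalizing total weight across the classes present
    in a batch; weights sum to the batch size."""
    labels = np.asarray(batch_labels)
    if labels.size == 0:
        raise ValueError("batch is empty")
    classes, counts = np.unique(labels, return_counts=True)
    per_class = labels.size / (len(classes))
    weight_of = {c: per_class / n for c, n in zip(classes, counts)}
    return np.array([weight_of[l] for l in labels], dtype=np.float32)


def to_arrays(records: list[PatchRecord]) -> tuple[np.ndarray, np.ndarray]:
    """Stack patch records into (N, 1, p, p) pixels and integer labels."""
    x = np.stack([r.pixels for r in records])[:, None].astype(np.float32)
    y = np.array([r.class_index for r in records], dtype=np.int64)
    return x, y
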