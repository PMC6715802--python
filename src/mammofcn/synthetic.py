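"""Seeded synthetic screening-image generator.

Emulates the structure of a screening mammography cohort so every pipeline
stage is testable without external data: large grayscale images whose
informative lesion occupies a small fraction of the frame, four foreground
lesion classes plus background, two views (CC/MLO) of one breast per
patient, and a monotone intensity-profile shift between two acquisition
"platforms" (digitized film vs full-field digital).

Lesion phenotypes are chosen so the 5-class patch task is learnable but not
trivial: masses are smooth bright blobs (malignant ones grow radial
spicules); calcifications are clusters of small bright dots over a faint
halo (malignant ones finer and pleomorphic). The same lesion list is
re-implanted with jittered geometry in both views of a breast; no
projective geometry is simulated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage

log = logging.getLogger(__name__)

PIXEL_MAX = 65535.0
LESION_CLASSES = ["benign_calc", "malignant_calc", "benign_mass", "malignant_mass"]
VIEWS = ["CC", "MLO"]


class ConfigurationError(ValueError):
    pass


class PlacementError(ValueError):
    pass


@dataclass
class SyntheticConfig:
    image_height: int = 1152
    image_width: int = 896
    n_patients: int = 20
    views_per_breast: int = 2
    malignant_fraction: float = 0.5
    lesion_size_range: tuple[int, int] = (100, 300)
    platform: str = "A"
    seed: int = 0
    # Phenotype knobs, fixed defaults: benign/malignant pairs share their
    # base morphology so the classes are separable but confusable.
    spicule_count_range: tuple[int, int] = (8, 14)
    benign_dot_count_range: tuple[int, int] = (4, 7)
    malignant_dot_count_range: tuple[int, int] = (10, 18)
    benign_lesion_prob: float = 0.85   # chance a nonmalignant breast has a benign ROI
    view_jitter_frac: float = 0.04     # center jitter between views, per dim

    def validate(self):
        if self.image_height < 2 or self.image_width < 2:
            raise ConfigurationError("image dimensions must be positive")
        if not 0.0 <= self.malignant_fraction <= 1.0:
            raise ConfigurationError("malignant_fraction must lie in [0, 1]")
        lo, hi = self.lesion_size_range
        if lo < 4 or hi < lo:
            raise ConfigurationError("invalid lesion_size_range")
        if hi >= min(self.image_height, self.image_width):
            raise ConfigurationError("lesions must fit inside the image")
        if self.views_per_breast < 1:
            raise ConfigurationError("views_per_breast must be >= 1")
        if self.platform not in ("A", "B"):
            raise ConfigurationError("platform must be 'A' or 'B'")

    @classmethod
    def desk_scale(cls, n_patients: int = 100, seed: int = 0, **kw) -> "SyntheticConfig":
        """CPU-scale study conditions: 1/8-size frames with proportionally
        smaller lesions, matched to a 32-pixel patch size downstream."""
        return cls(image_height=144, image_width=112, n_patients=n_patients,
                   lesion_size_range=(14, 28), seed=seed, **kw)


@dataclass
class ScreenImage:
    pixels: np.ndarray              # float32 (r, s), values in [0, PIXEL_MAX]
    patient_id: str
    view: str
    platform: str = "A"
    label: str = "nonmalignant"     # 'malignant' | 'nonmalignant'
    image_id: str = ""
    breast_id: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if not self.image_id:
            self.image_id = f"{self.patient_id}_{self.view}"
        if not self.breast_id:
            self.breast_id = self.patient_id  # one breast per synthetic patient


@dataclass
class RoiAnnotation:
    mask: np.ndarray                # bool (r, s)
    lesion_class: str

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.lesion_class not in LESION_CLASSES:
            raise ConfigurationError(f"unknown lesion class {self.lesion_class!r}")
        if not self.mask.any():
            raise ConfigurationError("ROI mask has no foreground pixels")

    @property
    def bounding_box(self) -> tuple[int, int, int, int]:
        """Tight (row, col, height, width) box of the mask, half-open."""
        rows = np.flatnonzero(self.mask.any(axis=1))
        cols = np.flatnonzero(self.mask.any(axis=0))
        return (int(rows[0]), int(cols[0]),
                int(rows[-1] - rows[0] + 1), int(cols[-1] - cols[0] + 1))

    @property
    def is_malignant(self) -> bool:
        return self.lesion_class.startswith("malignant")


# ---------------------------------------------------------------------------
# Lesion painting

def _disk_coords(size: int):
    r = size / 2.0
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float32)
    yy -= (size - 1) / 2.0
    xx -= (size - 1) / 2.0
    rad = np.sqrt(yy * yy + xx * xx)
    return yy, xx, rad, r


def _mass_texture(size, amplitude, rng, spicules=0):
    yy, xx, rad, r = _disk_coords(size)
    ecc = rng.uniform(0.75, 1.0)
    theta = rng.uniform(0, np.pi)
    u = np.cos(theta) * xx + np.sin(theta) * yy
    v = -np.sin(theta) * xx + np.cos(theta) * yy
    rr = np.sqrt((u / ecc) ** 2 + v ** 2)
    sigma = r * rng.uniform(0.35, 0.5)
    tex = amplitude * np.exp(-0.5 * (rr / sigma) ** 2)
    if spicules:
        ang = np.arctan2(yy, xx)
        phases = rng.uniform(0, 2 * np.pi, size=spicules)
        widths = rng.uniform(0.05, 0.10, size=spicules)
        spic = np.zeros_like(tex)
        for p, wdt in zip(phases, widths):
            d = np.angle(np.exp(1j * (ang - p)))
            spic += np.exp(-0.5 * (d / wdt) ** 2) * np.exp(-rad / (0.6 * r))
        tex += 0.55 * amplitude * np.clip(spic, 0, 1.2)
    tex[rad > r] = 0.0
    return tex


def _calc_texture(size, amplitude, rng, malignant, cfg: SyntheticConfig):
    yy, xx, rad, r = _disk_coords(size)
    counts = (cfg.malignant_dot_count_range if malignant
              else cfg.benign_dot_count_range)
    n_dots = int(rng.integers(counts[0], counts[1] + 1))
    # faint halo over the cluster extent keeps the ROI mask a solid region
    tex = 0.06 * amplitude * np.clip(1.0 - rad / r, 0, 1)
    for _ in range(n_dots):
        rho = r * np.sqrt(rng.uniform(0, 0.75))
        phi = rng.uniform(0, 2 * np.pi)
        cy, cx = rho * np.sin(phi), rho * np.cos(phi)
        if malignant:  # finer, pleomorphic: broad spread of small sizes
            dr = max(size / 28.0 * rng.uniform(0.4, 1.6), 0.8)
            amp = amplitude * rng.uniform(0.8, 1.8)
        else:          # fewer, larger, uniform round dots
            dr = max(size / 12.0 * rng.uniform(0.9, 1.1), 1.2)
            amp = amplitude * rng.uniform(0.9, 1.1)
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        tex += amp * np.exp(-0.5 * d2 / (dr / 2.0) ** 2)
    tex[rad > r] = 0.0
    return tex


def implant_lesion(image: ScreenImage, lesion_class: str,
                   center: tuple[int, int], size: int,
                   rng: np.random.Generator,
                   config: SyntheticConfig | None = None,
                   ) -> tuple[ScreenImage, RoiAnnotation]:
    """Paint one lesion; the mask covers exactly the modified pixels.

    The added texture is strictly positive inside its footprint, so the mean
    intensity inside the mask exceeds that of an equal-area surrounding
    annulus by construction.
    """
    cfg = config or SyntheticConfig()
    if lesion_class not in LESION_CLASSES:
        raise ConfigurationError(f"unknown lesion class {lesion_class!r}")
    h, w = image.pixels.shape
    size = int(size)
    half = size // 2
    r0, c0 = int(center[0]) - half, int(center[1]) - half
    if r0 < 0 or c0 < 0 or r0 + size > h or c0 + size > w:
        raise PlacementError(
            f"lesion of size {size} at {center} does not fit in {h}x{w}")
    amp = 9000.0 * rng.uniform(0.8, 1.2)
    if lesion_class == "benign_mass":
        tex = _mass_texture(size, amp, rng, spicules=0)
    elif lesion_class == "malignant_mass":
        tex = _mass_texture(size, amp, rng, spicules=int(
            rng.integers(cfg.spicule_count_range[0],
                         cfg.spicule_count_range[1] + 1)))
    else:
        tex = _calc_texture(size, 1.6 * amp, rng,
                            malignant=lesion_class == "malignant_calc",
                            cfg=cfg)
    footprint = tex > (0.01 * amp)
    tex = tex * footprint
    pixels = image.pixels.copy()
    pixels[r0:r0 + size, c0:c0 + size] = np.clip(
        pixels[r0:r0 + size, c0:c0 + size] + tex, 0, PIXEL_MAX)
    mask = np.zeros((h, w), dtype=bool)
    mask[r0:r0 + size, c0:c0 + size] = footprint
    out = replace(image, pixels=pixels)
    return out, RoiAnnotation(mask=mask, lesion_class=lesion_class)


# ---------------------------------------------------------------------------
# Background and platform shift

def _background(h, w, rng):
    base = rng.uniform(18000, 26000)
    coarse = rng.normal(0, 1, (max(h // 32, 2), max(w // 32, 2)))
    coarse = ndimage.zoom(coarse, (h / coarse.shape[0], w / coarse.shape[1]),
                          order=1)
    tissue = 2500.0 * ndimage.gaussian_filter(coarse, 3)
    gy = rng.uniform(-3000, 3000) * np.linspace(0, 1, h)[:, None]
    gx = rng.uniform(-3000, 3000) * np.linspace(0, 1, w)[None, :]
    noise = ndimage.gaussian_filter(rng.normal(0, 900, (h, w)), 1.5)
    return np.clip(base + tissue + gy + gx + noise, 0, PIXEL_MAX).astype(np.float32)


def gamma_profile(gamma: float = 0.35, gain: float = 1.0):
    """A monotone gamma-like intensity map (brightening, highlight
    compression); one of the two stock platform profiles."""
    def profile(x):
        return np.clip(gain * PIXEL_MAX * (np.asarray(x) / PIXEL_MAX) ** gamma,
                       0, PIXEL_MAX)
    return profile


def film_shoulder_profile(knee: float = 26000.0, slope: float = 0.15,
                          fog: float = 6000.0):
    """The default platform-B intensity map: film-like response with a
    saturation shoulder and base fog.

    Linear below the knee, strongly compressed (slope << 1) above it —
    mimicking how a film characteristic curve flattens in its shoulder so
    bright structures (lesions) lose most of their contrast — plus a
    constant fog offset lifting the floor. Monotone nondecreasing, so pixel
    ranks are preserved while the usable contrast of implanted lesions is
    sharply reduced; this is what makes zero-shot transfer across platforms
    genuinely degrade."""
    def profile(x):
        x = np.asarray(x, dtype=np.float64)
        out = np.where(x < knee, x, knee + slope * (x - knee))
        return np.clip(out + fog, 0, PIXEL_MAX)
    return profile


def platform_shift(image: ScreenImage, profile, new_platform: str = "B") -> ScreenImage:
    """Apply a monotone intensity map; pixel ranks (and ROI geometry) are
    preserved, only the histogram moves."""
    grid = np.linspace(0, PIXEL_MAX, 2049)
    vals = np.asarray(profile(grid), dtype=np.float64)
    if np.any(np.diff(vals) < -1e-6):
        raise ConfigurationError("intensity profile must be monotone nondecreasing")
    out = np.asarray(profile(image.pixels), dtype=np.float32)
    return replace(image, pixels=np.clip(out, 0, PIXEL_MAX),
                   platform=new_platform)


# ---------------------------------------------------------------------------
# Cohort generation

def _lesion_plan(malignant: bool, cfg: SyntheticConfig, rng) -> list[str]:
    if malignant:
        classes = [str(rng.choice(["malignant_calc", "malignant_mass"]))]
        if rng.uniform() < 0.3:
            classes.append(str(rng.choice(["benign_calc", "benign_mass"])))
        return classes
    if rng.uniform() < cfg.benign_lesion_prob:
        return [str(rng.choice(["benign_calc", "benign_mass"]))]
    return []


def generate_cohort(config: SyntheticConfig
                    ) -> list[tuple[ScreenImage, list[RoiAnnotation]]]:
    """Generate a seeded cohort: one breast per patient, `views_per_breast`
    images per breast, the same lesion list re-implanted (jittered) in each
    view. Deterministic under `config.seed`; an image is labeled malignant
    iff it carries at least one malignant ROI."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    h, w = config.image_height, config.image_width
    n_mal = int(round(config.n_patients * config.malignant_fraction))
    statuses = np.zeros(config.n_patients, dtype=bool)
    statuses[:n_mal] = True
    statuses = statuses[rng.permutation(config.n_patients)]

    cohort: list[tuple[ScreenImage, list[RoiAnnotation]]] = []
    for pi, malignant in enumerate(statuses):
        pid = f"P{pi:04d}"
        classes = _lesion_plan(bool(malignant), config, rng)
        lo, hi = config.lesion_size_range
        plan = []
        for cls in classes:
            size = int(rng.integers(lo, hi + 1))
            margin = size // 2 + 4
            cy = int(rng.integers(margin, h - margin))
            cx = int(rng.integers(margin, w - margin))
            plan.append((cls, (cy, cx), size))
        for vi in range(config.views_per_breast):
            view = VIEWS[vi] if vi < len(VIEWS) else f"V{vi}"
            img = ScreenImage(pixels=_background(h, w, rng), patient_id=pid,
                              view=view, platform="A")
            rois: list[RoiAnnotation] = []
            for cls, (cy, cx), size in plan:
                jy = int(rng.normal(0, config.view_jitter_frac * h))
                jx = int(rng.normal(0, config.view_jitter_frac * w))
                s = int(np.clip(size * rng.uniform(0.9, 1.1), lo, hi))
                m = s // 2 + 4
                cyj = int(np.clip(cy + jy, m, h - m))
                cxj = int(np.clip(cx + jx, m, w - m))
                img, roi = implant_lesion(img, cls, (cyj, cxj), s, rng,
                                          config=config)
                rois.append(roi)
            img.label = ("malignant" if any(r.is_malignant for r in rois)
                         else "nonmalignant")
            if config.platform == "B":
                img = platform_shift(img, film_shoulder_profile(),
                                     new_platform="B")
            cohort.append((img, rois))
    return cohort


# ---------------------------------------------------------------------------
# On-disk layout: 16-bit PNG images, 8-bit 0/255 masks, CSV manifest

def write_cohort(cohort, outdir) -> pd.DataFrame:
    from pathlib import Path

    from PIL import Image

    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    (outdir / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for img, rois in cohort:
        ipath = outdir / "images" / f"{img.image_id}.png"
        Image.fromarray(np.round(img.pixels).astype(np.uint16)).save(ipath)
        rpaths, rclasses = [], []
        for ri, roi in enumerate(rois):
            mpath = outdir / "masks" / f"{img.image_id}_roi{ri}.png"
            Image.fromarray((roi.mask * np.uint8(255))).save(mpath)
            rpaths.append(str(mpath.relative_to(outdir)))
            rclasses.append(roi.lesion_class)
        rows.append({"image_path": str(ipath.relative_to(outdir)),
                     "patient_id": img.patient_id, "view": img.view,
                     "platform": img.platform, "label": img.label,
                     "roi_paths": ";".join(rpaths),
                     "roi_classes": ";".join(rclasses)})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return manifest
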