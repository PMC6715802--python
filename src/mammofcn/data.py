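"""Dataset I/O, label mapping and patient-level splits.

Images are 8/16-bit grayscale PNG (DICOM read supported); every cohort is
described by a CSV manifest with one row per image (image_path, patient_id,
view, platform, label, optional roi_paths/roi_classes separated by ';').
Whole images are downsized to a fixed frame (default 1152 x 896) by
interpolation with no cropping, so aspect distortion is permitted. BI-RADS
assessment categories can stand in for pathology labels: 1-2 negative,
4-6 positive, 3 excluded. Splits are patient-level and label-stratified.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.transform import resize as _resize

from .synthetic import PIXEL_MAX, RoiAnnotation, ScreenImage

log = logging.getLogger(__name__)

TARGET_SIZE = (1152, 896)


class ImageIOError(IOError):
    pass


class SplitError(ValueError):
    pass


def _read_gray(path: Path) -> np.ndarray:
    if path.suffix.lower() in (".dcm", ".dicom"):
        try:
            import pydicom
            ds = pydicom.dcmread(str(path))
            return np.asarray(ds.pixel_array, dtype=np.float32)
        except Exception as exc:
            raise ImageIOError(f"cannot read DICOM {path}: {exc}") from exc
    try:
        from PIL import Image
        with Image.open(path) as im:
            arr = np.asarray(im)
    except Exception as exc:
        raise ImageIOError(f"cannot read image {path}: {exc}") from exc
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=2)
    return arr.astype(np.float32)


def load_and_resize(path, target_size: tuple[int, int] = TARGET_SIZE,
                    patient_id: str = "", view: str = "CC",
                    platform: str = "A", label: str = "nonmalignant",
                    order: int = 1) -> ScreenImage:
    """Read a grayscale PNG/DICOM and interpolate it to exactly
    `target_size` (no cropping or padding; aspect distortion allowed).
    Bilinear interpolation by default. An image already at the target size
    passes through unchanged."""
    path = Path(path)
    arr = _read_gray(path)
    orig_depth = 16 if arr.max() > 255 else 8
    if arr.shape != tuple(target_size):
        arr = _resize(arr, target_size, order=order, preserve_range=True,
                      anti_aliasing=arr.shape[0] > target_size[0])
    img = ScreenImage(pixels=np.clip(arr, 0, PIXEL_MAX), patient_id=patient_id,
                      view=view, platform=platform, label=label,
                      image_id=path.stem)
    img.bit_depth = orig_depth
    return img


def load_mask(path) -> np.ndarray:
    arr = _read_gray(Path(path))
    return arr > (arr.max() / 2 if arr.max() > 0 else 0.5)


def map_birads(category: int) -> str:
    """BI-RADS assessment to screening label: 1-2 negative, 4-6 positive,
    3 excluded (not a screening assessment). Category 0 (incomplete exam)
    is excluded with a warning since no label can be derived from it."""
    category = int(category)
    if not 0 <= category <= 6:
        raise ValueError(f"BI-RADS category {category} out of range 0-6")
    if category in (1, 2):
        return "negative"
    if category in (4, 5, 6):
        return "positive"
    if category == 0:
        warnings.warn("BI-RADS 0 (incomplete exam) excluded: no label can "
                      "be derived", stacklevel=2)
    return "excluded"


# ---------------------------------------------------------------------------
# Manifests and splits

def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str}, keep_default_na=False)
    if (df["patient_id"] == "").any():
        raise ValueError("manifest has empty patient ids")
    return df


def write_manifest(df: pd.DataFrame, path):
    df.to_csv(path, index=False)


def _positive(series: pd.Series) -> pd.Series:
    return series.isin(["malignant", "positive", "1", 1, True])


def split_patients(manifest: pd.DataFrame, ratios,
                   stratify_by_label: bool = True, seed: int = 0,
                   split_names: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Tag each manifest row with a split, keeping all images of a patient
    together and (optionally) stratifying by patient-level label so each
    split's positive proportion tracks the cohort's."""
    ratios = np.asarray(ratios, dtype=float)
    if not np.isclose(ratios.sum(), 1.0):
        raise SplitError(f"ratios {ratios.tolist()} do not sum to 1")
    n_splits = len(ratios)
    if split_names is None:
        split_names = {1: ("train",), 2: ("train", "test"),
                       3: ("train", "val", "test")}.get(
            n_splits, tuple(f"split{i}" for i in range(n_splits)))
    rng = np.random.default_rng(seed)
    pat = (manifest.assign(_pos=_positive(manifest["label"]))
           .groupby("patient_id")["_pos"].max())
    strata = ([pat[pat].index.to_numpy(), pat[~pat].index.to_numpy()]
              if stratify_by_label else [pat.index.to_numpy()])
    assignment: dict[str, str] = {}
    carry = np.zeros(n_splits)
    for stratum in strata:
        if len(stratum) == 0:
            continue
        if stratify_by_label and len(stratum) < n_splits:
            raise SplitError("a label stratum has fewer patients than splits")
        stratum = stratum[rng.permutation(len(stratum))]
        # largest-remainder apportionment, carrying rounding error across
        # strata so the overall split sizes honor the ratios exactly
        quotas = ratios * len(stratum) + carry
        base = np.floor(quotas).astype(int)
        rem = len(stratum) - base.sum()
        order = np.argsort(-(quotas - base))
        base[order[:rem]] += 1
        carry = quotas - base
        start = 0
        for name, k in zip(split_names, base):
            for pid in stratum[start:start + k]:
                assignment[pid] = name
            start += k
    out = manifest.copy()
    out["split"] = out["patient_id"].map(assignment)
    return out


def cohort_to_arrays(cohort, meta_platform: str | None = None
                     ) -> tuple[np.ndarray, pd.DataFrame]:
    """Stack a generated cohort into an (N,1,H,W) array and a metadata
    frame with PredictionSet-compatible columns."""
    images = np.stack([img.pixels for img, _ in cohort])[:, None]
    meta = pd.DataFrame({
        "image_id": [img.image_id for img, _ in cohort],
        "patient_id": [img.patient_id for img, _ in cohort],
        "breast_id": [img.breast_id for img, _ in cohort],
        "view": [img.view for img, _ in cohort],
        "platform": [meta_platform or img.platform for img, _ in cohort],
        "label": [int(img.label == "malignant") for img, _ in cohort],
    })
    return images.astype(np.float32), meta


def load_cohort(root) -> list[tuple[ScreenImage, list[RoiAnnotation]]]:
    """Round-trip loader for a directory written by synthetic.write_cohort."""
    root = Path(root)
    manifest = read_manifest(root / "manifest.csv")
    cohort = []
    for _, row in manifest.iterrows():
        arr = _read_gray(root / row["image_path"])
        img = ScreenImage(pixels=arr, patient_id=row["patient_id"],
                          view=row["view"], platform=row["platform"],
                          label=row["label"],
                          image_id=Path(row["image_path"]).stem)
        rois = []
        rp = str(row.get("roi_paths", "") or "")
        rc = str(row.get("roi_classes", "") or "")
        if rp:
            for mpath, cls in zip(rp.split(";"), rc.split(";")):
                rois.append(RoiAnnotation(mask=load_mask(root / mpath),
                                          lesion_class=cls))
        cohort.append((img, rois))
    return cohort
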