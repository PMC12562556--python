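"""Grade rules, dataset manifests, leakage-safe splits, augmentation, annotation IO.

Grading of *Stropharia rugoso-annulata* uses two morphological ratios:

* **RDHP** — cap diameter / cap height;
* **RLDS** — stalk length / stalk diameter.

First Grade: RDHP 1.5–2.5, RLDS 0–1.5; Second Grade: RDHP 1.0–1.5,
RLDS 1.5–2.5; Third Grade: RDHP 0–1.0, RLDS > 2.5. When the two ratios point
to different grades, RLDS prevails. Intervals are half-open ``[lo, hi)`` with
the last RLDS interval unbounded above, so the RLDS ranges partition (0, inf)
and every specimen receives a grade.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger("wavedetr")

__all__ = [
    "GRADE_LABELS",
    "GRADE_IDS",
    "GradeRule",
    "GRADE_RULES",
    "assign_grade",
    "ManifestRecord",
    "DatasetManifest",
    "split_dataset",
    "augment",
    "AugmentConfig",
    "read_labelme",
    "write_coco",
    "read_coco",
]

# Frozen label order; ids 1/2/3 are written into every COCO file.
GRADE_LABELS = ("Autumn_First_Grade", "Autumn_Second_Grade", "Autumn_Third_Grade")
GRADE_IDS = {label: i + 1 for i, label in enumerate(GRADE_LABELS)}


@dataclass(frozen=True)
class GradeRule:
    label: str
    rdhp_range: tuple[float, float]  # [lo, hi)
    rlds_range: tuple[float, float]  # [lo, hi); hi may be inf


GRADE_RULES = (
    GradeRule("Autumn_First_Grade", (1.5, 2.5), (0.0, 1.5)),
    GradeRule("Autumn_Second_Grade", (1.0, 1.5), (1.5, 2.5)),
    GradeRule("Autumn_Third_Grade", (0.0, 1.0), (2.5, math.inf)),
)


def _grade_by(value: float, key: str) -> str | None:
    for rule in GRADE_RULES:
        lo, hi = getattr(rule, key)
        if lo <= value < hi:
            return rule.label
    return None


def assign_grade(rdhp: float, rlds: float) -> str:
    """Grade a specimen from its two ratios; RLDS prevails on any conflict.

    RDHP values outside every listed range (e.g. > 2.5) defer entirely to
    RLDS. Because the RLDS intervals partition (0, inf), the result is total.
    """
    if not (rdhp > 0):
        raise ValueError(f"rdhp must be > 0, got {rdhp}")
    if rlds < 0:
        raise ValueError(f"rlds must be >= 0, got {rlds}")
    by_rdhp = _grade_by(rdhp, "rdhp_range")
    by_rlds = _grade_by(rlds, "rlds_range")
    assert by_rlds is not None  # RLDS ranges cover [0, inf)
    if by_rdhp is None or by_rdhp != by_rlds:
        return by_rlds
    return by_rdhp


# --- manifests and splits ----------------------------------------------------


@dataclass
class ManifestRecord:
    image_path: str
    origin_id: str
    annotations: list[dict] = field(default_factory=list)  # {bbox: [x0,y0,x1,y1], label}
    split: str = "unassigned"
    width: int = 0
    height: int = 0

    def to_dict(self) -> dict:
        return {
            "image_path": self.image_path,
            "origin_id": self.origin_id,
            "annotations": self.annotations,
            "split": self.split,
            "width": self.width,
            "height": self.height,
        }


@dataclass
class DatasetManifest:
    records: list[ManifestRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def split_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in self.records:
            counts[r.split] = counts.get(r.split, 0) + 1
        return counts

    def save(self, path: str | Path) -> None:
        payload = {"records": [r.to_dict() for r in self.records]}
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "DatasetManifest":
        payload = json.loads(Path(path).read_text())
        return cls(records=[ManifestRecord(**r) for r in payload["records"]])


def split_dataset(
    manifest: DatasetManifest,
    ratio: tuple[int, int, int] = (8, 1, 1),
    seed: int = 0,
) -> DatasetManifest:
    """Assign train/val/test splits, leakage-safe by origin image.

    Origin ids are shuffled with ``seed`` and assigned greedily so that the
    cumulative *record* counts reach floor(N*8/10) train and floor(N*1/10)
    val, the remainder test (9170 single-variant records -> 7336/917/917).
    Every augmented variant follows its origin, so no origin spans two splits.
    """
    if any(r <= 0 for r in ratio):
        raise ValueError("ratio parts must be positive")
    by_origin: dict[str, list[ManifestRecord]] = {}
    for rec in manifest.records:
        by_origin.setdefault(rec.origin_id, []).append(rec)
    origins = sorted(by_origin)
    if len(origins) < 3:
        raise ValueError("need at least as many origins as splits")
    rng = np.random.default_rng(seed)
    rng.shuffle(origins)

    n = len(manifest.records)
    total = sum(ratio)
    train_target = (n * ratio[0]) // total
    val_target = (n * ratio[1]) // total

    assigned = 0
    for origin in origins:
        if assigned < train_target:
            split = "train"
        elif assigned < train_target + val_target:
            split = "val"
        else:
            split = "test"
        for rec in by_origin[origin]:
            rec.split = split
        assigned += len(by_origin[origin])
    counts = manifest.split_counts()
    logger.info("split counts: %s", counts)
    return manifest


# --- augmentation ------------------------------------------------------------


@dataclass(frozen=True)
class AugmentConfig:
    """The study's augmentation suite with its stated parameter ranges."""

    rotation_deg: float = 15.0          # uniform in [-15, 15]
    scale_range: tuple[float, float] = (0.9, 1.1)
    brightness: float = 0.2             # multiplicative, uniform in [-20%, +20%]
    noise_sigma_max: float = 0.01       # Gaussian sigma on [0, 1] intensity scale
    hflip_prob: float = 0.5


def _rotate_boxes(boxes: np.ndarray, angle_deg: float, cx: float, cy: float) -> np.ndarray:
    """Axis-aligned hull of each box's rotated corners (image-coords rotation)."""
    theta = math.radians(angle_deg)
    c, s = math.cos(theta), math.sin(theta)
    out = np.empty_like(boxes, dtype=np.float64)
    for i, (x0, y0, x1, y1) in enumerate(boxes):
        xs = np.array([x0, x1, x1, x0]) - cx
        ys = np.array([y0, y0, y1, y1]) - cy
        xr = c * xs + s * ys + cx
        yr = -s * xs + c * ys + cy
        out[i] = [xr.min(), yr.min(), xr.max(), yr.max()]
    return out


def augment(
    image: np.ndarray,
    boxes: np.ndarray,
    cfg: AugmentConfig = AugmentConfig(),
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Apply one random draw of the augmentation suite.

    Geometric ops (rotation, scale about the center, horizontal flip)
    transform the boxes consistently; photometric ops (brightness, Gaussian
    noise) leave them unchanged. Boxes that collapse below 2 px on a side
    after clipping are dropped (a warning is logged).

    Returns ``(image', boxes', keep_mask)`` with the image in float [0, 1].
    """
    from skimage.transform import rotate as sk_rotate, rescale as sk_rescale

    rng = rng or np.random.default_rng()
    img = np.asarray(image, dtype=np.float64)
    if img.max() > 1.5:
        img = img / 255.0
    h, w = img.shape[:2]
    boxes = np.asarray(boxes, dtype=np.float64).reshape(-1, 4).copy()

    angle = rng.uniform(-cfg.rotation_deg, cfg.rotation_deg)
    scale = rng.uniform(*cfg.scale_range)
    bright = rng.uniform(-cfg.brightness, cfg.brightness)
    sigma = rng.uniform(0.0, cfg.noise_sigma_max)
    flip = rng.random() < cfg.hflip_prob

    # rotation (counter-clockwise, about the center, same output shape)
    if angle != 0.0:
        img = sk_rotate(img, angle, resize=False, mode="edge", preserve_range=True)
        boxes = _rotate_boxes(boxes, angle, (w - 1) / 2.0, (h - 1) / 2.0)

    # isotropic scale about the center, re-cropped/padded to the input shape
    if scale != 1.0:
        scaled = sk_rescale(img, scale, channel_axis=-1 if img.ndim == 3 else None,
                            preserve_range=True, anti_aliasing=scale < 1.0)
        sh, sw = scaled.shape[:2]
        canvas = np.zeros_like(img)
        y0, x0 = (h - sh) // 2, (w - sw) // 2
        sy0, sx0 = max(0, -y0), max(0, -x0)
        y0, x0 = max(0, y0), max(0, x0)
        ch, cw = min(h - y0, sh - sy0), min(w - x0, sw - sx0)
        canvas[y0:y0 + ch, x0:x0 + cw] = scaled[sy0:sy0 + ch, sx0:sx0 + cw]
        img = canvas
        cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
        boxes[:, [0, 2]] = (boxes[:, [0, 2]] - cx) * scale + cx
        boxes[:, [1, 3]] = (boxes[:, [1, 3]] - cy) * scale + cy

    if flip:
        img = img[:, ::-1].copy()
        x0s, x1s = boxes[:, 0].copy(), boxes[:, 2].copy()
        boxes[:, 0] = w - x1s
        boxes[:, 2] = w - x0s

    img = np.clip(img * (1.0 + bright), 0.0, 1.0)
    if sigma > 0:
        img = np.clip(img + rng.normal(0.0, sigma, img.shape), 0.0, 1.0)

    boxes[:, [0, 2]] = np.clip(boxes[:, [0, 2]], 0, w)
    boxes[:, [1, 3]] = np.clip(boxes[:, [1, 3]], 0, h)
    keep = (boxes[:, 2] - boxes[:, 0] >= 2) & (boxes[:, 3] - boxes[:, 1] >= 2)
    if not keep.all():
        logger.warning("dropping %d degenerate box(es) after augmentation",
                       int((~keep).sum()))
    return img, boxes[keep], keep


# --- annotation formats ------------------------------------------------------


def read_labelme(path: str | Path, strict: bool = True) -> dict:
    """Parse a LabelMe JSON file into {width, height, annotations}.

    Only rectangle shapes with the three grade labels are accepted; other
    shapes or labels raise in strict mode and are skipped with a warning
    otherwise.
    """
    data = json.loads(Path(path).read_text())
    anns = []
    for shape in data.get("shapes", []):
        label = shape.get("label")
        if shape.get("shape_type") != "rectangle":
            msg = f"non-rectangle shape {shape.get('shape_type')!r} (label {label!r}) in {path}"
            if strict:
                raise ValueError(msg)
            logger.warning("skipping %s", msg)
            continue
        if label not in GRADE_IDS:
            msg = f"unknown label {label!r} in {path}"
            if strict:
                raise ValueError(msg)
            logger.warning("skipping %s", msg)
            continue
        (xa, ya), (xb, yb) = shape["points"]
        anns.append({
            "bbox": [min(xa, xb), min(ya, yb), max(xa, xb), max(ya, yb)],
            "label": label,
        })
    return {
        "width": data.get("imageWidth", 0),
        "height": data.get("imageHeight", 0),
        "image_path": data.get("imagePath", ""),
        "annotations": anns,
    }


def write_coco(manifest: DatasetManifest, path: str | Path) -> None:
    """Serialize a manifest to COCO detection JSON (xywh boxes, ids 1..3)."""
    images, annotations = [], []
    ann_id = 1
    for img_id, rec in enumerate(manifest.records, start=1):
        images.append({
            "id": img_id,
            "file_name": rec.image_path,
            "width": rec.width,
            "height": rec.height,
        })
        for ann in rec.annotations:
            x0, y0, x1, y1 = ann["bbox"]
            annotations.append({
                "id": ann_id,
                "image_id": img_id,
                "category_id": GRADE_IDS[ann["label"]],
                "bbox": [x0, y0, x1 - x0, y1 - y0],
                "area": (x1 - x0) * (y1 - y0),
                "iscrowd": 0,
            })
            ann_id += 1
    payload = {
        "images": images,
        "annotations": annotations,
        "categories": [
            {"id": i, "name": label} for label, i in GRADE_IDS.items()
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_coco(path: str | Path) -> DatasetManifest:
    """Inverse of :func:`write_coco` (origin ids default to the file name)."""
    payload = json.loads(Path(path).read_text())
    id_to_label = {c["id"]: c["name"] for c in payload["categories"]}
    recs: dict[int, ManifestRecord] = {}
    for img in payload["images"]:
        recs[img["id"]] = ManifestRecord(
            image_path=img["file_name"],
            origin_id=img["file_name"],
            width=img.get("width", 0),
            height=img.get("height", 0),
        )
    for ann in payload["annotations"]:
        x, y, bw, bh = ann["bbox"]
        recs[ann["image_id"]].annotations.append({
            "bbox": [x, y, x + bw, y + bh],
            "label": id_to_label[ann["category_id"]],
        })
    return DatasetManifest(records=[recs[i] for i in sorted(recs)])
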