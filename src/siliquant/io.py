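"""Reading and writing instance annotations, manifests, and trait tables.

Two instance dialects are supported:

* ``coco_json`` — a COCO instance file (``images``/``annotations``/
  ``categories``, or a bare list of result records).  Polygon, list-RLE
  and compressed-string-RLE segmentations are all accepted.
* ``mask_folder`` — one binary PNG per instance under
  ``<image_id>/<instance_id>.png`` with a ``metadata.json`` sidecar.
  This layout keeps overlapping (amodal) instances as independent
  rasters; a single label image could not express the overlap.

Manifests and trait tables are RFC-4180 CSV, read and written with pandas.
"""

from __future__ import annotations

import json
import math
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage.draw import polygon as sk_polygon

from . import _rle
from .datatypes import (
    DEFAULT_DPI,
    InstanceMask,
    ParseError,
    SampleMeta,
    SiliqueTraits,
    TraitRecord,
    ValidationError,
)

MASK_FOLDER_VERSION = "1"

TRAIT_COLUMNS = [
    "instance_id",
    "image_id",
    "sample_id",
    "qc_status",
    "qc_reason",
    "SA_mm2",
    "SL_mm",
    "SD_mm",
    "SV_mm3",
    "dpi",
]

MANIFEST_COLUMNS = [
    "sample_id",
    "genotype",
    "treatment",
    "batch",
    "dpi",
    "images",
    "excluded",
    "exclusion_reason",
]


# ---------------------------------------------------------------------------
# instance reading
# ---------------------------------------------------------------------------

def read_instances(path, dialect: str) -> list[InstanceMask]:
    """Read per-instance masks from ``path`` in the given dialect.

    Returns one :class:`InstanceMask` per annotated/predicted object.
    Overlapping pixels are preserved on every instance that claims them.
    Instances with zero foreground pixels are dropped with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "coco_json":
        instances = _read_coco(path)
    elif dialect == "mask_folder":
        instances = _read_mask_folder(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    kept = []
    for inst in instances:
        if inst.is_empty():
            warnings.warn(
                f"instance {inst.instance_id} on image {inst.image_id} has no "
                "foreground pixels; rejected",
                stacklevel=2,
            )
            continue
        kept.append(inst)
    return kept


def _read_coco(path: Path) -> list[InstanceMask]:
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: malformed JSON ({exc})") from exc

    if isinstance(doc, dict):
        annotations = doc.get("annotations", [])
        images = {img["id"]: img for img in doc.get("images", [])}
        categories = {c["id"]: c.get("name", "silique") for c in doc.get("categories", [])}
    else:  # bare results list
        annotations = doc
        images, categories = {}, {}

    out = []
    for ann in annotations:
        try:
            out.append(_coco_annotation_to_instance(ann, images, categories))
        except (KeyError, TypeError, ValueError) as exc:
            ann_id = ann.get("id", "<missing id>") if isinstance(ann, dict) else ann
            raise ParseError(f"{path}: bad annotation {ann_id}: {exc}") from exc
    return out


def _coco_annotation_to_instance(ann, images, categories) -> InstanceMask:
    seg = ann["segmentation"]
    image_id = ann["image_id"]
    if isinstance(seg, dict):  # RLE
        mask = _rle.decode(seg)
    else:  # polygon(s): list of flat [x0, y0, x1, y1, ...]
        img = images.get(image_id)
        if img is None:
            raise ValueError("polygon segmentation requires image height/width")
        mask = np.zeros((img["height"], img["width"]), dtype=bool)
        for poly in seg:
            pts = np.asarray(poly, dtype=float).reshape(-1, 2)
            rr, cc = sk_polygon(pts[:, 1], pts[:, 0], shape=mask.shape)
            mask[rr, cc] = True
    bbox = tuple(ann["bbox"]) if "bbox" in ann else None
    cat = categories.get(ann.get("category_id"), ann.get("category", "silique"))
    return InstanceMask(
        instance_id=str(ann.get("id", f"{image_id}:{len(images)}")),
        image_id=str(image_id),
        mask=mask,
        bbox=bbox,
        score=float(ann.get("score", 1.0)),
        category=cat,
    )


def _read_mask_folder(path: Path) -> list[InstanceMask]:
    meta_path = path / "metadata.json"
    if not meta_path.exists():
        raise ParseError(f"{path}: missing metadata.json sidecar")
    try:
        with open(meta_path) as fh:
            meta = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ParseError(f"{meta_path}: malformed JSON ({exc})") from exc

    out = []
    for rec in meta.get("instances", []):
        png = path / str(rec["image_id"]) / f"{rec['instance_id']}.png"
        try:
            raster = np.asarray(Image.open(png))
        except OSError as exc:
            raise ParseError(f"unreadable mask raster {png}: {exc}") from exc
        out.append(
            InstanceMask(
                instance_id=str(rec["instance_id"]),
                image_id=str(rec["image_id"]),
                mask=raster > 0,
                score=float(rec.get("score", 1.0)),
                category=rec.get("category", "silique"),
            )
        )
    return out


# ---------------------------------------------------------------------------
# instance writing
# ---------------------------------------------------------------------------

def write_instances(instances: list[InstanceMask], path, dialect: str) -> None:
    """Write instances in the ``coco_json`` or ``mask_folder`` dialect."""
    path = Path(path)
    if dialect == "coco_json":
        _write_coco(instances, path)
    elif dialect == "mask_folder":
        _write_mask_folder(instances, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def to_coco_dict(instances: list[InstanceMask]) -> dict:
    """Assemble a COCO instance document (RLE segmentations) in memory."""
    images = {}
    annotations = []
    for i, inst in enumerate(instances, start=1):
        h, w = inst.mask.shape
        images.setdefault(inst.image_id, {"id": inst.image_id, "height": h, "width": w})
        annotations.append(
            {
                "id": inst.instance_id,
                "image_id": inst.image_id,
                "category_id": 1,
                "segmentation": _rle.encode(inst.mask),
                "bbox": [float(v) for v in inst.bbox],
                "area": inst.n_pixels,
                "score": float(inst.score),
                "iscrowd": 0,
            }
        )
    return {
        "images": list(images.values()),
        "annotations": annotations,
        "categories": [{"id": 1, "name": "silique"}],
    }


def _write_coco(instances, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(to_coco_dict(instances), fh)


def _write_mask_folder(instances, path: Path) -> None:
    path.mkdir(parents=True, exist_ok=True)
    records = []
    for inst in instances:
        img_dir = path / inst.image_id
        img_dir.mkdir(exist_ok=True)
        Image.fromarray(inst.mask.astype(np.uint8) * 255).save(
            img_dir / f"{inst.instance_id}.png"
        )
        records.append(
            {
                "image_id": inst.image_id,
                "instance_id": inst.instance_id,
                "category": inst.category,
                "score": float(inst.score),
            }
        )
    with open(path / "metadata.json", "w") as fh:
        json.dump({"format_version": MASK_FOLDER_VERSION, "instances": records}, fh, indent=1)


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

def read_manifest(path) -> list[SampleMeta]:
    """Read a sample manifest CSV into :class:`SampleMeta` records.

    A blank or absent dpi column defaults to 300 (flatbed scan resolution)
    with a warning.  Duplicate sample ids and unknown treatment labels are
    errors.
    """
    df = pd.read_csv(path, dtype={"sample_id": str, "batch": str})
    required = {"sample_id", "genotype", "treatment"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: manifest missing columns {sorted(missing)}")
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if not dup.empty:
        raise ValidationError(f"{path}: duplicate sample_id(s): {sorted(set(dup))}")

    out = []
    for idx, row in df.iterrows():
        dpi = row.get("dpi", math.nan)
        if pd.isna(dpi):
            warnings.warn(
                f"sample {row['sample_id']}: no dpi given, assuming {DEFAULT_DPI}",
                stacklevel=2,
            )
            dpi = DEFAULT_DPI
        images = row.get("images", "")
        image_ids = [] if pd.isna(images) or not str(images) else str(images).split(";")
        try:
            meta = SampleMeta(
                sample_id=str(row["sample_id"]),
                image_ids=image_ids,
                genotype_line=str(row["genotype"]),
                treatment=str(row["treatment"]),
                batch=str(row.get("batch", "")),
                dpi=float(dpi),
                excluded_flag=bool(row.get("excluded", False)),
                exclusion_reason=str(row.get("exclusion_reason", "") or ""),
            )
        except ValidationError as exc:
            raise ValidationError(f"{path} row {idx}: {exc}") from exc
        out.append(meta)
    return out


def write_manifest(samples: list[SampleMeta], path) -> None:
    rows = [
        {
            "sample_id": s.sample_id,
            "genotype": s.genotype_line,
            "treatment": s.treatment,
            "batch": s.batch,
            "dpi": s.dpi,
            "images": ";".join(s.image_ids),
            "excluded": s.excluded_flag,
            "exclusion_reason": s.exclusion_reason,
        }
        for s in samples
    ]
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# trait tables
# ---------------------------------------------------------------------------

def write_traits_table(records: list[TraitRecord], path) -> None:
    """One CSV row per instance; rejected instances keep their row with
    empty trait cells and a QC reason code."""
    rows = []
    for rec in records:
        t = rec.traits
        rows.append(
            {
                "instance_id": rec.instance_id,
                "image_id": rec.image_id,
                "sample_id": rec.sample_id,
                "qc_status": rec.qc_status,
                "qc_reason": rec.qc_reason or "",
                "SA_mm2": t.SA if t else np.nan,
                "SL_mm": t.SL if t else np.nan,
                "SD_mm": t.SD if t else np.nan,
                "SV_mm3": t.SV if t else np.nan,
                "dpi": t.dpi if t else np.nan,
            }
        )
    df = pd.DataFrame(rows, columns=TRAIT_COLUMNS)
    df.to_csv(path, index=False, float_format="%.6f")


def read_traits_table(path) -> list[TraitRecord]:
    df = pd.read_csv(path, dtype={"instance_id": str, "image_id": str, "sample_id": str})
    out = []
    for _, row in df.iterrows():
        traits = None
        if not pd.isna(row["SA_mm2"]):
            traits = SiliqueTraits(
                SA=float(row["SA_mm2"]),
                SL=float(row["SL_mm"]),
                SD=float(row["SD_mm"]),
                SV=float(row["SV_mm3"]),
                dpi=float(row["dpi"]),
            )
        out.append(
            TraitRecord(
                instance_id=str(row["instance_id"]),
                image_id=str(row["image_id"]),
                sample_id=str(row["sample_id"]),
                qc_status=str(row["qc_status"]),
                qc_reason="" if pd.isna(row["qc_reason"]) else str(row["qc_reason"]),
                traits=traits,
            )
        )
    return out
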