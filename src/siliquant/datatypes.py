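"""Core domain types shared across the toolkit.

An *instance mask* is one detected or annotated silique: a full-frame
binary raster plus a bounding box, a confidence score, and linkage to the
image it came from.  Masks are amodal — overlapping instances may share
pixels — so each instance carries its own raster rather than a shared
label image.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

VALID_TREATMENTS = ("isolation", "group")

#: Default flatbed-scanner resolution assumed when a manifest omits dpi.
DEFAULT_DPI = 300.0


class SiliquantError(Exception):
    """Base class for toolkit errors."""


class ParseError(SiliquantError):
    """Malformed input file or record."""


class ValidationError(SiliquantError):
    """Input violates a documented contract."""


def tight_bbox(mask: np.ndarray) -> tuple[int, int, int, int]:
    """Tight (x, y, w, h) pixel bounds of the foreground, 0-based, half-open.

    Raises :class:`ValidationError` on an empty mask.
    """
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        raise ValidationError("cannot compute bbox of an empty mask")
    x0, x1 = int(xs.min()), int(xs.max())
    y0, y1 = int(ys.min()), int(ys.max())
    return (x0, y0, x1 - x0 + 1, y1 - y0 + 1)


@dataclass
class InstanceMask:
    """One silique instance: binary raster + bbox + score + linkage.

    ``mask`` is a full-frame boolean array (H, W).  ``bbox`` follows the
    COCO convention (x, y, w, h) in pixels, origin top-left.  ``score`` is
    1.0 for ground-truth annotations.
    """

    instance_id: str
    image_id: str
    mask: np.ndarray
    bbox: tuple[float, float, float, float] = None  # type: ignore[assignment]
    score: float = 1.0
    category: str = "silique"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if not 0.0 <= self.score <= 1.0:
            raise ValidationError(
                f"instance {self.instance_id}: score {self.score} outside [0, 1]"
            )
        if self.mask.any():
            tight = tight_bbox(self.mask)
            if self.bbox is None or not _bbox_encloses(self.bbox, tight):
                self.bbox = tuple(float(v) for v in tight)

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    def is_empty(self) -> bool:
        return not self.mask.any()


def _bbox_encloses(outer, tight) -> bool:
    ox, oy, ow, oh = outer
    tx, ty, tw, th = tight
    return ox <= tx and oy <= ty and ox + ow >= tx + tw and oy + oh >= ty + th


@dataclass
class SampleMeta:
    """One pot/sample: genotype line, treatment, batch, scan resolution."""

    sample_id: str
    image_ids: list[str]
    genotype_line: str
    treatment: str
    batch: str
    dpi: float = DEFAULT_DPI
    excluded_flag: bool = False
    exclusion_reason: str = ""

    def __post_init__(self) -> None:
        if self.dpi <= 0:
            raise ValidationError(f"sample {self.sample_id}: dpi must be > 0")
        if self.treatment not in VALID_TREATMENTS:
            raise ValidationError(
                f"sample {self.sample_id}: unknown treatment {self.treatment!r}; "
                f"expected one of {VALID_TREATMENTS}"
            )


@dataclass
class SiliqueTraits:
    """Morphometric traits of one accepted silique, in metric units.

    SA: projected area (mm^2); SL: skeletal length (mm); SD: maximum
    diameter (mm); SV: disk-stack volume (mm^3).  ``dpi`` records the
    pixel-to-mm context used for the conversion.
    """

    SA: float
    SL: float
    SD: float
    SV: float
    dpi: float = DEFAULT_DPI


@dataclass
class QCResult:
    """Outcome of instance-level mask quality control."""

    status: str  # "accepted" | "rejected"
    reason: Optional[str] = None  # multi_component | residual_spur | empty_mask | degenerate_skeleton

    def __post_init__(self) -> None:
        if (self.status == "rejected") != (self.reason is not None):
            raise ValidationError("rejected status requires a reason, accepted forbids one")

    @property
    def accepted(self) -> bool:
        return self.status == "accepted"


@dataclass
class TraitRecord:
    """One row of the instance-level trait table (accepted or rejected)."""

    instance_id: str
    image_id: str
    sample_id: str
    qc_status: str
    qc_reason: str = ""
    traits: Optional[SiliqueTraits] = None
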