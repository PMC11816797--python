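"""Synthetic silique masks, scenes, and phenotype populations.

Everything downstream of segmentation is testable without real scans:
capsule-shaped masks with analytically known length, radius profile, area
and volume; multi-instance scenes with controllable overlap and perturbed
"predictions"; deliberately aberrant masks that trigger QC rejections;
and line-by-treatment phenotype tables with known variance components.

Rasterisation rule: a pixel is foreground iff its centre lies within
distance r(t) of the centerline.  This makes the analytic area and volume
truths well-defined (tube formula plus semicircular end caps).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import interpolate
from skimage.measure import label

from .datatypes import InstanceMask, SiliqueTraits, ValidationError

#: densification step (px) along the centerline used for quadrature and
#: rasterisation; fine enough that trapezoid truths converge well below
#: the 0.5% documented quadrature tolerance.
_DS = 0.25


class GenerationError(ValidationError):
    """Synthetic shape could not be generated as specified."""


@dataclass
class SyntheticSiliqueSpec:
    """Parametric capsule: smooth centerline + radius profile.

    ``centerline`` is an (k, 2) array of (x, y) control points; a cubic
    spline (or lower order for few points) is threaded through them.
    ``radius_profile`` gives radii at equally spaced points of normalised
    arclength t in [0, 1], linearly interpolated in between.  All truths
    (length, max radius, area, volume) are closed-form/quadrature values
    on the continuous shape, independent of rasterisation.
    """

    centerline: np.ndarray
    radius_profile: np.ndarray
    seed: int = 0

    def __post_init__(self) -> None:
        self.centerline = np.atleast_2d(np.asarray(self.centerline, dtype=float))
        self.radius_profile = np.atleast_1d(np.asarray(self.radius_profile, dtype=float))
        if self.centerline.shape[0] < 2:
            raise ValidationError("centerline needs at least 2 control points")
        if (self.radius_profile < 1.0).any():
            raise ValidationError("radius profile must be >= 1 px everywhere")

    def _dense(self, ds: float = _DS):
        """Resample the centerline at ~ds spacing; returns (points, arclen, radii)."""
        pts = self.centerline
        if pts.shape[0] == 2:
            # straight segment
            length = float(np.hypot(*(pts[1] - pts[0])))
            n = max(int(np.ceil(length / ds)) + 1, 2)
            t = np.linspace(0, 1, n)
            dense = pts[0] + t[:, None] * (pts[1] - pts[0])
        else:
            k = min(3, pts.shape[0] - 1)
            tck, _ = interpolate.splprep([pts[:, 0], pts[:, 1]], k=k, s=0)
            # two-pass: estimate length, then resample uniformly in parameter
            u = np.linspace(0, 1, 25 * pts.shape[0])
            xy = np.column_stack(interpolate.splev(u, tck))
            approx_len = np.sum(np.hypot(*np.diff(xy, axis=0).T))
            n = max(int(np.ceil(approx_len / ds)) + 1, 2)
            u = np.linspace(0, 1, n)
            dense = np.column_stack(interpolate.splev(u, tck))
        seglen = np.hypot(*np.diff(dense, axis=0).T)
        arclen = np.concatenate(([0.0], np.cumsum(seglen)))
        t_norm = arclen / arclen[-1]
        radii = np.interp(
            t_norm, np.linspace(0, 1, self.radius_profile.size), self.radius_profile
        ) if self.radius_profile.size > 1 else np.full(dense.shape[0], self.radius_profile[0])
        return dense, arclen, radii

    @property
    def true_length(self) -> float:
        """Centerline arclength (px)."""
        _, arclen, _ = self._dense()
        return float(arclen[-1])

    @property
    def true_max_radius(self) -> float:
        return float(self.radius_profile.max())

    def true_area(self, ds: float = _DS) -> float:
        """Analytic foreground area (px^2): tube strip + semicircular caps."""
        _, arclen, radii = self._dense(ds)
        strip = np.trapezoid(2.0 * radii, arclen)
        caps = 0.5 * np.pi * (radii[0] ** 2 + radii[-1] ** 2)
        return float(strip + caps)

    def true_volume(self, ds: float = _DS) -> float:
        """Disk-stack volume truth (px^3): integral of pi r(t)^2 over arclength."""
        _, arclen, radii = self._dense(ds)
        return float(np.trapezoid(np.pi * radii**2, arclen))


def generate_capsule(spec: SyntheticSiliqueSpec, pad: int = 4):
    """Rasterise a capsule spec into an instance mask plus px-unit truths.

    Returns ``(InstanceMask, SiliqueTraits)`` where the traits are the
    analytic ground truth in pixel units (dpi = 25.4, i.e. 1 px = 1 mm).
    Generation is deterministic given the spec.  Raises
    :class:`GenerationError` if the raster is not a single connected
    component (radius too small for the sampled curve).
    """
    dense, arclen, radii = spec._dense()
    rmax = radii.max()
    lo = np.floor(dense.min(axis=0) - rmax - pad).astype(int)
    hi = np.ceil(dense.max(axis=0) + rmax + pad).astype(int)
    offset = lo
    w, h = (hi - lo + 1).astype(int)
    mask = np.zeros((h, w), dtype=bool)

    # paint a disk of radius r_j at every dense sample; union is the capsule
    for (cx, cy), r in zip(dense - offset, radii):
        x0, x1 = int(np.floor(cx - r)), int(np.ceil(cx + r))
        y0, y1 = int(np.floor(cy - r)), int(np.ceil(cy + r))
        yy, xx = np.mgrid[y0 : y1 + 1, x0 : x1 + 1]
        disk = (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2
        mask[y0 : y1 + 1, x0 : x1 + 1] |= disk

    if label(mask, connectivity=2).max() != 1:
        raise GenerationError("rasterised capsule is not a single connected component")

    inst = InstanceMask(
        instance_id=f"capsule-{spec.seed}",
        image_id="synthetic",
        mask=mask,
        score=1.0,
    )
    truth = SiliqueTraits(
        SA=spec.true_area(),
        SL=spec.true_length,
        SD=2.0 * spec.true_max_radius,
        SV=spec.true_volume(),
        dpi=25.4,  # 1 px = 1 mm: traits are in pixel units
    )
    return inst, truth


def random_capsule_spec(
    rng: np.random.Generator,
    length_range=(60.0, 160.0),
    radius_range=(4.0, 8.0),
    curvature: float = 0.15,
    taper: float = 0.3,
    seed: int = 0,
) -> SyntheticSiliqueSpec:
    """Draw a random gently curved, gently tapered capsule spec.

    ``curvature`` bounds the sagitta as a fraction of length;
    ``taper`` bounds how much the end radii shrink below the mid radius.
    Defaults mimic scanned Arabidopsis siliques at 300 dpi (roughly
    5--14 mm long, 5--10 px across).
    """
    L = rng.uniform(*length_range)
    r_mid = rng.uniform(*radius_range)
    theta = rng.uniform(0, np.pi)
    d = np.array([np.cos(theta), np.sin(theta)])
    n = np.array([-d[1], d[0]])
    sag = rng.uniform(-curvature, curvature) * L
    p0 = np.zeros(2)
    p2 = L * d
    p1 = 0.5 * L * d + sag * n
    # keep bend shallow relative to the radius so the tube formula holds
    r_ends = r_mid * (1.0 - rng.uniform(0, taper, size=2))
    r_ends = np.maximum(r_ends, 1.5)
    profile = np.array([r_ends[0], r_mid, r_mid, r_mid, r_ends[1]])
    return SyntheticSiliqueSpec(
        centerline=np.vstack([p0, p1, p2]), radius_profile=profile, seed=seed
    )


# ---------------------------------------------------------------------------
# aberrant masks
# ---------------------------------------------------------------------------

ABERRANT_KINDS = ("multi_component", "spurred", "fused_pair")


def _measured_spur(mask: np.ndarray) -> int:
    """Skeleton side-branch length of a mask with exactly one spur."""
    from .qc import skeletonize_and_prune

    skel = skeletonize_and_prune(mask, max_spur_px=10**9)
    return skel.spurs_pruned[0] if skel.spurs_pruned else 0


def generate_aberrant(kind: str, seed: int = 0, spur_px: int = 8) -> InstanceMask:
    """Construct a mask that triggers (or plausibly triggers) QC rejection.

    * ``multi_component`` — a capsule plus a disjoint blob (exactly 2
      components).
    * ``spurred`` — a capsule with a 1-px-wide perpendicular protrusion;
      the resulting skeleton side branch has ~``spur_px`` pixels
      (body radius + overhang).  ``spur_px`` must exceed the body radius.
    * ``fused_pair`` — two capsules crossed mid-body; the skeleton retains
      branch points no pruning can remove.
    """
    rng = np.random.default_rng(seed)
    if kind == "multi_component":
        spec = SyntheticSiliqueSpec(
            centerline=[[0, 0], [80, 0]], radius_profile=[5.0], seed=seed
        )
        inst, _ = generate_capsule(spec, pad=14)
        h, w = inst.mask.shape
        yy, xx = np.mgrid[0:h, 0:w]
        blob = (xx - (w - 5)) ** 2 + (yy - (h - 5)) ** 2 <= 3**2
        assert not (inst.mask & blob).any()
        mask = inst.mask | blob
    elif kind == "spurred":
        r = 3
        if spur_px <= r:
            raise ValidationError(f"spur_px must exceed the body radius ({r})")
        spec = SyntheticSiliqueSpec(
            centerline=[[0, 0], [80, 0]], radius_profile=[float(r)], seed=seed
        )
        inst, _ = generate_capsule(spec, pad=spur_px + 6)
        body = inst.mask
        ys, xs = np.nonzero(body)
        # centerline row and a mid-body column (jitter the column a little
        # so different seeds give different junctions)
        cy = int(round(ys.mean()))
        cx = int(round(xs.mean())) + int(rng.integers(-15, 16))
        # 1-px protrusion upward from the centerline; the thinning junction
        # cluster can absorb one pixel of the branch, so calibrate the
        # overhang until the *measured* skeleton spur equals spur_px
        mask = None
        for extra in (0, 1, 2):
            cand = body.copy()
            cand[cy - spur_px - extra : cy, cx] = True
            if _measured_spur(cand) == spur_px:
                mask = cand
                break
        if mask is None:
            raise GenerationError(
                f"could not construct a skeleton spur of exactly {spur_px} px"
            )
    elif kind == "fused_pair":
        a = SyntheticSiliqueSpec(
            centerline=[[0, 0], [90, 0]], radius_profile=[4.0], seed=seed
        )
        inst_a, _ = generate_capsule(a, pad=40)
        mask = inst_a.mask.copy()
        h, w = mask.shape
        # second capsule crossing the first at ~45 degrees through the middle
        b = SyntheticSiliqueSpec(
            centerline=[[15, -30], [75, 30]], radius_profile=[4.0], seed=seed
        )
        dense, _, radii = b._dense()
        ys, xs = np.nonzero(inst_a.mask)
        centre = np.array([xs.mean(), ys.mean()])
        shift = centre - dense.mean(axis=0)
        for (cx, cy), rr in zip(dense + shift, radii):
            x0, x1 = int(np.floor(cx - rr)), int(np.ceil(cx + rr))
            y0, y1 = int(np.floor(cy - rr)), int(np.ceil(cy + rr))
            x0, y0 = max(x0, 0), max(y0, 0)
            x1, y1 = min(x1, w - 1), min(y1, h - 1)
            yy, xx = np.mgrid[y0 : y1 + 1, x0 : x1 + 1]
            mask[y0 : y1 + 1, x0 : x1 + 1] |= (xx - cx) ** 2 + (yy - cy) ** 2 <= rr**2
    else:
        raise ValueError(f"unknown aberrant kind {kind!r}; expected one of {ABERRANT_KINDS}")

    return InstanceMask(
        instance_id=f"aberrant-{kind}-{seed}", image_id="synthetic", mask=mask
    )


# ---------------------------------------------------------------------------
# scenes
# ---------------------------------------------------------------------------

@dataclass
class ScenePerturbation:
    """How predictions differ from ground truth in a synthetic scene.

    ``kind`` is one of ``identity``, ``dilate``, ``erode``, ``shift``;
    each has a computable effect on IoU.  ``magnitude`` is the structuring
    radius (dilate/erode) or the (dx, dy) shift.
    """

    kind: str = "identity"
    magnitude: object = 0

    def apply(self, mask: np.ndarray) -> np.ndarray:
        from scipy import ndimage

        if self.kind == "identity":
            return mask.copy()
        if self.kind == "dilate":
            return ndimage.binary_dilation(mask, iterations=int(self.magnitude))
        if self.kind == "erode":
            return ndimage.binary_erosion(mask, iterations=int(self.magnitude))
        if self.kind == "shift":
            dx, dy = self.magnitude
            return ndimage.shift(mask.astype(np.uint8), (dy, dx), order=0).astype(bool)
        raise ValueError(f"unknown perturbation {self.kind!r}")


def generate_scene(
    n_siliques: int,
    overlap_fraction: float = 0.0,
    image_size: tuple[int, int] = (640, 640),
    seed: int = 0,
    perturbation: ScenePerturbation | None = None,
    image_id: str = "scene-0",
    max_tries: int = 200,
):
    """Place ``n_siliques`` capsules in one image; return (gt, predictions).

    ``overlap_fraction`` is the fraction of instances placed so they
    overlap a partner (paired off, rounded to an even count).  Predictions
    are ground truth copies run through ``perturbation`` with confidence
    scores drawn from U(0.5, 1); with the default identity perturbation
    every prediction-to-truth IoU is exactly 1.
    """
    if not 0 <= overlap_fraction <= 1:
        raise ValidationError("overlap_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    h, w = image_size
    n_overlapping = 2 * int(round(overlap_fraction * n_siliques / 2))

    frame = np.zeros((h, w), dtype=bool)
    gt: list[InstanceMask] = []
    for i in range(n_siliques):
        want_overlap = i < n_overlapping and i % 2 == 1  # overlap its predecessor
        placed = False
        for _ in range(max_tries):
            spec = random_capsule_spec(
                rng, length_range=(50, 110), radius_range=(3.5, 6.5), seed=seed * 1000 + i
            )
            inst, _ = generate_capsule(spec, pad=2)
            mh, mw = inst.mask.shape
            if mh >= h or mw >= w:
                continue
            if want_overlap:
                prev = gt[-1]
                ys, xs = np.nonzero(prev.mask)
                cy, cx = int(ys.mean()), int(xs.mean())
                y0 = int(np.clip(cy - mh // 2 + rng.integers(-5, 6), 0, h - mh))
                x0 = int(np.clip(cx - mw // 2 + rng.integers(-5, 6), 0, w - mw))
            else:
                y0 = int(rng.integers(0, h - mh))
                x0 = int(rng.integers(0, w - mw))
            full = np.zeros((h, w), dtype=bool)
            full[y0 : y0 + mh, x0 : x0 + mw] = inst.mask
            overlaps = (frame & full).any()
            if want_overlap:
                ok = (gt[-1].mask & full).any()
            else:
                ok = not overlaps
            if ok:
                gt.append(
                    InstanceMask(
                        instance_id=f"{image_id}-gt-{i}",
                        image_id=image_id,
                        mask=full,
                        score=1.0,
                    )
                )
                frame |= full
                placed = True
                break
        if not placed:
            raise GenerationError(
                f"could not place instance {i} in {image_size} after {max_tries} tries"
            )

    perturbation = perturbation or ScenePerturbation()
    preds: list[InstanceMask] = []
    for i, inst in enumerate(gt):
        pmask = perturbation.apply(inst.mask)
        if not pmask.any():
            raise GenerationError("perturbation erased an instance entirely")
        preds.append(
            InstanceMask(
                instance_id=f"{image_id}-pred-{i}",
                image_id=image_id,
                mask=pmask,
                score=float(rng.uniform(0.5, 1.0)),
            )
        )
    return gt, preds


# ---------------------------------------------------------------------------
# phenotype populations
# ---------------------------------------------------------------------------

@dataclass
class PhenotypePopulationSpec:
    """Line-by-treatment phenotype design with known variance components.

    ``treatment_effect`` is the additive shift of the "group" treatment
    relative to "isolation".  Broad-sense heritability of the generated
    values within one treatment is line_sd^2 / (line_sd^2 + resid_sd^2).
    """

    n_lines: int = 300
    reps_per_line: int = 3
    treatment_effect: float = 0.0
    line_sd: float = 1.0
    resid_sd: float = 1.0
    mu: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lines < 2 or self.reps_per_line < 1:
            raise ValidationError("need n_lines >= 2 and reps_per_line >= 1")
        if self.line_sd < 0 or self.resid_sd < 0:
            raise ValidationError("standard deviations must be >= 0")


def generate_phenotype_population(spec: PhenotypePopulationSpec) -> pd.DataFrame:
    """Simulate the additive line + treatment + residual model.

    value = mu + line_effect + treatment_effect * 1[group] + eps, with
    line_effect ~ N(0, line_sd^2) shared by all replicates of a line and
    eps ~ N(0, resid_sd^2) i.i.d.  Returns a tidy DataFrame with columns
    (line, treatment, replicate, value); reproducible under the seed.
    """
    rng = np.random.default_rng(spec.seed)
    n, r = spec.n_lines, spec.reps_per_line
    line_eff = rng.normal(0.0, spec.line_sd, size=n)
    # layout: line-major, then treatment (isolation, group), then replicate
    eps = rng.normal(0.0, spec.resid_sd, size=(n, 2, r))
    shift = np.array([0.0, spec.treatment_effect])
    values = spec.mu + line_eff[:, None, None] + shift[None, :, None] + eps
    lines = np.repeat([f"L{i:04d}" for i in range(n)], 2 * r)
    treatments = np.tile(np.repeat(["isolation", "group"], r), n)
    reps = np.tile(np.arange(r), 2 * n)
    return pd.DataFrame(
        {
            "line": lines,
            "treatment": treatments,
            "replicate": reps,
            "value": values.ravel(),
        }
    )
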