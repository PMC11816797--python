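"""Instance-level mask quality control.

A silique mask is kept only if it is a single 8-connected shape whose
Zhang–Suen skeleton, after pruning of small spurs, is one clean open
curve (exactly 2 endpoints, no branch points).  Spurs of at most
``max_spur_px`` pixels (default 5, measured excluding the branch point)
are harmless thinning artefacts and are deleted, shortest first; any
longer side branch that survives pruning marks the mask as aberrant —
typically a fusion of two siliques.

Skeleton cycles (masks with holes) and masks that thin to a single pixel
are rejected as degenerate; the morphometric contracts downstream assume
an open curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.measure import label
from skimage.morphology import skeletonize

from .datatypes import InstanceMask, QCResult, SiliquantError

DEFAULT_MAX_SPUR_PX = 5

_NEIGH_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=np.uint8)

_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


class DegenerateSkeletonError(SiliquantError):
    """Mask thins to a single pixel or a closed cycle."""


@dataclass
class Skeleton:
    """A thinned medial line, as sets of raster (row, col) coordinates."""

    pixels: set
    endpoints: list
    branch_points: list
    spurs_pruned: list = field(default_factory=list)

    @property
    def is_clean(self) -> bool:
        return len(self.endpoints) == 2 and not self.branch_points

    def ordered_path(self) -> list[tuple[int, int]]:
        """Walk the clean skeleton from one endpoint to the other."""
        if not self.is_clean:
            raise SiliquantError("ordered_path requires a clean skeleton")
        start = min(self.endpoints)  # deterministic starting end
        path = [start]
        prev = None
        cur = start
        while True:
            nxt = [
                (cur[0] + dy, cur[1] + dx)
                for dy, dx in _OFFSETS
                if (cur[0] + dy, cur[1] + dx) in self.pixels
                and (cur[0] + dy, cur[1] + dx) != prev
            ]
            if not nxt:
                break
            # on a clean path there is exactly one way forward, except the
            # first step where a diagonal+orthogonal pair can both touch;
            # prefer the orthogonal (closer) neighbour for determinism
            nxt.sort(key=lambda p: ((p[0] - cur[0]) ** 2 + (p[1] - cur[1]) ** 2, p))
            prev, cur = cur, nxt[0]
            path.append(cur)
        return path


def component_count(mask: np.ndarray) -> int:
    """Number of 8-connected foreground components (0 for an empty mask)."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return 0
    return int(label(mask, connectivity=2).max())


def _neighbor_counts(skel: np.ndarray) -> np.ndarray:
    return ndimage.convolve(skel.astype(np.uint8), _NEIGH_KERNEL, mode="constant")


def _classify(pixels: set) -> tuple[list, list]:
    """Endpoints (1 neighbour) and branch points (>=3 neighbours)."""
    endpoints, branches = [], []
    for p in pixels:
        deg = sum(1 for dy, dx in _OFFSETS if (p[0] + dy, p[1] + dx) in pixels)
        if deg == 1:
            endpoints.append(p)
        elif deg >= 3:
            branches.append(p)
    return sorted(endpoints), sorted(branches)


def _terminal_branches(pixels: set, endpoints: list) -> list[list]:
    """Paths from each endpoint up to (excluding) the first branch point."""
    branches = []
    ep_set = set(endpoints)
    for ep in endpoints:
        path = [ep]
        visited = {ep}
        cur = ep
        while True:
            nbrs = [
                (cur[0] + dy, cur[1] + dx)
                for dy, dx in _OFFSETS
                if (cur[0] + dy, cur[1] + dx) in pixels
                and (cur[0] + dy, cur[1] + dx) not in visited
            ]
            if len(nbrs) != 1:
                break  # dead end or junction cluster: stop here
            nxt = nbrs[0]
            deg = sum(1 for dy, dx in _OFFSETS if (nxt[0] + dy, nxt[1] + dx) in pixels)
            if deg >= 3:
                break  # nxt is the branch point; exclude it from the spur
            path.append(nxt)
            visited.add(nxt)
            cur = nxt
            if nxt in ep_set:  # ran end to end: a simple path has no spurs
                return []
        branches.append(path)
    return branches


def _rethin(pixels: set) -> set:
    """Re-run thinning on a pixel set (as a minimal raster)."""
    rows, cols = zip(*pixels)
    r0, c0 = min(rows) - 1, min(cols) - 1
    arr = np.zeros((max(rows) - r0 + 2, max(cols) - c0 + 2), dtype=bool)
    for r, c in pixels:
        arr[r - r0, c - c0] = True
    thin = skeletonize(arr, method="zhang")
    return {(r + r0, c + c0) for r, c in zip(*np.nonzero(thin))}


def skeletonize_and_prune(
    mask: np.ndarray, max_spur_px: int = DEFAULT_MAX_SPUR_PX
) -> Skeleton:
    """Zhang–Suen thinning followed by iterative spur pruning.

    Terminal branches of at most ``max_spur_px`` pixels (branch point
    excluded) are deleted, shortest first, recomputing the topology after
    each deletion until stable.  The returned skeleton records the pruned
    spur lengths; surviving branch points signal an aberrant mask.

    Raises :class:`DegenerateSkeletonError` if the skeleton is a single
    pixel or has no endpoints (a cycle).
    """
    mask = np.asarray(mask, dtype=bool)
    skel = skeletonize(mask, method="zhang")
    pixels = set(zip(*np.nonzero(skel)))
    if len(pixels) <= 1:
        raise DegenerateSkeletonError("mask thinned to a single pixel")

    spurs_pruned: list[int] = []
    while True:
        endpoints, branch_points = _classify(pixels)
        if not endpoints:
            raise DegenerateSkeletonError("skeleton has no endpoints (cycle)")
        if not branch_points:
            break
        candidates = [
            b for b in _terminal_branches(pixels, endpoints) if len(b) <= max_spur_px
        ]
        if not candidates:
            break  # residual spurs longer than the threshold: leave for QC
        shortest = min(candidates, key=lambda b: (len(b), b[0]))
        pixels -= set(shortest)
        spurs_pruned.append(len(shortest))
        if len(pixels) <= 1:
            raise DegenerateSkeletonError("pruning consumed the skeleton")
        # re-thin: junction clusters can leave a redundant 1-px stub whose
        # degree is >= 3 (never walkable from an endpoint); thinning the
        # remaining set removes it without touching the rest of the line
        pixels = _rethin(pixels)

    endpoints, branch_points = _classify(pixels)
    return Skeleton(
        pixels=pixels,
        endpoints=endpoints,
        branch_points=branch_points,
        spurs_pruned=spurs_pruned,
    )


def qc_filter(
    instance: InstanceMask | np.ndarray, max_spur_px: int = DEFAULT_MAX_SPUR_PX
) -> QCResult:
    """Accept or reject one instance mask with a reason code."""
    result, _ = qc_with_skeleton(instance, max_spur_px=max_spur_px)
    return result


def qc_with_skeleton(
    instance: InstanceMask | np.ndarray, max_spur_px: int = DEFAULT_MAX_SPUR_PX
) -> tuple[QCResult, Skeleton | None]:
    """Like :func:`qc_filter` but also returns the pruned skeleton on
    acceptance, so trait extraction can reuse it."""
    mask = instance.mask if isinstance(instance, InstanceMask) else np.asarray(instance, bool)
    n_comp = component_count(mask)
    if n_comp == 0:
        return QCResult("rejected", "empty_mask"), None
    if n_comp != 1:
        return QCResult("rejected", "multi_component"), None
    try:
        skel = skeletonize_and_prune(mask, max_spur_px=max_spur_px)
    except DegenerateSkeletonError:
        return QCResult("rejected", "degenerate_skeleton"), None
    if skel.branch_points:
        return QCResult("rejected", "residual_spur"), None
    if len(skel.endpoints) != 2:
        return QCResult("rejected", "degenerate_skeleton"), None
    return QCResult("accepted"), skel
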