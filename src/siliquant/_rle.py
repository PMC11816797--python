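"""COCO run-length encoding of binary masks.

COCO RLE runs are column-major (Fortran order) and always start with a
(possibly zero-length) background run.  Two on-disk flavours exist: a
plain list of counts, and the compact LEB128-style string used in result
files; both are supported here.
"""

from __future__ import annotations

import numpy as np


def encode(mask: np.ndarray) -> dict:
    """Encode a boolean mask as an uncompressed COCO RLE dict."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    flat = mask.flatten(order="F").astype(np.int8)
    # run boundaries
    diffs = np.flatnonzero(flat[1:] != flat[:-1]) + 1
    boundaries = np.concatenate(([0], diffs, [flat.size]))
    counts = np.diff(boundaries).tolist()
    if flat.size and flat[0] == 1:
        counts = [0] + counts
    if not flat.size:
        counts = []
    return {"size": [int(h), int(w)], "counts": counts}


def decode(rle: dict) -> np.ndarray:
    """Decode a COCO RLE dict (list counts or compressed string) to bool mask."""
    h, w = rle["size"]
    counts = rle["counts"]
    if isinstance(counts, (bytes, str)):
        counts = _string_to_counts(counts)
    counts = np.asarray(counts, dtype=np.int64)
    total = int(counts.sum())
    if total != h * w:
        raise ValueError(f"RLE counts sum to {total}, expected {h * w}")
    flat = np.zeros(h * w, dtype=bool)
    pos = np.concatenate(([0], np.cumsum(counts)))
    for i in range(1, len(counts), 2):  # odd runs are foreground
        flat[pos[i]:pos[i + 1]] = True
    return flat.reshape((h, w), order="F")


def _string_to_counts(s) -> list[int]:
    """Decode the COCO compressed-RLE character string to run counts."""
    if isinstance(s, bytes):
        s = s.decode("ascii")
    counts: list[int] = []
    p = 0
    while p < len(s):
        x = 0
        k = 0
        more = True
        while more:
            c = ord(s[p]) - 48
            x |= (c & 0x1F) << (5 * k)
            more = bool(c & 0x20)
            p += 1
            k += 1
            if not more and (c & 0x10):
                x |= -1 << (5 * k)
        if len(counts) > 2:
            x += counts[-2]
        counts.append(x)
    return counts


def counts_to_string(counts: list[int]) -> str:
    """Encode run counts as the COCO compressed-RLE character string."""
    out = []
    for i, x in enumerate(counts):
        if i > 2:
            x -= counts[i - 2]
        more = True
        while more:
            c = x & 0x1F
            x >>= 5
            more = (x != -1) if (c & 0x10) else (x != 0)
            if more:
                c |= 0x20
            out.append(chr(c + 48))
    return "".join(out)
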