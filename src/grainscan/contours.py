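"""Moore-neighbor boundary tracing for binary grain masks."""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi

from .errors import InvalidRegionError

# clockwise 8-neighborhood starting east, in (row, col) offsets
_NEIGHBORS = [(0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1)]
_OFFSET_INDEX = {off: i for i, off in enumerate(_NEIGHBORS)}


def trace_contour(mask: np.ndarray) -> np.ndarray:
    """Ordered closed boundary of a single-component boolean mask.

    Returns an (n, 2) integer array of unique (row, col) boundary pixels in
    clockwise traversal order, starting from the first foreground pixel in
    raster-scan order.  Filling the traced contour recovers the (hole-free)
    mask, so the enclosed pixel set equals the region.

    Raises :class:`InvalidRegionError` for empty or multi-component masks.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise InvalidRegionError("empty mask has no contour")
    _, n = ndi.label(mask, structure=np.ones((3, 3), bool))
    if n != 1:
        raise InvalidRegionError(f"mask has {n} connected components, expected 1")

    if mask.sum() == 1:
        return np.argwhere(mask).astype(int)

    padded = np.pad(mask, 1)
    start = tuple(np.argwhere(padded)[0])  # raster-scan first pixel
    current = start
    # raster-scan minimality: the west neighbor of start is background,
    # so treat it as the backtrack pixel
    backtrack = (start[0], start[1] - 1)
    contour = [start]
    second: tuple[int, int] | None = None
    limit = 4 * int(mask.sum()) + 8

    while len(contour) <= limit:
        db = _OFFSET_INDEX[(backtrack[0] - current[0], backtrack[1] - current[1])]
        for step in range(1, 9):
            d = (db + step) % 8
            cand = (current[0] + _NEIGHBORS[d][0], current[1] + _NEIGHBORS[d][1])
            if padded[cand]:
                prev = (db + step - 1) % 8
                new_backtrack = (
                    current[0] + _NEIGHBORS[prev][0],
                    current[1] + _NEIGHBORS[prev][1],
                )
                break
        # stop once the initial move is about to repeat (Jacob's criterion)
        if current == start and second is not None and cand == second:
            break
        if second is None:
            second = cand
        contour.append(cand)
        backtrack = new_backtrack
        current = cand

    pts = np.array(contour, int) - 1  # undo padding
    # unique pixels in first-visit order (thin necks are traversed twice)
    seen: set[tuple[int, int]] = set()
    keep = []
    for i, rc in enumerate(map(tuple, pts)):
        if rc not in seen:
            seen.add(rc)
            keep.append(i)
    return pts[keep]


def contour_mask(contour: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a contour and fill it, reconstructing the enclosed region."""
    canvas = np.zeros(shape, bool)
    canvas[contour[:, 0], contour[:, 1]] = True
    return ndi.binary_fill_holes(canvas)
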