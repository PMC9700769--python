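"""Topology-preserving skeletonization by iterated boundary erosion.

The cord mask is peeled one border layer at a time, but a pixel is only
deleted when it is a *simple point*: its removal changes neither the number
of 8-connected foreground components nor the number of 4-connected holes in
its 3x3 neighbourhood.  This is the formal version of "erode repeatedly but
stop just before anything disconnects": erosion proceeds per pixel and halts
exactly at the pixels whose loss would break a cord or open a loop.
Endpoints (single-neighbour pixels) are never deleted, so arcs keep their
length instead of retracting to dots.

Deletion is sequential in raster order with two directional sub-passes per
iteration (north/west borders first, then south/east) to limit drift of the
skeleton toward one side.  Because every deletion is re-validated against
the current raster, topology preservation holds by construction, not just in
expectation: ``euler_summary(mask) == euler_summary(skeletonize(mask))`` for
every input.

Foreground uses 8-connectivity and background 4-connectivity throughout
(the standard planar duality; anything else lets loops leak diagonally).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

__all__ = ["Skeleton", "skeletonize", "euler_summary", "prune_spurs"]

# ring offsets around a pixel, fixed order
_OFFS = [(-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1)]
_STRUCT8 = np.ones((3, 3), dtype=int)
_STRUCT4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=int)


def _build_luts() -> tuple[np.ndarray, np.ndarray]:
    """Per-3x3-configuration tables: is the centre pixel simple, and how
    many foreground neighbours does it have.

    A configuration is encoded as an 8-bit number over ``_OFFS``.  The
    centre is simple iff the foreground cells of the ring form exactly one
    8-connected component and the background cells form exactly one
    4-connected component that touches the centre 4-adjacently.
    """
    simple = np.zeros(256, dtype=bool)
    ncount = np.zeros(256, dtype=np.uint8)
    coords = [np.array(o) for o in _OFFS]
    for code in range(256):
        fg = [coords[i] for i in range(8) if code >> i & 1]
        bg = [coords[i] for i in range(8) if not code >> i & 1]
        ncount[code] = len(fg)
        if not fg:
            continue

        def n_comp(cells, max_dist_cheb):
            comps = 0
            seen = set()
            cells = [tuple(c) for c in cells]
            for c in cells:
                if c in seen:
                    continue
                comps += 1
                stack = [c]
                seen.add(c)
                while stack:
                    cur = stack.pop()
                    for other in cells:
                        if other in seen:
                            continue
                        dr = abs(cur[0] - other[0])
                        dc = abs(cur[1] - other[1])
                        adj = (
                            max(dr, dc) == 1
                            if max_dist_cheb
                            else dr + dc == 1
                        )
                        if adj:
                            seen.add(other)
                            stack.append(other)
            return comps

        if n_comp(fg, True) != 1:
            continue
        # background components (4-connected within the ring) that are
        # 4-adjacent to the centre, i.e. contain an N/E/S/W cell
        bg_cells = [tuple(c) for c in bg]
        four = {(-1, 0), (0, 1), (1, 0), (0, -1)}
        seen: set = set()
        touching = 0
        for c in bg_cells:
            if c in seen:
                continue
            comp = [c]
            seen.add(c)
            stack = [c]
            while stack:
                cur = stack.pop()
                for other in bg_cells:
                    if other in seen:
                        continue
                    if abs(cur[0] - other[0]) + abs(cur[1] - other[1]) == 1:
                        seen.add(other)
                        comp.append(other)
                        stack.append(other)
            if any(p in four for p in comp):
                touching += 1
        simple[code] = touching == 1
    return simple, ncount


_SIMPLE, _NCOUNT = _build_luts()
_POW2 = np.array([1 << i for i in range(8)], dtype=np.int32)


def _codes(fg: np.ndarray) -> np.ndarray:
    """8-bit neighbourhood code of every pixel of a padded boolean array."""
    h, w = fg.shape
    out = np.zeros((h, w), dtype=np.int32)
    for i, (dr, dc) in enumerate(_OFFS):
        shifted = np.zeros_like(fg)
        rs0, rs1 = max(dr, 0), h + min(dr, 0)
        cs0, cs1 = max(dc, 0), w + min(dc, 0)
        shifted[rs0 - dr : rs1 - dr, cs0 - dc : cs1 - dc] = fg[rs0:rs1, cs0:cs1]
        out += shifted.astype(np.int32) * _POW2[i]
    return out


def _code_at(fg: np.ndarray, r: int, c: int) -> int:
    code = 0
    for i, (dr, dc) in enumerate(_OFFS):
        if fg[r + dr, c + dc]:
            code |= 1 << i
    return code


def euler_summary(raster) -> tuple[int, int]:
    """(n_components, n_holes) of a binary raster.

    Components are 8-connected foreground; holes are 4-connected background
    components that do not touch the frame border.
    """
    fg = raster.pixels if hasattr(raster, "pixels") else np.asarray(raster, dtype=bool)
    if fg.ndim != 2:
        raise ValueError("expected a 2-D raster")
    _, n_comp = ndi.label(fg, structure=_STRUCT8)
    lab_bg, n_bg = ndi.label(~fg, structure=_STRUCT4)
    border = np.concatenate(
        [lab_bg[0, :], lab_bg[-1, :], lab_bg[:, 0], lab_bg[:, -1]]
    )
    n_border = np.unique(border[border > 0]).size
    return int(n_comp), int(n_bg - n_border)


@dataclass
class Skeleton:
    """One-pixel-wide topological core of a cord mask."""

    pixels: np.ndarray  # bool, 2-D
    n_components: int
    n_holes: int

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @classmethod
    def from_pixels(cls, pixels: np.ndarray) -> "Skeleton":
        comp, holes = euler_summary(pixels)
        return cls(pixels=np.asarray(pixels, dtype=bool), n_components=comp,
                   n_holes=holes)


def _thin(padded: np.ndarray) -> None:
    """In-place sequential thinning of a 1-px zero-padded boolean array."""
    while True:
        deleted = False
        codes = _codes(padded)
        for northwest in (True, False):
            if northwest:
                border = ~(np.roll(padded, 1, axis=0) & np.roll(padded, 1, axis=1))
            else:
                border = ~(np.roll(padded, -1, axis=0) & np.roll(padded, -1, axis=1))
            cand = padded & _SIMPLE[codes] & (_NCOUNT[codes] >= 2) & border
            cand[0, :] = cand[-1, :] = False
            cand[:, 0] = cand[:, -1] = False
            rows, cols = np.nonzero(cand)
            for r, c in zip(rows, cols):
                code = _code_at(padded, r, c)
                if _SIMPLE[code] and _NCOUNT[code] >= 2:
                    padded[r, c] = False
                    deleted = True
            codes = _codes(padded)
        if not deleted:
            return


def _neighbor_count(fg: np.ndarray) -> np.ndarray:
    return ndi.convolve(fg.astype(np.uint8), _STRUCT8, mode="constant") - fg


def _blocks(fg: np.ndarray) -> np.ndarray:
    """Top-left corners of all 2x2 all-foreground blocks."""
    hit = fg[:-1, :-1] & fg[1:, :-1] & fg[:-1, 1:] & fg[1:, 1:]
    return np.argwhere(hit)


def _repair_blocks(padded: np.ndarray, mask_padded: np.ndarray) -> None:
    """Resolve residual 2x2 blocks where no pixel is a simple point.

    Four arcs meeting diagonally in a 2x2 core cannot be thinned by
    deletion alone: removing any core pixel strands an arc.  If the
    original mask still has a spare pixel next to the core, re-routing the
    junction through it restores deletability, so we add one such pixel
    (checking the Euler summary is unchanged), re-thin, and keep the edit
    only if the block disappears.  The skeleton stays inside the mask.
    """
    for _ in range(8):  # each round resolves at least one block or stops
        blocks = _blocks(padded)
        if blocks.size == 0:
            return
        progressed = False
        for r, c in blocks:
            if not (padded[r, c] & padded[r + 1, c] & padded[r, c + 1]
                    & padded[r + 1, c + 1]):
                continue
            candidates = []
            for br, bc in ((r, c), (r, c + 1), (r + 1, c), (r + 1, c + 1)):
                for dr, dc in _OFFS:
                    q = (br + dr, bc + dc)
                    if mask_padded[q] and not padded[q]:
                        candidates.append(q)
            before = euler_summary(padded)
            for q in candidates:
                padded[q] = True
                if euler_summary(padded) != before:
                    padded[q] = False
                    continue
                trial = padded.copy()
                _thin(trial)
                if not (trial[r, c] & trial[r + 1, c] & trial[r, c + 1]
                        & trial[r + 1, c + 1]):
                    padded[:] = trial
                    progressed = True
                    break
                padded[q] = False
        if not progressed:
            return


def prune_spurs(pixels: np.ndarray, prune_length: int) -> np.ndarray:
    """Remove endpoint branches shorter than ``prune_length`` px.

    A spur is walked from its endpoint through 2-neighbour pixels until a
    junction (>= 3 neighbours) is reached; the walked pixels, junction
    excluded, are deleted if fewer than ``prune_length``.  Arcs that end at
    another endpoint are whole components and are never pruned, and
    deletion proceeds from the free end inward (each removed pixel has one
    remaining neighbour), so components and holes are provably unchanged.
    """
    if prune_length <= 0:
        return pixels.copy()
    out = pixels.copy()
    changed = True
    while changed:
        changed = False
        ncnt = _neighbor_count(out)
        endpoints = np.argwhere(out & (ncnt == 1))
        for r, c in endpoints:
            if not out[r, c]:
                continue
            path = [(int(r), int(c))]
            prev = None
            cur = (int(r), int(c))
            reached_junction = False
            while True:
                nbrs = [
                    (cur[0] + dr, cur[1] + dc)
                    for dr, dc in _OFFS
                    if 0 <= cur[0] + dr < out.shape[0]
                    and 0 <= cur[1] + dc < out.shape[1]
                    and out[cur[0] + dr, cur[1] + dc]
                    and (cur[0] + dr, cur[1] + dc) != prev
                ]
                if len(nbrs) != 1:
                    break
                nxt = nbrs[0]
                if ncnt[nxt] >= 3:
                    reached_junction = True
                    break
                path.append(nxt)
                prev, cur = cur, nxt
                if len(path) >= prune_length:
                    break
            if reached_junction and len(path) < prune_length:
                for p in path:
                    out[p] = False
                changed = True
    return out


def skeletonize(mask, prune_length: int = 5) -> Skeleton:
    """Thin a cord mask to its one-pixel-wide topological core.

    Parameters
    ----------
    mask : BinaryMask or 2-D boolean array
        Foreground is the cord network.  An empty mask yields an empty
        skeleton (a warning-level event, not a failure).
    prune_length : int
        Spur branches shorter than this many pixels are removed after
        thinning; pruning never alters (n_components, n_holes).  0 disables.

    Returns
    -------
    Skeleton
        Satisfies: same Euler summary as the input; no 2x2 foreground
        block; skeleton foreground is a subset of the mask foreground;
        re-skeletonizing is the identity.
    """
    fg = mask.pixels if hasattr(mask, "pixels") else np.asarray(mask, dtype=bool)
    if fg.ndim != 2:
        raise ValueError("expected a 2-D mask")
    padded = np.zeros((fg.shape[0] + 2, fg.shape[1] + 2), dtype=bool)
    padded[1:-1, 1:-1] = fg
    mask_padded = padded.copy()
    # pruning can expose newly deletable corner pixels, so thin and prune
    # alternate until the raster is stable (usually two rounds)
    while True:
        before = padded.copy()
        _thin(padded)
        _repair_blocks(padded, mask_padded)
        if prune_length > 0:
            padded[1:-1, 1:-1] = prune_spurs(padded[1:-1, 1:-1], prune_length)
        if np.array_equal(padded, before):
            break
    return Skeleton.from_pixels(padded[1:-1, 1:-1])
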