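"""Shared fixtures and independent brute-force oracles.

The oracles re-derive expected results by exhaustive/naive computation and
deliberately share no code with the package: Otsu by looping over all
candidate split bins, the mean blur by an O(w^2) per-pixel window loop,
and spur trimming by walking pixel sets with dictionaries.
"""

from __future__ import annotations

import numpy as np
import pytest

from veindensity import PipelineConfig, load_config


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------

@pytest.fixture
def base_config_map() -> dict:
    """The five mandatory keys only."""
    return {
        "input_path": ".",
        "trim_factor": 10,
        "pixel_length_um": 0.65,
        "y_pixels": 1040,
        "x_pixels": 1392,
    }


def make_config(**overrides) -> PipelineConfig:
    m = {
        "input_path": ".",
        "trim_factor": 10,
        "pixel_length_um": 1.0,
        "y_pixels": 100,
        "x_pixels": 100,
    }
    m.update(overrides)
    return load_config(m)


# ---------------------------------------------------------------------------
# raster fixtures
# ---------------------------------------------------------------------------

def make_ladder(n_rungs: int = 5, rung_spacing: int = 25, span: int = 10,
                margin: int = 5) -> tuple[np.ndarray, np.ndarray]:
    """1-px ladder skeleton: two vertical rails ``span`` apart joined by
    ``n_rungs`` horizontal rungs. Returns (ladder, rails_only)."""
    height = 2 * margin + n_rungs * rung_spacing
    c0, c1 = 10, 10 + span
    lad = np.zeros((height, c1 + 10), dtype=np.uint8)
    lad[margin:height - margin, c0] = 1
    lad[margin:height - margin, c1] = 1
    rails = lad.copy()
    for k in range(n_rungs):
        r = margin + rung_spacing // 2 + k * rung_spacing
        lad[r, c0 + 1:c1] = 1
    return lad, rails


def random_skeleton(rng: np.random.Generator, size: int = 64) -> np.ndarray:
    """A valid 1-px skeleton: thin a scribble of random thick line segments."""
    from skimage.draw import line
    from skimage.morphology import dilation, disk

    from veindensity import skeletonize

    canvas = np.zeros((size, size), dtype=bool)
    for _ in range(rng.integers(3, 8)):
        r0, c0, r1, c1 = rng.integers(2, size - 2, size=4)
        rr, cc = line(int(r0), int(c0), int(r1), int(c1))
        canvas[rr, cc] = True
    canvas = dilation(canvas, disk(1))
    return skeletonize(canvas)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def oracle_otsu_bin(img: np.ndarray, nbins: int = 256) -> int:
    """Exhaustive-search Otsu: argmax over all split bins of the
    between-class variance of a fixed-range [0, 1] histogram."""
    counts, edges = np.histogram(img, bins=nbins, range=(0.0, 1.0))
    centers = (edges[:-1] + edges[1:]) / 2.0
    total = counts.sum()
    best_k, best_var = 0, -1.0
    for k in range(nbins):
        w0 = counts[: k + 1].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            var = 0.0
        else:
            m0 = (counts[: k + 1] * centers[: k + 1]).sum() / w0
            m1 = (counts[k + 1:] * centers[k + 1:]).sum() / w1
            var = float(w0) * float(w1) * (m0 - m1) ** 2
        if var > best_var:
            best_var, best_k = var, k
    return best_k


def oracle_mean_blur(img: np.ndarray, w: int) -> np.ndarray:
    """Direct O(w^2) windowed mean with replicate (clamped-index) padding."""
    h, wd = img.shape
    out = np.empty_like(img, dtype=np.float64)
    for i in range(h):
        for j in range(wd):
            acc = 0.0
            for di in range(-w, w + 1):
                ii = min(max(i + di, 0), h - 1)
                for dj in range(-w, w + 1):
                    jj = min(max(j + dj, 0), wd - 1)
                    acc += img[ii, jj]
            out[i, j] = acc / (2 * w + 1) ** 2
    return out


def _nb8(p):
    r, c = p
    return [(r + dr, c + dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
            if (dr, dc) != (0, 0)]


def _oracle_is_simple(S: set, p) -> bool:
    nbrs = [q for q in _nb8(p) if q in S]
    if not nbrs:
        return False
    seen = {nbrs[0]}
    stack = [nbrs[0]]
    while stack:
        q = stack.pop()
        for s in nbrs:
            if s not in seen and abs(s[0] - q[0]) <= 1 and abs(s[1] - q[1]) <= 1:
                seen.add(s)
                stack.append(s)
    return len(seen) == len(nbrs)


def oracle_trim(skeleton: np.ndarray, trim_factor: int) -> np.ndarray:
    """Brute-force spur pruning on plain pixel sets.

    Deletable pieces are: tip-walk paths reaching a branch pixel (spurs,
    length includes the branch pixel), walks dead-ending at another tip
    (floating fragments, deleted whole), and isolated pixels (length 1).
    Per round: enumerate every deletable piece shorter than
    ``trim_factor``, delete all pieces of the minimum length at once, then
    remove reached branch pixels that are simple points (sorted order, to
    a fixpoint), and repeat until no deletable piece remains.
    """
    S = {tuple(map(int, p)) for p in np.argwhere(np.asarray(skeleton).astype(bool))}
    if trim_factor > 0:
        while True:
            deg = {p: sum(q in S for q in _nb8(p)) for p in S}
            pieces = []  # (length, pixels-to-delete, reached-branch-or-None)
            for t in sorted(p for p in S if deg[p] == 1):
                path = [t]
                prev, cur = None, t
                reached = None
                while True:
                    if deg[cur] >= 3:
                        reached = cur
                        break
                    nxt = [q for q in _nb8(cur) if q in S and q != prev]
                    if not nxt:
                        break
                    path.append(nxt[0])
                    prev, cur = cur, nxt[0]
                if reached is not None:
                    pieces.append((len(path), set(path[:-1]), reached))
                else:
                    pieces.append((len(path), set(path), None))
            for p in S:
                if deg[p] == 0:
                    pieces.append((1, {p}, None))
            pieces = [pc for pc in pieces if pc[0] < trim_factor]
            if not pieces:
                break
            lmin = min(pc[0] for pc in pieces)
            doomed: set = set()
            cleanup: set = set()
            for length, px, reached in pieces:
                if length == lmin:
                    doomed |= px
                    if reached is not None:
                        cleanup.add(reached)
            S -= doomed
            changed = True
            while changed:
                changed = False
                for t in sorted(cleanup):
                    if t in S and _oracle_is_simple(S, t):
                        S.discard(t)
                        changed = True
    out = np.zeros_like(np.asarray(skeleton), dtype=np.uint8)
    for p in S:
        out[p] = 1
    return out
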