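"""Skeletonization and skeleton-graph analysis.

The binarized vein mask is thinned to a one-pixel-wide skeleton, which is
then decomposed into a graph: *tips* (skeleton pixels with exactly one
8-connected neighbour), *branch points* (pixels with three or more
neighbours) and *edges* (maximal 8-connected pixel paths between them,
carrying their geodesic length in pixels). Two cleaning operations act on
that graph:

* spur trimming — short tip-to-branch-point branches, typically thinning
  artefacts, are deleted iteratively until a fixpoint (removing a spur can
  demote a branch point and expose a new spur);
* commissural removal — in parallel-veined (grass) leaves, short transverse
  connections between longitudinal veins are identified as
  branch-point-to-branch-point edges whose terminal Euclidean span falls
  below a user threshold and removed, because they are not wrapped in
  bundle sheath and are excluded from Kranz vein density.

Adjacent branch pixels (which thinning frequently produces at junctions)
are grouped into a single junction *cluster* for edge tracing, so an edge
never terminates inside a junction. Coordinates are 0-based (row, col);
connectivity is 8 throughout. Edge length is the number of pixels on the
path including both terminals — the same pixel-count currency the density
estimate uses.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize as _skimage_skeletonize

__all__ = [
    "SkeletonGraph",
    "SkeletonEdge",
    "skeletonize",
    "build_graph",
    "trim_spurs",
    "auto_trim_factor",
    "remove_commissural",
    "diagonal_corrected_length",
]

_NBR_OFFSETS = tuple(
    (dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)
)

_EIGHT = np.ones((3, 3), dtype=np.uint8)


@dataclass(frozen=True)
class SkeletonEdge:
    """A maximal skeleton path between two node pixels.

    ``a`` and ``b`` are the terminal pixels (branch-point, tip or — for an
    isolated cycle — the same pixel twice); ``path`` lists every pixel from
    ``a`` to ``b`` inclusive; ``length`` is ``len(path)``. ``a_kind`` /
    ``b_kind`` are ``"junction"``, ``"tip"`` or ``"cycle"``.
    """

    a: tuple[int, int]
    b: tuple[int, int]
    path: tuple[tuple[int, int], ...]
    length: int
    a_kind: str
    b_kind: str

    @property
    def is_spur(self) -> bool:
        """True when exactly one terminal is a tip and the other a junction."""
        kinds = {self.a_kind, self.b_kind}
        return kinds == {"tip", "junction"}

    @property
    def is_bridge(self) -> bool:
        """True when both terminals are (distinct) junction clusters."""
        return self.a_kind == "junction" and self.b_kind == "junction"

    def euclidean_span(self) -> float:
        """Straight-line distance between the two terminal pixels."""
        return math.hypot(self.a[0] - self.b[0], self.a[1] - self.b[1])


@dataclass
class SkeletonGraph:
    """Node/edge decomposition of a one-pixel-wide skeleton."""

    skeleton: np.ndarray
    branch_points: list[tuple[int, int]]
    end_points: list[tuple[int, int]]
    edges: list[SkeletonEdge]
    isolated_points: list[tuple[int, int]] = field(default_factory=list)
    #: maps each branch pixel to the id of its 8-connected junction cluster
    cluster_of: dict[tuple[int, int], int] = field(default_factory=dict)

    @property
    def total_pixels(self) -> int:
        return int(self.skeleton.sum())

    def spur_edges(self) -> list[SkeletonEdge]:
        return [e for e in self.edges if e.is_spur]


def skeletonize(mask: np.ndarray) -> np.ndarray:
    """Thin a veins-as-foreground mask to a 1-pixel-wide centreline.

    An empty mask yields an empty skeleton (flagged downstream, not an
    error).
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        return np.zeros_like(mask, dtype=np.uint8)
    return _skimage_skeletonize(mask).astype(np.uint8)


def _neighbour_counts(skel: np.ndarray) -> np.ndarray:
    """8-connected foreground-neighbour count at every pixel."""
    return ndimage.convolve(skel.astype(np.uint8), _EIGHT, mode="constant") - skel


def _neighbours(skel: np.ndarray, p: tuple[int, int]) -> list[tuple[int, int]]:
    h, w = skel.shape
    r, c = p
    out = []
    for dr, dc in _NBR_OFFSETS:
        rr, cc = r + dr, c + dc
        if 0 <= rr < h and 0 <= cc < w and skel[rr, cc]:
            out.append((rr, cc))
    return out


def build_graph(skeleton: np.ndarray) -> SkeletonGraph:
    """Decompose a 1-pixel-wide skeleton into tips, branch points and edges.

    Pixels with >= 3 neighbours are branch points; touching branch pixels
    form one junction cluster and edges terminate on the cluster's boundary
    pixels. A connected component with no tips or branch points (a pure
    cycle) is stored as a single closed edge whose two terminals coincide.
    Isolated single pixels are retained in ``isolated_points``.
    """
    skel = np.asarray(skeleton).astype(np.uint8)
    counts = _neighbour_counts(skel)
    fg = skel.astype(bool)
    branch = fg & (counts >= 3)
    tips = fg & (counts == 1)
    isolated = fg & (counts == 0)

    branch_points = [tuple(p) for p in np.argwhere(branch)]
    end_points = [tuple(p) for p in np.argwhere(tips)]
    isolated_points = [tuple(p) for p in np.argwhere(isolated)]

    labels, _ = ndimage.label(branch, structure=_EIGHT)
    cluster_of = {p: int(labels[p]) for p in branch_points}

    is_node = branch | tips
    node_kind = {}
    for p in branch_points:
        node_kind[p] = "junction"
    for p in end_points:
        node_kind[p] = "tip"

    edges: list[SkeletonEdge] = []
    visited = np.zeros_like(fg, dtype=bool)  # interior path pixels consumed

    def _same_cluster(p, q) -> bool:
        return (node_kind.get(p) == "junction" and node_kind.get(q) == "junction"
                and cluster_of[p] == cluster_of[q])

    # Edges with at least one interior (non-node) pixel: walk from each node
    # through an unvisited path pixel until another node is reached.
    node_list = end_points + branch_points
    for start in node_list:
        for first in _neighbours(skel, start):
            if is_node[first] or visited[first]:
                continue
            path = [start, first]
            visited[first] = True
            prev, cur = start, first
            while True:
                nxt = None
                for q in _neighbours(skel, cur):
                    if q == prev:
                        continue
                    if is_node[q]:
                        nxt = q
                        break
                    if not visited[q]:
                        nxt = q
                if nxt is None:
                    # dead end without a terminal node: cannot happen on a
                    # well-formed skeleton, but guard by closing on cur
                    edges.append(SkeletonEdge(start, cur, tuple(path), len(path),
                                              node_kind[start], "tip"))
                    break
                if is_node[nxt]:
                    path.append(nxt)
                    edges.append(SkeletonEdge(start, nxt, tuple(path), len(path),
                                              node_kind[start], node_kind[nxt]))
                    break
                visited[nxt] = True
                path.append(nxt)
                prev, cur = cur, nxt

    # Directly adjacent node pixels (no interior): one 2-pixel edge each,
    # skipping pairs inside the same junction cluster.
    seen_pairs = set()
    for p in node_list:
        for q in _neighbours(skel, p):
            if not is_node[q] or _same_cluster(p, q):
                continue
            key = (min(p, q), max(p, q))
            if key in seen_pairs:
                continue
            seen_pairs.add(key)
            edges.append(SkeletonEdge(key[0], key[1], key, 2,
                                      node_kind[key[0]], node_kind[key[1]]))

    # Pure cycles: remaining foreground pixels that are neither nodes nor
    # consumed interior pixels.
    remaining = fg & ~is_node & ~visited & ~isolated
    if remaining.any():
        cyc_labels, n_cyc = ndimage.label(remaining, structure=_EIGHT)
        for lab in range(1, n_cyc + 1):
            pix = [tuple(p) for p in np.argwhere(cyc_labels == lab)]
            start = min(pix)
            path = [start]
            prev, cur = None, start
            while True:
                nxt = None
                for q in _neighbours(skel, cur):
                    if q == prev or q == start:
                        continue
                    if remaining[q] and q not in path[-2:]:
                        nxt = q
                        break
                if nxt is None or len(path) == len(pix):
                    break
                path.append(nxt)
                prev, cur = cur, nxt
            edges.append(SkeletonEdge(start, start, tuple(path), len(pix),
                                      "cycle", "cycle"))

    return SkeletonGraph(
        skeleton=skel,
        branch_points=branch_points,
        end_points=end_points,
        edges=edges,
        isolated_points=isolated_points,
        cluster_of=cluster_of,
    )


def _is_simple_point(mask: np.ndarray, p: tuple[int, int]) -> bool:
    """True when removing ``p`` cannot change the skeleton's topology:
    its foreground 8-neighbours form exactly one 8-connected component."""
    nbrs = _neighbours(mask, p)
    if not nbrs:
        return False
    remaining = set(nbrs[1:])
    frontier = [nbrs[0]]
    while frontier and remaining:
        q = frontier.pop()
        linked = {s for s in remaining
                  if abs(s[0] - q[0]) <= 1 and abs(s[1] - q[1]) <= 1}
        remaining -= linked
        frontier.extend(linked)
    return not remaining


def _delete_edges(graph: SkeletonGraph, edges: list[SkeletonEdge]) -> np.ndarray:
    """Return a copy of the skeleton with the given edges removed.

    Non-junction path pixels are deleted outright. A doomed edge's
    junction-side terminal is an edge pixel too, but deleting it could
    sever the veins meeting there; it is removed only while it is a simple
    point (candidates revisited in sorted order until stable), which clears
    the one-pixel nubs that diagonal adjacency otherwise leaves behind
    without ever breaking a surviving vein.
    """
    out = graph.skeleton.copy()
    branch_set = set(graph.branch_points)
    for e in edges:
        for p in e.path:
            if p not in branch_set:
                out[p] = 0
    candidates = sorted({t for e in edges for t in (e.path[0], e.path[-1])
                         if t in branch_set})
    changed = True
    while changed:
        changed = False
        for t in candidates:
            if out[t] and _is_simple_point(out, t):
                out[t] = 0
                changed = True
    return out


def trim_spurs(graph: SkeletonGraph | np.ndarray, trim_factor: int) -> np.ndarray:
    """Delete spur branches shorter than ``trim_factor`` pixels, iteratively.

    A spur is an edge running from a tip to a branch point; it is deleted
    when its pixel-count length is strictly below ``trim_factor`` (so
    ``trim_factor=0`` is the identity). Floating fragments below the trim
    scale — tip-to-tip segments and isolated single pixels shorter than
    ``trim_factor`` — are equally superfluous (noise specks, or remnants
    orphaned by an earlier deletion) and fall to the same rule.

    Deletion proceeds shortest-first: each round removes every deletable
    piece of the current minimum length, re-detects branch points, and
    repeats until no piece shorter than ``trim_factor`` remains. Pruning a
    spur can demote its junction and expose a new, longer spur, which later
    rounds then see. The shortest-first order makes the cascade for a
    larger trim factor a continuation of the cascade for a smaller one, so
    trimming is monotone in ``trim_factor`` (pixel sets only shrink) as
    well as idempotent.
    """
    if trim_factor < 0:
        raise ValueError("trim_factor must be >= 0")
    g = graph if isinstance(graph, SkeletonGraph) else build_graph(graph)
    skel = g.skeleton.copy()
    if trim_factor == 0:
        return skel
    while True:
        deletable = [e for e in g.edges
                     if e.is_spur or {e.a_kind, e.b_kind} == {"tip"}]
        lengths = [e.length for e in deletable]
        if g.isolated_points:
            lengths.append(1)
        lengths = [L for L in lengths if L < trim_factor]
        if not lengths:
            return skel
        lmin = min(lengths)
        doomed = [e for e in deletable if e.length == lmin]
        skel = _delete_edges(g, doomed)
        if lmin == 1:
            for p in g.isolated_points:
                skel[p] = 0
        g = build_graph(skel)


def auto_trim_factor(graph: SkeletonGraph, trigger_fraction: float,
                     user_trim_factor: int, border_margin: int = 0) -> int:
    """Derive the trim factor from the modal spur length when spurs dominate.

    Let S be the multiset of spur-edge lengths. When the fraction of
    skeleton pixels that belong exclusively to spurs exceeds
    ``trigger_fraction``, return ``mode(S) + 1`` (ties broken toward the
    smaller length), so that spurs of the modal length fall to the strict
    ``<`` trimming rule. Otherwise — including when there are no spurs —
    the user's trim factor is returned unchanged.

    A vein truncated by the image frame also ends in a tip, but it is real
    anatomy, not a thinning artefact: spurs whose tip lies within
    ``border_margin`` pixels of the image edge are excluded from S and from
    the trigger fraction (the pipeline sets the margin from the blur
    half-width, the scale over which a cut vein's skeleton recedes from the
    frame).
    """
    spurs = graph.spur_edges()
    if border_margin > 0:
        h, w = graph.skeleton.shape

        def _tip(e: SkeletonEdge) -> tuple[int, int]:
            return e.a if e.a_kind == "tip" else e.b

        spurs = [e for e in spurs
                 if not (min(_tip(e)[0], h - 1 - _tip(e)[0]) < border_margin
                         or min(_tip(e)[1], w - 1 - _tip(e)[1]) < border_margin)]
    total = graph.total_pixels
    if not spurs or total == 0:
        return int(user_trim_factor)
    branch_set = set(graph.branch_points)
    spur_pixels = sum(sum(1 for p in e.path if p not in branch_set) for e in spurs)
    if spur_pixels / total <= trigger_fraction:
        return int(user_trim_factor)
    counts = Counter(e.length for e in spurs)
    best = min(counts, key=lambda L: (-counts[L], L))
    return int(best) + 1


def remove_commissural(graph: SkeletonGraph, keep_length: float) -> np.ndarray:
    """Remove short transverse connections between longitudinal veins.

    Deletes every edge whose two terminals are branch points in *distinct*
    junction clusters and whose terminal-to-terminal Euclidean distance is
    strictly below ``keep_length`` pixels. ``keep_length=0`` disables
    removal entirely; spur (tip-ended) edges are never touched. Junction
    pixels themselves are preserved, so the longitudinal veins' pixel sets
    are unchanged.
    """
    if keep_length < 0:
        raise ValueError("keep_length must be >= 0")
    skel = graph.skeleton.copy()
    if keep_length == 0:
        return skel
    doomed = []
    for e in graph.edges:
        if not e.is_bridge:
            continue
        if graph.cluster_of.get(e.a) == graph.cluster_of.get(e.b):
            continue  # self-loop on one junction: not a commissural vein
        if e.euclidean_span() < keep_length:
            doomed.append(e)
    return _delete_edges(graph, doomed)


def diagonal_corrected_length(skeleton: np.ndarray) -> float:
    """Optional diagnostic: skeleton length counting diagonal steps as sqrt(2).

    The pipeline's primary length estimate is the raw pixel count; this
    alternative weights each adjacency by its step length (1 for axial,
    sqrt(2) for diagonal) and sums half the per-pixel incident step lengths.
    """
    skel = np.asarray(skeleton).astype(bool)
    length = 0.0
    for p in map(tuple, np.argwhere(skel)):
        for dr, dc in _NBR_OFFSETS:
            q = (p[0] + dr, p[1] + dc)
            if 0 <= q[0] < skel.shape[0] and 0 <= q[1] < skel.shape[1] and skel[q]:
                length += math.hypot(dr, dc) / 2.0
    # a pixel with no neighbours still contributes one unit
    counts = _neighbour_counts(skel.astype(np.uint8))
    length += float(((counts == 0) & skel).sum())
    return length
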