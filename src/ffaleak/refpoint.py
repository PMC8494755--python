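"""Optic-disk reference point detection by skeleton-graph line voting.

Large retinal vessels radiate from the optic disk, so prolonging their local
directions produces lines that intersect near a single stable point.  The
detector:

1. thins the large-vessel mask to a 1-pixel medial axis;
2. builds a graph whose nodes are skeleton bifurcations (>= 3 neighbors) and
   terminations (exactly 1 neighbor) and whose edges carry the ordered
   medial-axis pixel chain between them;
3. iteratively prunes terminal branches shorter than ``T_b`` pixels;
4. for every chain pixel, fits a total-least-squares line to the chain
   points within a circle of radius ``L_0`` and draws the full line into an
   accumulator array;
5. returns the argmax of the (lightly smoothed) accumulator.

The detected point is stable across timepoints of the same eye and seeds the
rigid registration.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import ndimage as ndi
from skimage.draw import line as draw_line
from skimage.morphology import skeletonize as _sk_skeletonize

from .io_core import FFAImage
from .morphology import OpeningParams
from .segmentation import large_vessel_mask

__all__ = [
    "VesselGraph",
    "LineFit",
    "Accumulator",
    "ReferencePointError",
    "skeletonize",
    "build_graph",
    "prune",
    "fit_local_line",
    "vote",
    "reference_point",
    "reference_point_from_mask",
]

_K8 = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]])


class ReferencePointError(RuntimeError):
    """Raised when no vessel structure is available to vote from."""


@dataclass
class VesselGraph:
    """Topology of a vessel skeleton.

    ``graph`` is a :class:`networkx.MultiGraph`; node attributes are
    ``pixel`` (representative (row, col)), ``pixels`` (all skeleton pixels
    merged into the node) and ``kind`` (``bifurcation`` / ``termination`` /
    ``anchor`` for node-free cycles).  Edge attribute ``chain`` is the
    ordered medial-axis pixel list, endpoints included.
    """

    graph: nx.MultiGraph
    skeleton: np.ndarray
    shape: tuple[int, int] = field(init=False)

    def __post_init__(self) -> None:
        self.shape = self.skeleton.shape

    @property
    def chains(self) -> list[list[tuple[int, int]]]:
        return [d["chain"] for _, _, d in self.graph.edges(data=True)]

    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class LineFit:
    """A local total-least-squares line: unit direction through a point."""

    point: np.ndarray  # (row, col) centroid of the window
    direction: np.ndarray  # unit (drow, dcol)


@dataclass
class Accumulator:
    """Vote grid; ``total_votes`` equals the summed in-frame length of all drawn lines."""

    A: np.ndarray
    total_votes: int


def skeletonize(mask: np.ndarray) -> np.ndarray:
    """1-pixel-wide, topology-preserving 8-connected medial axis (thinning)."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.zeros(mask.shape, dtype=bool)
    return _sk_skeletonize(mask)


def _neighbor_degree(skel: np.ndarray) -> np.ndarray:
    return ndi.convolve(skel.astype(np.uint8), _K8, mode="constant") * skel


def _adjacent(p: tuple[int, int], q: tuple[int, int]) -> bool:
    return max(abs(p[0] - q[0]), abs(p[1] - q[1])) == 1 or p == q


_OFFSETS8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _order_chain(comp_pixels: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Order the pixels of a degree-<=2 component into a path (or cycle)."""
    if len(comp_pixels) == 1:
        return list(comp_pixels)
    pix = set(comp_pixels)
    nbrs = {
        p: [(p[0] + dr, p[1] + dc) for dr, dc in _OFFSETS8 if (p[0] + dr, p[1] + dc) in pix]
        for p in pix
    }
    ends = sorted(p for p, ns in nbrs.items() if len(ns) <= 1)
    start = ends[0] if ends else min(pix)  # cycle: anchor at scan-order min
    chain = [start]
    prev = None
    cur = start
    while True:
        nxt = [q for q in nbrs[cur] if q != prev]
        if not nxt:
            break
        # Prefer 4-adjacent continuation to avoid diagonal shortcuts in staircases.
        nxt.sort(key=lambda q: (abs(q[0] - cur[0]) + abs(q[1] - cur[1]), q))
        prev, cur = cur, nxt[0]
        if cur == start:
            break
        chain.append(cur)
        if len(chain) > len(comp_pixels):  # safety; cannot happen on valid skeletons
            break
    return chain


def build_graph(skeleton: np.ndarray) -> VesselGraph:
    """Graph of bifurcations/terminations connected by medial-axis chains.

    Mutually adjacent bifurcation pixels (thinning often emits 2x2 junction
    blocks) are merged into a single node at their centroid.  A closed loop
    with no node pixels becomes one cyclic self-edge anchored at its
    scan-order-first pixel.
    """
    skeleton = np.asarray(skeleton, dtype=bool)
    g = nx.MultiGraph()
    deg = _neighbor_degree(skeleton)
    bif = skeleton & (deg >= 3)
    term = skeleton & (deg == 1)
    isolated = skeleton & (deg == 0)

    node_px = bif | term | isolated
    node_id_of: dict[tuple[int, int], int] = {}
    next_id = 0

    # Bifurcation clusters (8-connected) collapse into one node.
    lab, n_lab = ndi.label(bif, structure=np.ones((3, 3)))
    for k in range(1, n_lab + 1):
        pts = [tuple(p) for p in np.argwhere(lab == k)]
        centroid = tuple(np.round(np.mean(pts, axis=0)).astype(int))
        g.add_node(next_id, pixel=centroid, pixels=pts, kind="bifurcation")
        for p in pts:
            node_id_of[p] = next_id
        next_id += 1
    for mask, kind in ((term, "termination"), (isolated, "termination")):
        for p in map(tuple, np.argwhere(mask)):
            g.add_node(next_id, pixel=p, pixels=[p], kind=kind)
            node_id_of[p] = next_id
            next_id += 1

    # Chains = skeleton minus node pixels.
    chain_mask = skeleton & ~node_px
    lab, n_lab = ndi.label(chain_mask, structure=np.ones((3, 3)))
    comp_pixels: dict[int, list[tuple[int, int]]] = {k: [] for k in range(1, n_lab + 1)}
    for p in map(tuple, np.argwhere(chain_mask)):
        comp_pixels[lab[p]].append(p)

    linked_node_pairs = set()
    for pts in comp_pixels.values():
        chain = _order_chain(pts)
        ends = [chain[0], chain[-1]]
        attach = []
        end_cands = []
        for e in ends:
            cands = sorted(
                (e[0] + dr, e[1] + dc)
                for dr, dc in _OFFSETS8
                if (e[0] + dr, e[1] + dc) in node_id_of
            )
            end_cands.append(cands)
            attach.append(node_id_of[cands[0]] if cands else None)
        n0, n1 = attach
        if len(chain) == 1 and n0 is not None and n0 == n1:
            # single-pixel chain between two distinct adjacent nodes: attach
            # the second end to the next distinct node if one exists
            others = [node_id_of[c] for c in end_cands[1] if node_id_of[c] != n0]
            if others:
                n1 = others[0]
        if n0 is None and n1 is None:
            # node-free cycle: anchor a node at the first chain pixel
            anchor = chain[0]
            g.add_node(next_id, pixel=anchor, pixels=[anchor], kind="anchor")
            g.add_edge(next_id, next_id, chain=chain + [chain[0]])
            next_id += 1
            continue
        if n0 is None or n1 is None:
            # dangling chain end (possible when the nearest node pixel was on
            # the chain's flank); treat the free end as a termination
            free_end = ends[0] if n0 is None else ends[-1]
            g.add_node(next_id, pixel=free_end, pixels=[free_end], kind="termination")
            if n0 is None:
                n0 = next_id
            else:
                n1 = next_id
            next_id += 1
        full = [_node_attach_pixel(g, n0, chain[0])] + chain + [_node_attach_pixel(g, n1, chain[-1])]
        g.add_edge(n0, n1, chain=full)
        linked_node_pairs.add(frozenset((n0, n1)))

    # Directly adjacent node clusters with no chain pixels in between.
    for p, na in node_id_of.items():
        for dr, dc in _OFFSETS8:
            q = (p[0] + dr, p[1] + dc)
            nb = node_id_of.get(q)
            if nb is not None and nb != na:
                key = frozenset((na, nb))
                if key not in linked_node_pairs:
                    g.add_edge(na, nb, chain=[p, q])
                    linked_node_pairs.add(key)

    return VesselGraph(g, skeleton)


def _node_attach_pixel(g: nx.MultiGraph, node: int, chain_end: tuple[int, int]) -> tuple[int, int]:
    """The node's skeleton pixel adjacent to the chain end (for chain endpoints)."""
    for p in g.nodes[node]["pixels"]:
        if _adjacent(p, chain_end) and p != chain_end:
            return p
    return g.nodes[node]["pixel"]


def prune(vgraph: VesselGraph, T_b: int) -> VesselGraph:
    """Iteratively delete terminal branches shorter than ``T_b`` pixels.

    A terminal edge has a termination node at (at least) one end.  Removing a
    branch may turn a bifurcation into a pass-through pixel or expose new
    short branches, so the skeleton is re-analyzed between passes until no
    deletable branch remains.  Non-terminal edges are never deleted.
    """
    if T_b < 0:
        raise ValueError("T_b must be >= 0")
    skel = vgraph.skeleton.copy()
    while True:
        g = build_graph(skel)
        removed = False
        doomed: set[tuple[int, int]] = set()
        for u, v, d in g.graph.edges(data=True):
            if len(d["chain"]) >= T_b:
                continue
            ku, kv = g.graph.nodes[u]["kind"], g.graph.nodes[v]["kind"]
            if "termination" not in (ku, kv):
                continue
            # delete chain pixels plus the termination-end node pixels,
            # keeping any junction-end node pixels
            px = set(d["chain"])
            for n, kind in ((u, ku), (v, kv)):
                if kind == "termination":
                    px.update(g.graph.nodes[n]["pixels"])
                else:
                    px.difference_update(g.graph.nodes[n]["pixels"])
            doomed.update(px)
            removed = True
        if not removed:
            return g
        for r, c in doomed:
            skel[r, c] = False
        # re-thin: branch removal can leave bump pixels at ex-junctions
        # (diagonal staircases), which must not survive as parasite loops
        skel = skeletonize(skel)


def fit_local_line(chain, p_i: int, L_0: float) -> LineFit | None:
    """Total-least-squares line through chain points within ``L_0`` of point ``p_i``.

    Returns None when fewer than two distinct points fall in the window.
    The principal axis handles vertical vessels, where ordinary regression
    on rows would be degenerate.
    """
    pts = np.asarray(chain, dtype=float)
    d2 = ((pts - pts[p_i]) ** 2).sum(axis=1)
    win = pts[d2 <= L_0**2]
    if len(np.unique(win, axis=0)) < 2:
        return None
    centroid = win.mean(axis=0)
    x = win - centroid
    sxx, syy = (x[:, 0] ** 2).sum(), (x[:, 1] ** 2).sum()
    sxy = (x[:, 0] * x[:, 1]).sum()
    ang = 0.5 * math.atan2(2 * sxy, sxx - syy)
    direction = np.array([math.cos(ang), math.sin(ang)])
    return LineFit(point=centroid, direction=direction)


def _clip_line_to_frame(point: np.ndarray, direction: np.ndarray, shape) -> tuple | None:
    """Endpoints (integer) of the full line through `point` clipped to the frame."""
    h, w = shape
    t_min, t_max = -np.inf, np.inf
    for k, lim in ((0, h - 1), (1, w - 1)):
        d, p = direction[k], point[k]
        if abs(d) < 1e-12:
            if not (0 <= p <= lim):
                return None
        else:
            t0, t1 = (0 - p) / d, (lim - p) / d
            t_min = max(t_min, min(t0, t1))
            t_max = min(t_max, max(t0, t1))
    if not np.isfinite(t_min) or not np.isfinite(t_max) or t_min > t_max:
        return None
    e0 = np.clip(np.round(point + t_min * direction).astype(int), [0, 0], [h - 1, w - 1])
    e1 = np.clip(np.round(point + t_max * direction).astype(int), [0, 0], [h - 1, w - 1])
    return tuple(e0), tuple(e1)


def vote(vgraph: VesselGraph, L_0: float, shape=None, stride: int = 1) -> Accumulator:
    """Accumulate full-frame lines from local fits at every chain pixel.

    Each emitted line adds one vote per rasterized in-frame pixel; the total
    vote count is conserved as the sum of rasterized lengths.  ``stride``
    optionally subsamples chain pixels (default: every pixel votes).
    """
    shape = shape or vgraph.shape
    A = np.zeros(shape, dtype=np.int64)
    total = 0
    chains = vgraph.chains
    if not chains:
        warnings.warn("empty vessel graph: zero accumulator")
        return Accumulator(A, 0)
    L2 = float(L_0) ** 2
    for chain in chains:
        pts = np.asarray(chain, dtype=float)
        m = len(pts)
        if m < 2:
            continue
        # pairwise window membership and vectorized window means
        from scipy.spatial.distance import cdist

        W = cdist(pts, pts, "sqeuclidean") <= L2
        n = W.sum(1)
        means = (W @ pts) / n[:, None]
        for i in range(0, m, stride):
            if n[i] < 2:
                continue
            wpts = pts[W[i]] - means[i]
            if not (np.abs(wpts) > 0).any():
                continue
            sxx, syy = (wpts[:, 0] ** 2).sum(), (wpts[:, 1] ** 2).sum()
            sxy = (wpts[:, 0] * wpts[:, 1]).sum()
            ang = 0.5 * math.atan2(2 * sxy, sxx - syy)
            direction = np.array([math.cos(ang), math.sin(ang)])
            seg = _clip_line_to_frame(means[i], direction, shape)
            if seg is None:
                continue
            rr, cc = draw_line(*seg[0], *seg[1])
            A[rr, cc] += 1
            total += len(rr)
    return Accumulator(A, total)


def reference_point_from_mask(
    mask: np.ndarray,
    T_b: int = 20,
    L_0: float = 30.0,
    smooth_sigma: float = 2.0,
) -> tuple[int, int]:
    """Convergence point from an existing large-vessel mask."""
    if not np.asarray(mask, dtype=bool).any():
        raise ReferencePointError("reference point unavailable: no vessels detected")
    skel = skeletonize(mask)
    vg = prune(build_graph(skel), T_b)
    acc = vote(vg, L_0)
    if acc.total_votes == 0:
        raise ReferencePointError("reference point unavailable: no votes cast")
    smoothed = ndi.gaussian_filter(acc.A.astype(float), smooth_sigma)
    idx = int(np.argmax(smoothed))  # scan-order tie-break
    return tuple(int(v) for v in np.unravel_index(idx, acc.A.shape))


def reference_point(
    image: FFAImage,
    T_b: int = 20,
    L_0: float = 30.0,
    params: OpeningParams | None = None,
    hyst_quantiles: tuple[float, float] = (0.85, 0.97),
    n_s: int = 2,
    sigma: float = 3.0,
) -> tuple[int, int]:
    """Detect the vessel convergence point of a frame.

    Composes large-vessel masking, thinning, graph pruning at branch-length
    threshold ``T_b`` and line voting at analysis scale ``L_0``; ties in the
    accumulator break by scan order (smallest row, then column).
    """
    mask = large_vessel_mask(image, params, hyst_quantiles, n_s, sigma)
    return reference_point_from_mask(mask, T_b=T_b, L_0=L_0)
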