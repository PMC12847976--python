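"""Skeletonization, branch/junction graph extraction and the 15 descriptors.

A skeleton pixel with >= 3 8-neighbors is a junction pixel; 8-adjacent
junction pixels are merged into a single junction node so that an
X-crossing counts once. Pixels with exactly one neighbor are endpoints,
isolated pixels are their own nodes, and the remaining degree-2 pixels form
edge paths. Edge length is geometric: axial steps count 1, diagonal steps
sqrt(2).
"""
from __future__ import annotations

import math
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage.morphology import convex_hull_image, skeletonize as _skeletonize

from .types import (
    DESCRIPTOR_NAMES,
    ChipGeometry,
    SkeletonEdge,
    SkeletonGraph,
    SkeletonNode,
    VesselDescriptors,
    VesselMask,
)

_STRUCT8 = np.ones((3, 3), dtype=bool)
_SQRT2 = math.sqrt(2.0)
_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def skeletonize_mask(mask: VesselMask) -> np.ndarray:
    """1-px-wide, topology-preserving medial skeleton of thin+thick union."""
    return _skeletonize(mask.vessel)


def _step(a: tuple[int, int], b: tuple[int, int]) -> float:
    return _SQRT2 if (a[0] != b[0] and a[1] != b[1]) else 1.0


def neighbor_degrees(skel: np.ndarray) -> np.ndarray:
    """Number of 8-neighbors of each skeleton pixel (0 elsewhere)."""
    s = skel.astype(np.uint8)
    kernel = np.ones((3, 3), dtype=np.uint8)
    kernel[1, 1] = 0
    return ndimage.convolve(s, kernel, mode="constant") * s


def build_graph(skel: np.ndarray) -> SkeletonGraph:
    """Convert a binary skeleton into its branch/junction graph.

    Every skeleton pixel ends up in exactly one node cluster or one edge
    path. Cycles without any junction (closed loops) are represented as a
    self-loop on a single bookkeeping node of kind ``"isolated"``.
    """
    skel = np.asarray(skel, dtype=bool)
    nr, nc = skel.shape
    deg = neighbor_degrees(skel)

    junction_px = skel & (deg >= 3)
    jlab, n_j = ndimage.label(junction_px, structure=_STRUCT8)

    nodes: list[SkeletonNode] = []
    node_of_pixel: dict[tuple[int, int], int] = {}
    for j in range(1, n_j + 1):
        pix = np.argwhere(jlab == j)
        nid = len(nodes)
        nodes.append(
            SkeletonNode(
                id=nid,
                kind="junction",
                coordinate=tuple(pix.mean(axis=0)),
                pixels=pix,
            )
        )
        for r, c in pix:
            node_of_pixel[(int(r), int(c))] = nid

    for r, c in np.argwhere(skel & (deg == 1)):
        nid = len(nodes)
        nodes.append(
            SkeletonNode(id=nid, kind="endpoint", coordinate=(float(r), float(c)),
                         pixels=np.array([[r, c]]))
        )
        node_of_pixel[(int(r), int(c))] = nid
    for r, c in np.argwhere(skel & (deg == 0)):
        nid = len(nodes)
        nodes.append(
            SkeletonNode(id=nid, kind="isolated", coordinate=(float(r), float(c)),
                         pixels=np.array([[r, c]]))
        )
        node_of_pixel[(int(r), int(c))] = nid

    is_path = skel & (deg == 2) & ~junction_px
    edges: list[SkeletonEdge] = []
    visited = np.zeros(skel.shape, dtype=bool)

    def skel_neighbors(p: tuple[int, int]):
        r, c = p
        for dr, dc in _NEIGHBORS:
            rr, cc = r + dr, c + dc
            if 0 <= rr < nr and 0 <= cc < nc and skel[rr, cc]:
                yield (rr, cc)

    def walk(start_node: int, anchor: tuple[int, int], first: tuple[int, int]) -> None:
        """Trace an edge path starting from node pixel ``anchor`` into path
        pixel ``first``; terminates at the next node pixel reached."""
        path = [first]
        visited[first] = True
        length = _step(anchor, first)
        prev, cur = anchor, first
        while True:
            nxt = None
            for nb in skel_neighbors(cur):
                if nb == prev:
                    continue
                if is_path[nb] and not visited[nb]:
                    nxt = nb
                    break
                if nb in node_of_pixel:
                    nxt = nb
                    break
            if nxt is None:
                # closed back onto the anchor's own cluster through `prev`
                end_node = start_node
                length += 0.0
                break
            length += _step(cur, nxt)
            if nxt in node_of_pixel:
                end_node = node_of_pixel[nxt]
                break
            path.append(nxt)
            visited[nxt] = True
            prev, cur = cur, nxt
        edges.append(
            SkeletonEdge(u=start_node, v=end_node, path=np.array(path), length=length)
        )

    # edges leaving each node through a path pixel
    for node in nodes:
        for r, c in node.pixels:
            for nb in skel_neighbors((int(r), int(c))):
                if is_path[nb] and not visited[nb]:
                    walk(node.id, (int(r), int(c)), nb)

    # direct node-to-node contacts (no path pixels in between)
    seen_pairs: set[tuple] = set()
    for node in nodes:
        for r, c in node.pixels:
            p = (int(r), int(c))
            for nb in skel_neighbors(p):
                other = node_of_pixel.get(nb)
                if other is None or other == node.id:
                    continue
                key = (min(p, nb), max(p, nb))
                if key in seen_pairs:
                    continue
                seen_pairs.add(key)
                edges.append(
                    SkeletonEdge(u=node.id, v=other, path=np.empty((0, 2), dtype=int),
                                 length=_step(p, nb))
                )

    # pure cycles: leftover unvisited path pixels with no adjacent node
    leftover = is_path & ~visited
    if leftover.any():
        clab, n_c = ndimage.label(leftover, structure=_STRUCT8)
        for j in range(1, n_c + 1):
            pix = np.argwhere(clab == j)
            p0 = (int(pix[0, 0]), int(pix[0, 1]))
            nid = len(nodes)
            nodes.append(
                SkeletonNode(id=nid, kind="isolated", coordinate=(float(p0[0]), float(p0[1])),
                             pixels=np.array([p0]))
            )
            node_of_pixel[p0] = nid
            is_path[p0] = False
            nbs = [nb for nb in skel_neighbors(p0) if is_path[nb] and not visited[nb]]
            if nbs:
                walk(nid, p0, nbs[0])

    return SkeletonGraph(nodes=nodes, edges=edges, shape=skel.shape)


def prune_spurs(skel: np.ndarray, graph: Optional[SkeletonGraph] = None,
                min_length: float = 3.0) -> tuple[np.ndarray, SkeletonGraph]:
    """Remove endpoint-terminated spur edges shorter than ``min_length`` px.

    Spurs are skeletonization artifacts at vessel boundaries. The spur's
    path pixels and its endpoint pixel are erased and the graph rebuilt, so
    a junction reduced to degree 2 dissolves into a through-path. Whole
    isolated segments (endpoint to endpoint) are never pruned.
    """
    skel = np.asarray(skel, dtype=bool).copy()
    if graph is None:
        graph = build_graph(skel)
    kinds = {n.id: n.kind for n in graph.nodes}
    pixels = {n.id: n.pixels for n in graph.nodes}
    changed = False
    touched_clusters: list[np.ndarray] = []
    for e in graph.edges:
        if e.length >= min_length:
            continue
        ku, kv = kinds[e.u], kinds[e.v]
        if ku == "endpoint" and kv == "junction":
            tip, junc = e.u, e.v
        elif kv == "endpoint" and ku == "junction":
            tip, junc = e.v, e.u
        else:
            continue
        for r, c in e.path:
            skel[r, c] = False
        for r, c in pixels[tip]:
            skel[r, c] = False
        touched_clusters.append(pixels[junc])
        changed = True
    if changed:
        _erode_simple_nubs(skel, touched_clusters)
        graph = build_graph(skel)
    return skel, graph


def _erode_simple_nubs(skel: np.ndarray, clusters: list[np.ndarray]) -> None:
    """Remove leftover 1-px protrusions inside spur-adjacent junction clusters.

    A pixel is removed only if it is a simple point (its remaining skeleton
    neighbors form a single 8-connected component, so topology is kept) and
    it has >= 2 neighbors (never erodes genuine line ends). In place.
    """
    nr, nc = skel.shape
    candidates = {(int(r), int(c)) for pix in clusters for r, c in pix}
    stable = False
    while not stable:
        stable = True
        for r, c in sorted(candidates):
            if not skel[r, c]:
                continue
            patch = skel[max(0, r - 1) : r + 2, max(0, c - 1) : c + 2].copy()
            pr, pc = r - max(0, r - 1), c - max(0, c - 1)
            patch[pr, pc] = False
            n_fg = int(patch.sum())
            if n_fg < 2:
                continue
            _, n_comp = ndimage.label(patch, structure=_STRUCT8)
            if n_comp != 1:
                continue
            # all remaining neighbors must stay mutually connected locally;
            # additionally require the pixel to be a protrusion, i.e. its
            # removal does not split the 3x3 ring: n_comp == 1 guarantees it
            skel[r, c] = False
            stable = False


def compute_descriptors(
    mask: VesselMask,
    graph: SkeletonGraph,
    geometry: ChipGeometry,
) -> VesselDescriptors:
    """Compute the 15 per-chip vascular descriptors.

    Densities divide class areas by the center-circle ("glass hole") area;
    the branching index divides the junction count by the total vessel area;
    the average width is total area over total skeleton length; the
    inside/outside ratios compare class areas inside the center circle with
    those outside it (within the compartment). Degenerate denominators yield
    NaN plus a flag; an empty mask yields all zeros with the ``empty_mask``
    flag.
    """
    vessel = mask.vessel
    flags: list[str] = []
    if not vessel.any():
        return VesselDescriptors(flags=("empty_mask",))

    thick_area = float(mask.thick.sum())
    thin_area = float(mask.thin.sum())
    total_area = thick_area + thin_area
    explant_area = float(convex_hull_image(vessel).sum())

    circle = geometry.center_mask()
    circle_area = float(circle.sum())
    inside = geometry.compartment_mask()

    n_junctions = float(graph.n_junctions)
    total_length = graph.total_length
    n_edges = len(graph.edges)

    def ratio(num: float, den: float, flag: str) -> float:
        if den == 0:
            flags.append(flag)
            return float("nan")
        return num / den

    total_in = float((vessel & circle).sum())
    total_out = float((vessel & ~circle & inside).sum())
    thick_in = float((mask.thick & circle).sum())
    thick_out = float((mask.thick & ~circle & inside).sum())

    avg_width = total_area / total_length if total_length > 0 else 0.0
    if total_length == 0:
        flags.append("zero_length")

    return VesselDescriptors(
        explant_area=explant_area,
        thick_area=thick_area,
        thin_area=thin_area,
        total_area=total_area,
        thick_density=thick_area / circle_area,
        thin_density=thin_area / circle_area,
        total_density=total_area / circle_area,
        n_junctions=n_junctions,
        branching_index=n_junctions / total_area,
        total_length=total_length,
        avg_branch_length=total_length / n_edges if n_edges else 0.0,
        avg_width=avg_width,
        thick_total_area_ratio=thick_area / total_area,
        inout_total_ratio=ratio(total_in, total_out, "inout_total_ratio"),
        inout_thick_ratio=ratio(thick_in, thick_out, "inout_thick_ratio"),
        flags=tuple(flags),
    )


def measure_chip(
    mask: VesselMask,
    geometry: ChipGeometry,
    spur_min_length: float = 3.0,
) -> tuple[VesselDescriptors, SkeletonGraph]:
    """Mask -> skeleton -> pruned graph -> descriptors, in one call."""
    skel = skeletonize_mask(mask)
    skel, graph = prune_spurs(skel, min_length=spur_min_length)
    return compute_descriptors(mask, graph, geometry), graph


__all__ = [
    "DESCRIPTOR_NAMES",
    "skeletonize_mask",
    "neighbor_degrees",
    "build_graph",
    "prune_spurs",
    "compute_descriptors",
    "measure_chip",
]
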