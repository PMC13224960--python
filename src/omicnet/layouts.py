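"""Layout algorithms: classical delegates, polygon/grouped/packed/
multi-layer placements, polygon-constrained sampling, and affine
transforms of coordinate sets.

Conventions (fixed in :mod:`omicnet.config`): circular placements start
at 90 degrees (12 o'clock) and proceed counter-clockwise on the unit
circle; polygon vertices follow the same rule.  Seeded algorithms are
bit-reproducible for a given seed.
"""

from __future__ import annotations

import math

import networkx as nx
import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from . import config
from .model import Coors

__all__ = [
    "c_net_layout",
    "as_polygon",
    "as_polycircle",
    "spatstat_layout",
    "g_layout",
    "g_layout_circlepack",
    "g_layout_multi_layer",
    "transform_coors",
    "LAYOUT_REGISTRY",
]


def _coors_from_dict(pos: dict, groups: dict | None = None,
                     group_meta: dict | None = None) -> Coors:
    rows = [{"node": n, "x": float(x), "y": float(y)} for n, (x, y) in pos.items()]
    table = pd.DataFrame(rows, columns=["node", "x", "y"])
    if groups is not None:
        table["group"] = [groups.get(n) for n in table["node"]]
    return Coors(table=table, group_meta=group_meta or {})


def _circle_positions(nodes, radius: float = 1.0, center=(0.0, 0.0)) -> dict:
    n = len(nodes)
    start = math.radians(config.ANGLE_START_DEG)
    return {
        node: (center[0] + radius * math.cos(start + 2 * math.pi * k / n),
               center[1] + radius * math.sin(start + 2 * math.pi * k / n))
        for k, node in enumerate(nodes)
    }


# --------------------------------------------------------------------------
# registry of basic layouts

def _layout_circle(net, params, seed):
    return _circle_positions(list(net.nodes))


def _layout_grid(net, params, seed):
    nodes = list(net.nodes)
    cols = params.get("cols") or math.ceil(math.sqrt(len(nodes)))
    return {node: (float(k % cols), float(k // cols)) for k, node in enumerate(nodes)}


def _layout_star(net, params, seed):
    nodes = list(net.nodes)
    if len(nodes) == 1:
        return {nodes[0]: (0.0, 0.0)}
    pos = _circle_positions(nodes[1:])
    pos[nodes[0]] = (0.0, 0.0)
    return pos


def _layout_tree(net, params, seed):
    root = params.get("root", next(iter(net.nodes)))
    return {n: (float(x), float(y)) for n, (x, y) in nx.bfs_layout(net, root).items()}


def _layout_force(net, params, seed):
    pos = nx.spring_layout(net, seed=seed, **{k: v for k, v in params.items()
                                              if k in ("k", "iterations")})
    return {n: (float(x), float(y)) for n, (x, y) in pos.items()}


def _layout_random(net, params, seed):
    pos = nx.random_layout(net, seed=seed)
    return {n: (float(x), float(y)) for n, (x, y) in pos.items()}


def _layout_kamada_kawai(net, params, seed):
    pos = nx.kamada_kawai_layout(net)
    return {n: (float(x), float(y)) for n, (x, y) in pos.items()}


LAYOUT_REGISTRY = {
    "circle": _layout_circle,
    "grid": _layout_grid,
    "star": _layout_star,
    "tree": _layout_tree,
    "force_directed": _layout_force,
    "random": _layout_random,
    "kamada_kawai": _layout_kamada_kawai,
}


def c_net_layout(net: nx.Graph, algorithm: str = "circle",
                 params: dict | None = None, seed: int | None = None) -> Coors:
    """Dispatch to a registered layout; seeded algorithms are reproducible."""
    if algorithm not in LAYOUT_REGISTRY:
        raise ValueError(
            f"unknown algorithm {algorithm!r}; registry: {sorted(LAYOUT_REGISTRY)}")
    pos = LAYOUT_REGISTRY[algorithm](net, params or {}, seed)
    return _coors_from_dict(pos)


# --------------------------------------------------------------------------
# polygon-family layouts

def _regular_polygon_vertices(n_sides: int, radius: float = 1.0) -> np.ndarray:
    start = math.radians(config.ANGLE_START_DEG)
    ang = start + 2 * np.pi * np.arange(n_sides) / n_sides
    return np.column_stack([radius * np.cos(ang), radius * np.sin(ang)])


def as_polygon(net: nx.Graph, groups: dict, n_sides: int) -> Coors:
    """Place each group's nodes evenly along one side of a regular polygon.

    The polygon is inscribed in the unit circle with vertex 1 at 90
    degrees; groups take sides in sorted-label order, and a side's k
    nodes sit at fractions 1/(k+1) .. k/(k+1) of the open segment
    (vertices excluded).
    """
    labels = sorted({groups[n] for n in net.nodes}, key=str)
    _check_groups(net, groups)
    if len(labels) > n_sides:
        raise ValueError(f"{len(labels)} groups exceed {n_sides} sides")
    verts = _regular_polygon_vertices(n_sides)
    pos = {}
    meta = {}
    for g_idx, label in enumerate(labels):
        a = verts[g_idx]
        b = verts[(g_idx + 1) % n_sides]
        members = sorted((n for n in net.nodes if groups[n] == label), key=str)
        k = len(members)
        for j, node in enumerate(members, start=1):
            t = j / (k + 1)
            pos[node] = tuple(a + t * (b - a))
        meta[label] = {"side": g_idx, "endpoints": (tuple(a), tuple(b))}
    return _coors_from_dict(pos, groups=groups, group_meta=meta)


def as_polycircle(net: nx.Graph, groups: dict, n_polygons: int) -> Coors:
    """One circle per group, circle centers on the vertices of a regular
    polygon (unit circumradius); within-group placement follows the
    circle convention at radius ``config.POLYCIRCLE_RADIUS``."""
    labels = sorted({groups[n] for n in net.nodes}, key=str)
    _check_groups(net, groups)
    if len(labels) > n_polygons:
        raise ValueError(f"{len(labels)} groups exceed {n_polygons} polygon vertices")
    verts = _regular_polygon_vertices(n_polygons)
    pos = {}
    meta = {}
    for g_idx, label in enumerate(labels):
        center = tuple(verts[g_idx])
        members = sorted((n for n in net.nodes if groups[n] == label), key=str)
        pos.update(_circle_positions(members, radius=config.POLYCIRCLE_RADIUS,
                                     center=center))
        meta[label] = {"anchor": center, "scale": config.POLYCIRCLE_RADIUS}
    return _coors_from_dict(pos, groups=groups, group_meta=meta)


def _check_groups(net, groups):
    missing = [n for n in net.nodes if n not in groups]
    if missing:
        raise ValueError(f"nodes without group: {missing[:5]}")


# --------------------------------------------------------------------------
# polygon-constrained placement

def _ear_clip(ring: np.ndarray) -> list[np.ndarray]:
    """Triangulate a simple polygon (no holes) by ear clipping."""
    pts = [np.asarray(p, dtype=float) for p in ring]
    # signed area > 0 <=> counter-clockwise
    area2 = sum(pts[i][0] * pts[(i + 1) % len(pts)][1]
                - pts[(i + 1) % len(pts)][0] * pts[i][1] for i in range(len(pts)))
    if area2 < 0:
        pts = pts[::-1]
    idx = list(range(len(pts)))
    tris = []

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    def point_in_tri(p, a, b, c):
        d1, d2, d3 = cross(a, b, p), cross(b, c, p), cross(c, a, p)
        return (d1 >= -1e-12) and (d2 >= -1e-12) and (d3 >= -1e-12)

    guard = 0
    while len(idx) > 3 and guard < 10000:
        guard += 1
        n = len(idx)
        clipped = False
        for k in range(n):
            i0, i1, i2 = idx[(k - 1) % n], idx[k], idx[(k + 1) % n]
            a, b, c = pts[i0], pts[i1], pts[i2]
            if cross(a, b, c) <= 1e-14:   # reflex or degenerate corner
                continue
            if any(point_in_tri(pts[j], a, b, c)
                   for j in idx if j not in (i0, i1, i2)):
                continue
            tris.append(np.array([a, b, c]))
            idx.pop(k)
            clipped = True
            break
        if not clipped:
            raise ValueError("ear clipping failed: polygon may be degenerate")
    tris.append(np.array([pts[idx[0]], pts[idx[1]], pts[idx[2]]]))
    return tris


def spatstat_layout(net: nx.Graph, polygon, mode: str = "uniform_inside",
                    seed: int | None = None) -> Coors:
    """Constrain node placement to a simple polygon.

    ``uniform_inside`` (and its alias ``random_inside``) samples points
    uniformly over the polygon area: ear-clip triangulation, triangle
    chosen with probability proportional to area, uniform barycentric
    point.  ``on_edges`` spaces nodes arc-length-uniformly along the
    boundary starting at the first vertex.
    """
    ring = np.asarray(polygon, dtype=float)
    if ring.shape[0] >= 2 and np.allclose(ring[0], ring[-1]):
        ring = ring[:-1]
    if ring.shape[0] < 3:
        raise ValueError("polygon needs at least 3 distinct vertices")
    poly = Polygon(ring)
    if not poly.is_simple or not poly.is_valid:
        raise ValueError("polygon is self-intersecting or invalid")
    nodes = sorted(net.nodes, key=str)
    if mode in ("uniform_inside", "random_inside"):
        if poly.area <= 0:
            raise ValueError("zero-area polygon cannot host interior points")
        tris = _ear_clip(ring)
        areas = np.array([abs((t[1][0] - t[0][0]) * (t[2][1] - t[0][1])
                              - (t[1][1] - t[0][1]) * (t[2][0] - t[0][0])) / 2
                          for t in tris])
        rng = np.random.default_rng(seed)
        probs = areas / areas.sum()
        pos = {}
        for node in nodes:
            t = tris[rng.choice(len(tris), p=probs)]
            u, v = rng.random(2)
            if u + v > 1:
                u, v = 1 - u, 1 - v
            p = t[0] + u * (t[1] - t[0]) + v * (t[2] - t[0])
            pos[node] = (float(p[0]), float(p[1]))
    elif mode == "on_edges":
        seglens = np.linalg.norm(np.diff(np.vstack([ring, ring[:1]]), axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seglens)])
        total = cum[-1]
        pos = {}
        for k, node in enumerate(nodes):
            s = (k / len(nodes)) * total
            i = int(np.searchsorted(cum, s, side="right")) - 1
            i = min(i, len(seglens) - 1)
            t = (s - cum[i]) / seglens[i]
            a, b = ring[i], ring[(i + 1) % len(ring)]
            p = a + t * (b - a)
            pos[node] = (float(p[0]), float(p[1]))
    else:
        raise ValueError("mode must be uniform_inside, random_inside or on_edges")
    return _coors_from_dict(pos)


# --------------------------------------------------------------------------
# grouped layouts

def g_layout(net: nx.Graph, groups: dict, group_spec: dict,
             seed: int | None = None) -> Coors:
    """Per-group placement: each group gets an independent inner layout,
    re-centered on its anchor and scaled.

    ``group_spec`` maps group label -> ``{"anchor": (x, y), "scale": s,
    "algorithm": name, "params": {...}}``.  Inner relative geometry is
    preserved (similarity transform), so nested compositions keep the
    inner arrangement.
    """
    _check_groups(net, groups)
    labels = sorted({groups[n] for n in net.nodes}, key=str)
    pos = {}
    meta = {}
    for label in labels:
        spec = group_spec.get(label, {})
        anchor = np.asarray(spec.get("anchor", (0.0, 0.0)), dtype=float)
        scale = float(spec.get("scale", 1.0))
        algorithm = spec.get("algorithm", "circle")
        params = spec.get("params", {})
        members = sorted((n for n in net.nodes if groups[n] == label), key=str)
        sub = net.subgraph(members)
        inner = c_net_layout(sub, algorithm=algorithm, params=params, seed=seed)
        xy = inner.table[["x", "y"]].to_numpy()
        xy = (xy - xy.mean(axis=0)) * scale + anchor
        for node, (x, y) in zip(inner.table["node"], xy):
            pos[node] = (float(x), float(y))
        meta[label] = {"anchor": tuple(anchor), "scale": scale, "algorithm": algorithm}
    return _coors_from_dict(pos, groups=groups, group_meta=meta)


def g_layout_circlepack(net: nx.Graph, modules, seed: int | None = None) -> Coors:
    """Modules as packed circles: radius proportional to sqrt(module
    size), greedy spiral packing in descending size order, nodes on an
    inner circle at ``config.CIRCLEPACK_INNER_SCALE`` of the module
    radius."""
    membership = getattr(modules, "membership", modules)
    _check_groups(net, membership)
    sizes: dict = {}
    for n in net.nodes:
        sizes[membership[n]] = sizes.get(membership[n], 0) + 1
    if not sizes:
        raise ValueError("empty module set")
    order = sorted(sizes, key=lambda m: (-sizes[m], str(m)))
    radii = {m: math.sqrt(sizes[m]) for m in order}
    centers: dict = {}
    placed: list[tuple[np.ndarray, float]] = []
    for m in order:
        r = radii[m]
        if not placed:
            c = np.zeros(2)
        else:
            c = _spiral_place(placed, r)
        centers[m] = c
        placed.append((c, r))
    pos = {}
    for m in order:
        members = sorted((n for n in net.nodes if membership[n] == m), key=str)
        inner_r = config.CIRCLEPACK_INNER_SCALE * radii[m]
        if len(members) == 1:
            pos[members[0]] = tuple(centers[m])
        else:
            pos.update(_circle_positions(members, radius=inner_r,
                                         center=tuple(centers[m])))
    meta = {m: {"anchor": tuple(centers[m]), "radius": radii[m], "size": sizes[m]}
            for m in order}
    return _coors_from_dict(pos, groups=dict(membership), group_meta=meta)


def _spiral_place(placed, r) -> np.ndarray:
    """Walk an Archimedean spiral until the new circle fits without overlap."""
    theta = 0.0
    step = 0.05
    while True:
        rho = 0.2 + 0.15 * theta
        c = np.array([rho * math.cos(theta), rho * math.sin(theta)])
        if all(np.linalg.norm(c - c0) >= r + r0 - 1e-12 for c0, r0 in placed):
            return c
        theta += step


def g_layout_multi_layer(net: nx.Graph, layers: dict, dz: float = 1.0,
                         alpha_deg: float = 60.0,
                         inner: str = "circle", seed: int | None = None) -> Coors:
    """Stacked pseudo-3D layout: each layer is laid out in 2D, then mapped
    through (x, y) -> (x + y cos a, y sin a + index * dz); layers are
    stacked bottom-up in sorted-label order."""
    if dz <= 0:
        raise ValueError("dz must be positive")
    _check_groups(net, layers)
    labels = sorted({layers[n] for n in net.nodes}, key=str)
    ca, sa = math.cos(math.radians(alpha_deg)), math.sin(math.radians(alpha_deg))
    pos = {}
    meta = {}
    for idx, label in enumerate(labels):
        members = sorted((n for n in net.nodes if layers[n] == label), key=str)
        inner_pos = c_net_layout(net.subgraph(members), algorithm=inner,
                                 seed=seed).as_dict()
        for node, (x, y) in inner_pos.items():
            pos[node] = (x + y * ca, y * sa + idx * dz)
        meta[label] = {"index": idx, "dz": dz, "alpha_deg": alpha_deg}
    return _coors_from_dict(pos, groups=layers, group_meta=meta)


# --------------------------------------------------------------------------
# affine transforms

def transform_coors(coors: Coors, op: str, params: dict | None = None) -> Coors:
    """Exact affine transforms of a coordinate set.

    Ops: ``scale`` (factor), ``rotate`` (degrees), ``mirror_x``
    ((x, y) -> (x, -y)), ``mirror_y`` ((x, y) -> (-x, y)),
    ``shear_pseudo3d`` (alpha_deg).  Centered on the centroid unless
    ``params["origin"]`` is given.
    """
    params = params or {}
    xy = coors.table[["x", "y"]].to_numpy(dtype=float)
    origin = params.get("origin")
    o = xy.mean(axis=0) if origin is None else np.asarray(origin, dtype=float)
    rel = xy - o
    if op == "scale":
        f = float(params.get("factor", 1.0))
        if f == 0:
            raise ValueError("scale factor 0")
        rel = rel * f
    elif op == "rotate":
        a = math.radians(float(params.get("degrees", 0.0)))
        rot = np.array([[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]])
        rel = rel @ rot.T
    elif op == "mirror_x":
        rel = rel * np.array([1.0, -1.0])
    elif op == "mirror_y":
        rel = rel * np.array([-1.0, 1.0])
    elif op == "shear_pseudo3d":
        a = math.radians(float(params.get("alpha_deg", 60.0)))
        rel = np.column_stack([rel[:, 0] + rel[:, 1] * math.cos(a),
                               rel[:, 1] * math.sin(a)])
    else:
        raise ValueError("op must be scale, rotate, mirror_x, mirror_y or shear_pseudo3d")
    out = coors.table.copy()
    new_xy = rel + o
    out["x"] = new_xy[:, 0]
    out["y"] = new_xy[:, 1]
    return Coors(table=out, group_meta=dict(coors.group_meta))
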