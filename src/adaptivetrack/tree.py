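"""Quadtree/octree partitions of an image domain.

A tree covers the smallest dyadic square/cube enclosing the image
(side ``2**max_level`` pixels).  Integer "tick" coordinates at the finest
resolution index everything exactly: a leaf at ``level`` has side
``2**(max_level - level)`` ticks, its corners are tree vertices, and at
``max_level`` the cells coincide with pixels.

Refinement follows the Whitney rule: a cell is split while the magnitude
of the level-set function at its nodes is small compared to the cell
diagonal, which concentrates the finest cells in a band around the zero
level set.  An optional 2:1 grading pass guarantees that edge-adjacent
leaves differ by at most one level, so every T-junction matches the
standard ghost-node stencils.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .geometry import Domain, max_level_for_image

__all__ = [
    "AdaptiveTree",
    "NodeField",
    "NeighborInfo",
    "build_tree",
    "build_uniform_tree",
    "enforce_grading",
    "cell_average",
    "vertex_neighborhood",
    "save_tree",
    "load_tree",
]


# ---------------------------------------------------------------------------
# tree structure


class AdaptiveTree:
    """Set of leaf cells partitioning the dyadic embedding of a domain.

    Parameters
    ----------
    domain:
        The image domain (pixel units by default).
    max_level:
        Tree depth at which cells are pixel-sized.
    leaf_levels, leaf_origins:
        Arrays of per-leaf level and lower-corner tick coordinates.
    """

    def __init__(self, domain: Domain, max_level: int,
                 leaf_levels: np.ndarray, leaf_origins: np.ndarray):
        self.domain = domain
        self.max_level = int(max_level)
        order = np.lexsort(
            tuple(leaf_origins[:, a] for a in range(domain.dim - 1, -1, -1))
            + (leaf_levels,))
        self.leaf_levels = np.asarray(leaf_levels, dtype=np.int64)[order]
        self.leaf_origins = np.asarray(leaf_origins, dtype=np.int64)[order]
        self._cache: dict = {}

    # -- basic geometry -----------------------------------------------------

    @property
    def dim(self) -> int:
        return self.domain.dim

    @property
    def side(self) -> int:
        """Embedding side length in ticks (= pixels at the finest level)."""
        return 1 << self.max_level

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_levels)

    @property
    def leaf_sizes(self) -> np.ndarray:
        """Per-leaf side length in ticks."""
        return (1 << (self.max_level - self.leaf_levels)).astype(np.int64)

    @property
    def spacing(self) -> np.ndarray:
        """Physical size of one tick per axis (= pixel spacing)."""
        return np.asarray(self.domain.spacing, dtype=float)

    @property
    def min_spacing(self) -> float:
        return float(self.spacing.min())

    def leaf_diag(self) -> np.ndarray:
        """Physical diagonal length of every leaf."""
        sz = self.leaf_sizes[:, None] * self.spacing[None, :]
        return np.sqrt((sz ** 2).sum(axis=1))

    def leaf_volumes(self) -> np.ndarray:
        sz = self.leaf_sizes[:, None] * self.spacing[None, :]
        return sz.prod(axis=1)

    def ticks_to_physical(self, ticks) -> np.ndarray:
        t = np.asarray(ticks, dtype=float)
        return np.asarray(self.domain.lower) + t * self.spacing

    def physical_to_ticks(self, points) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        return (p - np.asarray(self.domain.lower)) / self.spacing

    # -- derived tables (cached) -------------------------------------------

    @property
    def vertices(self) -> np.ndarray:
        """Distinct leaf-corner positions, tick coordinates, (n, dim)."""
        self._build_vertices()
        return self._cache["vertices"]

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def leaf_corner_ids(self) -> np.ndarray:
        """(n_leaves, 2**dim) vertex ids of each leaf's corners.

        Corner order follows the binary expansion of the corner index,
        bit ``a`` selecting the upper face along axis ``a``.
        """
        self._build_vertices()
        return self._cache["corner_ids"]

    def _build_vertices(self):
        if "vertices" in self._cache:
            return
        offs = _corner_offsets(self.dim)  # (2**dim, dim) in {0,1}
        corners = (self.leaf_origins[:, None, :]
                   + offs[None, :, :] * self.leaf_sizes[:, None, None])
        flat = corners.reshape(-1, self.dim)
        verts, inverse = np.unique(flat, axis=0, return_inverse=True)
        self._cache["vertices"] = verts.astype(np.int64)
        self._cache["corner_ids"] = inverse.reshape(
            self.n_leaves, 1 << self.dim).astype(np.int64)

    @property
    def vertex_index(self) -> dict:
        if "vindex" not in self._cache:
            self._cache["vindex"] = {
                tuple(v): i for i, v in enumerate(self.vertices)}
        return self._cache["vindex"]

    @property
    def leafmap(self) -> np.ndarray:
        """Array over finest-level cells giving the covering leaf id."""
        if "leafmap" not in self._cache:
            lm = np.full((self.side,) * self.dim, -1, dtype=np.int64)
            sizes = self.leaf_sizes
            for i in range(self.n_leaves):
                o = self.leaf_origins[i]
                s = sizes[i]
                sl = tuple(slice(o[a], o[a] + s) for a in range(self.dim))
                lm[sl] = i
            if (lm < 0).any():
                raise AssertionError("leaves do not cover the embedding")
            self._cache["leafmap"] = lm
        return self._cache["leafmap"]

    def vertex_positions(self) -> np.ndarray:
        """Physical coordinates of the tree vertices."""
        return self.ticks_to_physical(self.vertices)

    # -- queries ------------------------------------------------------------

    def locate(self, points) -> np.ndarray:
        """Leaf id containing each physical point (clamped to the embedding)."""
        t = self.physical_to_ticks(np.atleast_2d(points))
        idx = np.clip(np.floor(t).astype(np.int64), 0, self.side - 1)
        return self.leafmap[tuple(idx[:, a] for a in range(self.dim))]

    def incident_leaves(self, vertex_ticks) -> list:
        """Ids of leaves whose closure contains the given vertex."""
        v = np.asarray(vertex_ticks, dtype=np.int64)
        found = []
        for off in itertools.product((-1, 0), repeat=self.dim):
            q = v + np.asarray(off)
            if (q < 0).any() or (q >= self.side).any():
                continue
            lid = int(self.leafmap[tuple(q)])
            if lid not in found:
                found.append(lid)
        return found

    @property
    def links(self) -> list:
        """Per-vertex, per-direction neighbor descriptions (cached)."""
        if "links" not in self._cache:
            self._cache["links"] = _build_links(self)
        return self._cache["links"]

    def refined_at(self, leaf_id: int) -> "AdaptiveTree":
        """New tree with one leaf replaced by its 2**dim children."""
        lvl = self.leaf_levels[leaf_id]
        if lvl >= self.max_level:
            raise ValueError("cannot refine a finest-level leaf")
        half = self.leaf_sizes[leaf_id] // 2
        offs = _corner_offsets(self.dim) * half
        children = self.leaf_origins[leaf_id][None, :] + offs
        levels = np.concatenate([
            np.delete(self.leaf_levels, leaf_id),
            np.full(1 << self.dim, lvl + 1, dtype=np.int64)])
        origins = np.concatenate([
            np.delete(self.leaf_origins, leaf_id, axis=0), children])
        return AdaptiveTree(self.domain, self.max_level, levels, origins)


def _corner_offsets(dim: int) -> np.ndarray:
    return np.array(list(itertools.product((0, 1), repeat=dim)),
                    dtype=np.int64)[:, ::-1].copy()


# ---------------------------------------------------------------------------
# node-sampled fields


@dataclass
class NodeField:
    """One scalar value per tree vertex."""

    tree: AdaptiveTree
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.tree.n_vertices,):
            raise ValueError("one value per tree vertex required")

    def check_finite(self, name: str = "field"):
        if not np.isfinite(self.values).all():
            raise ValueError(f"{name} contains non-finite values")
        return self

    def copy(self) -> "NodeField":
        return NodeField(self.tree, self.values.copy())


# ---------------------------------------------------------------------------
# construction


def build_tree(domain: Domain,
               phi_at_point: Callable[[np.ndarray], np.ndarray],
               max_level: Optional[int] = None,
               lip: float = 1.2,
               grade: bool = True) -> AdaptiveTree:
    """Whitney-refined tree around the zero level set of ``phi_at_point``.

    A cell is split while the smallest ``|phi|`` over its corner nodes does
    not exceed ``lip/2`` times the cell diagonal (and its level is below
    ``max_level``), so every leaf with a sign change among its corners ends
    at the finest level.  Cells entirely outside the image region of a
    non-dyadic domain are never split.

    ``phi_at_point`` maps an ``(n, dim)`` array of physical points to ``n``
    values and must return finite numbers.
    """
    if lip <= 0:
        raise ValueError("lip must be positive")
    if max_level is None:
        max_level = max_level_for_image(domain.pixel_counts)
    max_level = int(max_level)
    if (1 << max_level) < max(domain.pixel_counts):
        raise ValueError("2**max_level must cover the image")
    spacing = np.asarray(domain.spacing)
    lower = np.asarray(domain.lower)
    counts = np.asarray(domain.pixel_counts)
    offs = _corner_offsets(domain.dim)

    levels_out = []
    origins_out = []
    current = np.zeros((1, domain.dim), dtype=np.int64)
    for level in range(max_level + 1):
        if len(current) == 0:
            break
        size = 1 << (max_level - level)
        diag = float(np.sqrt(((size * spacing) ** 2).sum()))
        corners = (current[:, None, :] + offs[None, :, :] * size)
        pts = lower + corners.reshape(-1, domain.dim) * spacing
        vals = np.asarray(phi_at_point(pts), dtype=float)
        if not np.isfinite(vals).all():
            raise ValueError("level-set function returned non-finite values")
        vals = np.abs(vals).reshape(len(current), -1)
        want = vals.min(axis=1) <= 0.5 * lip * diag
        inside = (current < counts[None, :]).all(axis=1)
        split = want & inside & (level < max_level)
        keep = ~split
        if keep.any():
            levels_out.append(np.full(keep.sum(), level, dtype=np.int64))
            origins_out.append(current[keep])
        if split.any():
            half = size // 2
            children = (current[split][:, None, :] + offs[None, :, :] * half)
            current = children.reshape(-1, domain.dim)
        else:
            current = np.empty((0, domain.dim), dtype=np.int64)
    tree = AdaptiveTree(domain, max_level,
                        np.concatenate(levels_out),
                        np.concatenate(origins_out, axis=0))
    if grade:
        tree = enforce_grading(tree)
    return tree


def build_uniform_tree(domain: Domain, max_level: Optional[int] = None,
                       level: Optional[int] = None) -> AdaptiveTree:
    """Tree with all leaves at one level (default: the finest)."""
    if max_level is None:
        max_level = max_level_for_image(domain.pixel_counts)
    if level is None:
        level = max_level
    if level > max_level:
        raise ValueError("level exceeds max_level")
    n = 1 << level
    size = 1 << (max_level - level)
    grids = np.meshgrid(*[np.arange(n) * size] * domain.dim, indexing="ij")
    origins = np.stack([g.ravel() for g in grids], axis=1).astype(np.int64)
    levels = np.full(len(origins), level, dtype=np.int64)
    return AdaptiveTree(domain, max_level, levels, origins)


def enforce_grading(tree: AdaptiveTree) -> AdaptiveTree:
    """Refine until edge-adjacent leaves differ by at most one level.

    Only splits cells (never coarsens), so the Whitney band is preserved.
    In 3D 'edge-adjacent' covers leaves sharing a face or an edge.
    """
    dim = tree.dim
    L = tree.max_level
    side = tree.side
    cells = {(int(l), tuple(int(x) for x in o))
             for l, o in zip(tree.leaf_levels, tree.leaf_origins)}

    def find(q):
        # leaf containing finest cell q, walking from the root
        for lvl in range(L + 1):
            shift = L - lvl
            key = (lvl, tuple((int(x) >> shift) << shift for x in q))
            if key in cells:
                return key
        raise AssertionError("point not covered by any leaf")

    dirs = [d for d in itertools.product((-1, 0, 1), repeat=dim)
            if 1 <= sum(abs(x) for x in d) <= max(1, dim - 1)]
    changed = True
    while changed:
        changed = False
        for lvl, origin in list(cells):
            if (lvl, origin) not in cells:
                continue
            size = 1 << (L - lvl)
            for d in dirs:
                q = []
                ok = True
                for a in range(dim):
                    if d[a] < 0:
                        x = origin[a] - 1
                    elif d[a] > 0:
                        x = origin[a] + size
                    else:
                        x = origin[a] + size // 2
                    if x < 0 or x >= side:
                        ok = False
                        break
                    q.append(x)
                if not ok:
                    continue
                nlvl, norig = find(q)
                if nlvl < lvl - 1:
                    # split the coarse neighbor
                    cells.discard((nlvl, norig))
                    half = 1 << (L - nlvl - 1)
                    for off in itertools.product((0, 1), repeat=dim):
                        child = tuple(norig[a] + off[a] * half
                                      for a in range(dim))
                        cells.add((nlvl + 1, child))
                    changed = True
    levels = np.array([c[0] for c in cells], dtype=np.int64)
    origins = np.array([c[1] for c in cells], dtype=np.int64)
    return AdaptiveTree(tree.domain, L, levels, origins)


# ---------------------------------------------------------------------------
# image averaging


def cell_values_from_image(tree: AdaptiveTree, image: np.ndarray) -> np.ndarray:
    """Average pixel value of every leaf (nearest pixel outside the image).

    Pixel centers sit at half-integer ticks, so a leaf box ``[o, o+s)``
    covers exactly the pixels with indices ``o .. o+s-1``.
    """
    image = np.asarray(image, dtype=float)
    if image.shape != tuple(tree.domain.pixel_counts):
        raise ValueError("image shape does not match the domain")
    # summed-area table with a zero border
    sat = image
    for a in range(tree.dim):
        sat = np.cumsum(sat, axis=a)
    sat = np.pad(sat, [(1, 0)] * tree.dim)
    counts = np.asarray(tree.domain.pixel_counts)
    o = tree.leaf_origins
    s = tree.leaf_sizes[:, None]
    lo = np.minimum(o, counts - 1)          # clamp for fully-outside cells
    hi = np.clip(o + s, 1, counts)
    lo_in = np.minimum(lo, hi - 1)
    npix = np.prod(hi - lo_in, axis=1)

    def corner(bounds):
        return sat[tuple(bounds[:, a] for a in range(tree.dim))]

    total = np.zeros(tree.n_leaves)
    for signs in itertools.product((0, 1), repeat=tree.dim):
        b = np.where(np.asarray(signs)[None, :] == 1, hi, lo_in)
        sgn = (-1) ** (tree.dim - sum(signs))
        total += sgn * corner(b)
    return total / npix


def cell_average(tree: AdaptiveTree, image: np.ndarray, leaf_id: int) -> float:
    """Mean of the pixels whose centers fall inside one leaf."""
    image = np.asarray(image, dtype=float)
    if image.shape != tuple(tree.domain.pixel_counts):
        raise ValueError("image shape does not match the domain")
    o = tree.leaf_origins[leaf_id]
    s = int(tree.leaf_sizes[leaf_id])
    counts = tree.domain.pixel_counts
    if any(o[a] >= counts[a] for a in range(tree.dim)):
        raise ValueError("cell lies outside the image")
    sl = tuple(slice(int(o[a]), min(int(o[a]) + s, counts[a]))
               for a in range(tree.dim))
    return float(image[sl].mean())


def node_values_from_image(tree: AdaptiveTree, image: np.ndarray) -> NodeField:
    """Node-sampled image: each vertex averages its incident leaves' values."""
    cell_vals = cell_values_from_image(tree, image)
    acc = np.zeros(tree.n_vertices)
    cnt = np.zeros(tree.n_vertices)
    cids = tree.leaf_corner_ids
    for k in range(cids.shape[1]):
        np.add.at(acc, cids[:, k], cell_vals)
        np.add.at(cnt, cids[:, k], 1.0)
    return NodeField(tree, acc / cnt)


# ---------------------------------------------------------------------------
# vertex neighborhoods and T-junction records


@dataclass
class NeighborInfo:
    """Neighbor of a vertex along one Cartesian direction.

    ``kind`` is ``"node"`` (existing vertex), ``"tjunction"`` (ghost value
    required) or ``"missing"`` (domain boundary).  For T-junctions,
    ``weights`` holds the full linear form of the third-order ghost value
    over vertex ids, ``interp`` the face/edge interpolation nodes with
    their transverse distances, and ``transverse`` one record per
    correction axis: ``(axis, id_minus, s_minus, id_plus, s_plus)``.
    """

    kind: str
    distance: float = np.nan
    vertex: Optional[int] = None
    interp: list = field(default_factory=list)
    transverse: list = field(default_factory=list)
    weights: list = field(default_factory=list)


def _build_links(tree: AdaptiveTree) -> list:
    dim = tree.dim
    vindex = tree.vertex_index
    verts = tree.vertices
    origins = tree.leaf_origins
    sizes = tree.leaf_sizes
    spacing = tree.spacing
    links = [[None] * (2 * dim) for _ in range(tree.n_vertices)]

    # Fast path: find every direction whose neighbor is an existing
    # vertex in bulk; only genuine T-junctions fall through to the
    # recursive ghost construction below.
    n = tree.n_vertices
    lm = tree.leafmap
    side_len = tree.side
    probes = []
    for off in itertools.product((-1, 0), repeat=dim):
        q = verts + np.asarray(off)
        ok = ((q >= 0) & (q < side_len)).all(axis=1)
        qc = np.clip(q, 0, side_len - 1)
        lid = lm[tuple(qc[:, a] for a in range(dim))]
        probes.append((np.asarray(off), np.where(ok, lid, -1)))
    pending = []
    for axis in range(dim):
        for side, sgn in ((0, -1), (1, 1)):
            best = np.full(n, np.iinfo(np.int64).max, dtype=np.int64)
            for off, lid in probes:
                if (sgn > 0 and off[axis] != 0) or (sgn < 0 and off[axis] != -1):
                    continue
                valid = lid >= 0
                o_a = np.where(valid, origins[np.maximum(lid, 0), axis], 0)
                s_a = np.where(valid, sizes[np.maximum(lid, 0)], 0)
                if sgn > 0:
                    d = o_a + s_a - verts[:, axis]
                else:
                    d = verts[:, axis] - o_a
                d = np.where(valid, d, np.iinfo(np.int64).max)
                best = np.minimum(best, d)
            missing = best == np.iinfo(np.int64).max
            p = verts.copy()
            p[:, axis] += sgn * np.where(missing, 0, best)
            slot = 2 * axis + (sgn > 0)
            for i in range(n):
                if missing[i]:
                    links[i][slot] = NeighborInfo(kind="missing")
                    continue
                j = vindex.get(tuple(p[i]))
                if j is not None:
                    links[i][slot] = NeighborInfo(
                        kind="node", vertex=int(j),
                        distance=float(best[i] * spacing[axis]),
                        weights=[(int(j), 1.0)])
                else:
                    pending.append((i, axis, sgn))

    def link(vi: int, axis: int, sgn: int, depth: int = 0) -> NeighborInfo:
        slot = 2 * axis + (sgn > 0)
        cached = links[vi][slot]
        if cached is not None:
            return cached
        v = verts[vi]
        best = None
        bestleaf = -1
        for lf in tree.incident_leaves(v):
            oa = origins[lf][axis]
            S = int(sizes[lf])
            if sgn > 0 and v[axis] < oa + S:
                d = oa + S - v[axis]
            elif sgn < 0 and v[axis] > oa:
                d = v[axis] - oa
            else:
                continue
            if best is None or d < best:
                best, bestleaf = int(d), lf
        if best is None:
            info = NeighborInfo(kind="missing")
            links[vi][slot] = info
            return info
        p = v.copy()
        p[axis] += sgn * best
        j = vindex.get(tuple(p))
        if j is not None:
            info = NeighborInfo(kind="node", vertex=int(j),
                                distance=best * spacing[axis],
                                weights=[(int(j), 1.0)])
            links[vi][slot] = info
            return info
        # T-junction: p lies inside a face/edge of the coarse leaf
        if depth > 2:
            raise AssertionError(
                "nested T-junction recursion exceeded; tree is not graded")
        o = origins[bestleaf]
        S = int(sizes[bestleaf])
        r = v - o
        hang = [b for b in range(dim)
                if b != axis and 0 < int(r[b]) < S]
        if not hang:
            raise AssertionError("inconsistent T-junction geometry")
        # interpolation nodes: corners of the far face patch around p
        wmap: dict = {}
        interp = []
        for pick in itertools.product((0, 1), repeat=len(hang)):
            q = p.copy()
            w = 1.0
            for b, hi_side in zip(hang, pick):
                if hi_side:
                    q[b] = o[b] + S
                    w *= r[b] / S
                else:
                    q[b] = o[b]
                    w *= (S - r[b]) / S
            qi = vindex.get(tuple(q))
            if qi is None:
                raise AssertionError(
                    "far-face corner missing; tree is not graded")
            interp.append((int(qi), float(w)))
            wmap[int(qi)] = wmap.get(int(qi), 0.0) + float(w)
        # curvature corrections from the vertex's transverse neighbors
        transverse = []
        for b in hang:
            minus = link(vi, b, -1, depth + 1)
            plus = link(vi, b, +1, depth + 1)
            if minus.kind == "missing" or plus.kind == "missing":
                raise AssertionError(
                    "transverse neighbor missing at a T-junction")
            s3 = r[b] * spacing[b]
            s4 = (S - r[b]) * spacing[b]
            c = (s3 * s4) / (minus.distance + plus.distance)
            transverse.append((b, minus.vertex, minus.distance,
                               plus.vertex, plus.distance))
            for side_info in (minus, plus):
                f = -c / side_info.distance
                for (k, w) in side_info.weights:
                    wmap[k] = wmap.get(k, 0.0) + f * w
                wmap[vi] = wmap.get(vi, 0.0) - f
        info = NeighborInfo(kind="tjunction",
                            distance=best * spacing[axis],
                            interp=interp,
                            transverse=transverse,
                            weights=sorted(wmap.items()))
        links[vi][slot] = info
        return info

    for vi in range(tree.n_vertices):
        for axis in range(dim):
            for sgn in (-1, 1):
                link(vi, axis, sgn)
    return links


def vertex_neighborhood(tree: AdaptiveTree, vertex) -> dict:
    """Neighbor description of one vertex, keyed by ``(axis, side)``.

    ``side`` is -1 or +1.  ``vertex`` may be a vertex id or tick
    coordinates.  Raises ``ValueError`` for positions that are not tree
    vertices.
    """
    if np.isscalar(vertex):
        vi = int(vertex)
        if not 0 <= vi < tree.n_vertices:
            raise ValueError("vertex id out of range")
    else:
        key = tuple(int(x) for x in vertex)
        vi = tree.vertex_index.get(key)
        if vi is None:
            raise ValueError(f"{key} is not a tree vertex")
    links = tree.links[vi]
    return {(axis, sgn): links[2 * axis + (sgn > 0)]
            for axis in range(tree.dim) for sgn in (-1, 1)}


# ---------------------------------------------------------------------------
# plain-text dump / restore


def save_tree(tree: AdaptiveTree, path):
    """Write a tree as plain text; round-trips bit-exactly."""
    with open(path, "w") as fh:
        fh.write("adaptivetrack-tree 1\n")
        fh.write(f"dim {tree.dim}\n")
        fh.write(f"max_level {tree.max_level}\n")
        fh.write("pixel_counts " +
                 " ".join(str(c) for c in tree.domain.pixel_counts) + "\n")
        fh.write("lower " +
                 " ".join(repr(x) for x in tree.domain.lower) + "\n")
        fh.write("spacing " +
                 " ".join(repr(x) for x in tree.domain.spacing) + "\n")
        for lvl, o in zip(tree.leaf_levels, tree.leaf_origins):
            fh.write("leaf " + str(int(lvl)) + " " +
                     " ".join(str(int(x)) for x in o) + "\n")


def load_tree(path) -> AdaptiveTree:
    header = {}
    levels = []
    origins = []
    with open(path) as fh:
        magic = fh.readline().strip()
        if not magic.startswith("adaptivetrack-tree"):
            raise ValueError("not a tree file")
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0] == "leaf":
                levels.append(int(parts[1]))
                origins.append([int(x) for x in parts[2:]])
            else:
                header[parts[0]] = parts[1:]
    domain = Domain(
        pixel_counts=tuple(int(x) for x in header["pixel_counts"]),
        lower=tuple(float(x) for x in header["lower"]),
        spacing=tuple(float(x) for x in header["spacing"]))
    return AdaptiveTree(domain, int(header["max_level"][0]),
                        np.asarray(levels, dtype=np.int64),
                        np.asarray(origins, dtype=np.int64))
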