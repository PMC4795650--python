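"""Vectorised finite-difference operators over a tree's node fields.

The per-vertex neighbor links (including third-order ghost values at
T-junctions, which are linear in the node values) are assembled once per
tree into sparse matrices, so derivatives, interpolation and elliptic
operators act on whole node-value vectors with sparse matvecs.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .tree import AdaptiveTree, _corner_offsets

__all__ = ["TreeOperators", "get_ops"]


def get_ops(tree: AdaptiveTree) -> "TreeOperators":
    ops = tree._cache.get("ops")
    if ops is None:
        ops = TreeOperators(tree)
        tree._cache["ops"] = ops
    return ops


class TreeOperators:
    def __init__(self, tree: AdaptiveTree):
        self.tree = tree
        n = tree.n_vertices
        dim = tree.dim
        self.n = n
        self.dim = dim
        self.s = np.full((dim, 2, n), np.nan)
        self.has = np.zeros((dim, 2, n), dtype=bool)
        self.M = [[None, None] for _ in range(dim)]
        links = tree.links
        for axis in range(dim):
            for side in range(2):  # 0 = minus, 1 = plus
                rows, cols, data = [], [], []
                for i in range(n):
                    info = links[i][2 * axis + side]
                    if info.kind == "missing":
                        continue
                    self.s[axis, side, i] = info.distance
                    self.has[axis, side, i] = True
                    for j, w in info.weights:
                        rows.append(i)
                        cols.append(j)
                        data.append(w)
                self.M[axis][side] = sp.csr_matrix(
                    (data, (rows, cols)), shape=(n, n))
        # dual volume of each vertex (share of incident leaf volumes)
        vols = tree.leaf_volumes() / (1 << dim)
        dual = np.zeros(n)
        cids = tree.leaf_corner_ids
        for k in range(cids.shape[1]):
            np.add.at(dual, cids[:, k], vols)
        self.dual_volumes = dual
        self._grad_mats = None

    # -- neighbor access ----------------------------------------------------

    def neighbor_values(self, u: np.ndarray, axis: int, side: int):
        return self.M[axis][side] @ u

    def _sides(self, axis):
        sm = self.s[axis, 0]
        sp_ = self.s[axis, 1]
        hm = self.has[axis, 0]
        hp = self.has[axis, 1]
        return sm, sp_, hm, hp

    # -- derivatives --------------------------------------------------------

    def d_central(self, u: np.ndarray, axis: int) -> np.ndarray:
        """Central first derivative; one-sided at domain-boundary vertices."""
        um = self.neighbor_values(u, axis, 0)
        up = self.neighbor_values(u, axis, 1)
        sm, sp_, hm, hp = self._sides(axis)
        sm_ = np.where(hm, sm, 1.0)
        sp__ = np.where(hp, sp_, 1.0)
        both = hm & hp
        out = np.zeros_like(u)
        c = ((up - u) / sp__ * sm_ / (sm_ + sp__)
             + (u - um) / sm_ * sp__ / (sm_ + sp__))
        out[both] = c[both]
        only_p = hp & ~hm
        out[only_p] = ((up - u) / sp__)[only_p]
        only_m = hm & ~hp
        out[only_m] = ((u - um) / sm_)[only_m]
        return out

    def d_second(self, u: np.ndarray, axis: int) -> np.ndarray:
        um = self.neighbor_values(u, axis, 0)
        up = self.neighbor_values(u, axis, 1)
        sm, sp_, hm, hp = self._sides(axis)
        sm_ = np.where(hm, sm, 1.0)
        sp__ = np.where(hp, sp_, 1.0)
        out = ((up - u) / sp__ - (u - um) / sm_) * 2.0 / (sm_ + sp__)
        out[~(hm & hp)] = 0.0
        return out

    def gradient(self, u: np.ndarray) -> np.ndarray:
        """(dim, n) array of central derivatives."""
        return np.stack([self.d_central(u, a) for a in range(self.dim)])

    def one_sided(self, u: np.ndarray, axis: int, order: int = 2):
        """Backward/forward first derivatives ``(d_minus, d_plus)``.

        Order 2 applies the minmod-limited second-derivative correction;
        at domain-boundary vertices the available one-sided value is
        copied to the missing side.
        """
        um = self.neighbor_values(u, axis, 0)
        up = self.neighbor_values(u, axis, 1)
        sm, sp_, hm, hp = self._sides(axis)
        sm_ = np.where(hm, sm, 1.0)
        sp__ = np.where(hp, sp_, 1.0)
        dm = (u - um) / sm_
        dp = (up - u) / sp__
        if order == 2:
            dxx = self.d_second(u, axis)
            dxx_m = self.neighbor_values(dxx, axis, 0)
            dxx_p = self.neighbor_values(dxx, axis, 1)
            dm = dm + sm_ / 2.0 * _minmod(dxx, dxx_m)
            dp = dp - sp__ / 2.0 * _minmod(dxx, dxx_p)
        dm = np.where(hm, dm, np.where(hp, dp, 0.0))
        dp = np.where(hp, dp, np.where(hm, dm, 0.0))
        return dm, dp

    # -- forward-difference gradient / divergence (for dual TV) -------------

    @property
    def grad_mats(self):
        """Forward-difference matrices per axis (zero rows at boundaries)."""
        if self._grad_mats is None:
            mats = []
            eye = sp.identity(self.n, format="csr")
            for axis in range(self.dim):
                sm, sp_, hm, hp = self._sides(axis)
                inv = np.where(hp, 1.0 / np.where(hp, sp_, 1.0), 0.0)
                mats.append(sp.diags(inv) @ (self.M[axis][1] - eye))
            self._grad_mats = [m.tocsr() for m in mats]
        return self._grad_mats

    def forward_grad(self, u: np.ndarray) -> np.ndarray:
        return np.stack([m @ u for m in self.grad_mats])

    def neg_adjoint_div(self, p: np.ndarray) -> np.ndarray:
        """Divergence as the negative adjoint of ``forward_grad``."""
        out = np.zeros(self.n)
        for a in range(self.dim):
            out -= self.grad_mats[a].T @ p[a]
        return out

    # -- elliptic operator ---------------------------------------------------

    def stiffness(self, c: np.ndarray) -> sp.csr_matrix:
        """Symmetric stiffness matrix of the energy ``sum c |grad u|^2 / 2``.

        Assembled variationally as ``sum_a G_a^T diag(vol * c_edge) G_a``
        with forward-difference gradients and arithmetic edge means of
        the per-vertex diffusivity ``c``, so the matrix is symmetric
        positive semi-definite on any tree.  ``A u`` approximates
        ``-vol * div(c grad u)`` with Neumann walls.
        """
        A = sp.csr_matrix((self.n, self.n))
        for axis in range(self.dim):
            ce = 0.5 * (c + self.M[axis][1] @ c)
            ce = np.where(self.has[axis, 1], ce, 0.0)
            Ga = self.grad_mats[axis]
            A = A + Ga.T @ sp.diags(self.dual_volumes * ce) @ Ga
        return A.tocsr()

    # -- interpolation and quadrature ---------------------------------------

    def interpolate(self, u: np.ndarray, points) -> np.ndarray:
        """Multilinear interpolation of a node field at physical points.

        Points outside the embedding are clamped to its boundary.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        tree = self.tree
        t = tree.physical_to_ticks(pts)
        t = np.clip(t, 0.0, float(tree.side))
        cell = np.clip(np.floor(t).astype(np.int64), 0, tree.side - 1)
        leaf = tree.leafmap[tuple(cell[:, a] for a in range(self.dim))]
        o = tree.leaf_origins[leaf]
        size = tree.leaf_sizes[leaf]
        xi = (t - o) / size[:, None]
        xi = np.clip(xi, 0.0, 1.0)
        cids = tree.leaf_corner_ids[leaf]
        offs = _corner_offsets(self.dim)
        out = np.zeros(len(pts))
        for k in range(1 << self.dim):
            w = np.ones(len(pts))
            for a in range(self.dim):
                w *= xi[:, a] if offs[k, a] else (1.0 - xi[:, a])
            out += w * u[cids[:, k]]
        # snap exact vertex hits: a hanging node's stored value is not
        # reproduced by the coarse leaf's multilinear corners
        rounded = np.rint(t)
        exact = (np.abs(t - rounded) < 1e-9).all(axis=1)
        if exact.any():
            vindex = tree.vertex_index
            for i in np.nonzero(exact)[0]:
                j = vindex.get(tuple(rounded[i].astype(np.int64)))
                if j is not None:
                    out[i] = u[j]
        return out

    def integrate(self, u: np.ndarray) -> float:
        """Quadrature over leaves (corner-mean rule) of a node field."""
        return float(self.dual_volumes @ u)


def _minmod(x, y):
    return np.where(np.abs(y) < np.abs(x), y, x)
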