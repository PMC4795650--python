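"""Joint estimation of dense flow and sparse corruption between frames.

The displacement field ``u`` and the sparse error ``G`` minimise

    E(u, G) = int rho(|I(x+u, t) - I(x, t-1) - G|^2)
            + alpha_u  int rho(|grad u|^2 + |grad v|^2 [+ |grad w|^2])
            + alpha_g1 int rho(|G|^2)
            + alpha_g2 int rho(|grad G|^2)

with the Charbonnier penaliser ``rho(x^2) = sqrt(x^2 + eps^2)``.  The
Euler-Lagrange system is solved coarse-to-fine on trees capped at
decreasing maximum level, with lagged-nonlinearity fixed-point
iterations: the smoothing terms are implicit, the data terms
semi-implicit (linearised in the flow increment), and each linear system
is solved with block-preconditioned conjugate gradients.

When a shape-coupling term is supplied, its contribution
``rho_c'(phi_w^2) phi_w grad(phi_w) |grad H(phi0)|`` (with
``phi_w = phi0(x + u, t-1)`` the warped previous shape) is linearised in
the increment alongside the brightness term, which registers the
previous contour onto the current one within the Dirac band of the
current shape estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.sparse as sp

from .levelset import LevelSetField, smoothed_dirac
from .operators import get_ops
from .tree import AdaptiveTree, NodeField, node_values_from_image

__all__ = [
    "RegistrationParams", "FlowField", "SparseError", "CouplingTerm",
    "rho", "rho_prime", "warp", "residual", "solve_flow_and_G",
    "energy_rg", "coarsen_tree",
]


@dataclass
class RegistrationParams:
    """Weights and iteration controls for the flow/sparse-error solver.

    The default weights are the constants used for all experiments:
    ``alpha_u`` (flow smoothness) 8e-4, ``alpha_g1`` (sparsity of G)
    9e-5, ``alpha_g2`` (smoothness of G) 3e-3 and the Charbonnier
    ``epsilon`` 1e-3, on intensities normalised to unit dynamic range
    and displacements in pixels.
    """

    alpha_u: float = 8e-4
    alpha_g1: float = 9e-5
    alpha_g2: float = 3e-3
    epsilon: float = 1e-3
    pyramid_levels: Optional[int] = None   # None: down to ~32 px
    inner_iters: int = 5                   # warping fixed-point iterations
    outer_iters: int = 1                   # repeats of the full pyramid
    sweeps: int = 200                      # CG steps per linear solve
    sweep_tol: float = 1e-4                # relative residual target
    normalize: bool = True                 # rescale intensities internally
    min_coarse_pixels: int = 32

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if min(self.alpha_u, self.alpha_g1, self.alpha_g2) < 0:
            raise ValueError("weights must be non-negative")


@dataclass
class FlowField:
    """Displacement components (u, v[, w]) as node fields on one tree."""

    components: list

    @property
    def tree(self) -> AdaptiveTree:
        return self.components[0].tree

    @property
    def dim(self) -> int:
        return len(self.components)

    def as_array(self) -> np.ndarray:
        return np.stack([c.values for c in self.components])

    @classmethod
    def zero(cls, tree: AdaptiveTree) -> "FlowField":
        return cls([NodeField(tree, np.zeros(tree.n_vertices))
                    for _ in range(tree.dim)])


@dataclass
class SparseError:
    """Per-vertex brightness corruption (occlusion, shading) field."""

    G: NodeField

    @classmethod
    def zero(cls, tree: AdaptiveTree) -> "SparseError":
        return cls(NodeField(tree, np.zeros(tree.n_vertices)))


@dataclass
class CouplingTerm:
    """Shape coupling for simultaneous registration and segmentation.

    ``prev_shape`` is the previous frame's signed-distance shape
    (interpolatable on its own tree); ``current_shape`` supplies the
    narrow band ``|grad H|`` of the running shape estimate, frozen
    during each flow solve.  ``weight`` is the combination-term weight.
    """

    prev_shape: LevelSetField
    current_shape: LevelSetField
    weight: float = 2e-5
    eps_h: float = 1.5


def rho(x_sq, epsilon: float):
    """Charbonnier penaliser ``sqrt(x^2 + eps^2)`` of a squared argument."""
    x_sq = np.asarray(x_sq, dtype=float)
    if (x_sq < 0).any():
        raise ValueError("squared argument must be non-negative")
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    out = np.sqrt(x_sq + epsilon ** 2)
    return float(out) if out.ndim == 0 else out


def rho_prime(x_sq, epsilon: float):
    """Derivative of :func:`rho` with respect to its squared argument."""
    x_sq = np.asarray(x_sq, dtype=float)
    if (x_sq < 0).any():
        raise ValueError("squared argument must be non-negative")
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    out = 0.5 / np.sqrt(x_sq + epsilon ** 2)
    return float(out) if out.ndim == 0 else out


def warp(image_field: NodeField, flow: FlowField) -> NodeField:
    """Image sampled at ``x + u(x)`` by multilinear interpolation."""
    tree = image_field.tree
    ops = get_ops(tree)
    x = tree.vertex_positions() + flow.as_array().T
    return NodeField(tree, ops.interpolate(image_field.values, x))


def residual(I_prev: NodeField, I_curr: NodeField, flow: FlowField,
             G: SparseError):
    """Brightness residual ``I_d = I(x+u, t) - I(x, t-1) - G`` and the
    spatial derivatives of the warped image."""
    if I_prev.tree is not I_curr.tree or I_prev.tree is not flow.tree:
        raise ValueError("fields must live on one tree")
    ops = get_ops(I_prev.tree)
    Iw = warp(I_curr, flow)
    Id = NodeField(I_prev.tree, Iw.values - I_prev.values - G.G.values)
    grads = [ops.d_central(Iw.values, a) for a in range(I_prev.tree.dim)]
    return Id, grads


def coarsen_tree(tree: AdaptiveTree, cap: int) -> AdaptiveTree:
    """Merge leaves deeper than ``cap`` into their level-``cap`` ancestors."""
    if cap >= tree.max_level:
        return tree
    size_cap = 1 << (tree.max_level - cap)
    keys = set()
    for lvl, o in zip(tree.leaf_levels, tree.leaf_origins):
        if lvl <= cap:
            keys.add((int(lvl), tuple(int(x) for x in o)))
        else:
            anc = tuple((int(x) // size_cap) * size_cap for x in o)
            keys.add((cap, anc))
    levels = np.array([k[0] for k in keys], dtype=np.int64)
    origins = np.array([k[1] for k in keys], dtype=np.int64)
    return AdaptiveTree(tree.domain, tree.max_level, levels, origins)


def _transfer(src_field: NodeField, dst_tree: AdaptiveTree) -> NodeField:
    vals = get_ops(src_field.tree).interpolate(
        src_field.values, dst_tree.vertex_positions())
    return NodeField(dst_tree, vals)


def _solve_coupled(A_diag: np.ndarray, S: sp.csr_matrix,
                   alpha: float, rhs: np.ndarray, params: RegistrationParams
                   ) -> np.ndarray:
    """Solve ``A_diag X + alpha S X_a = rhs`` (symmetric positive definite).

    ``A_diag`` is ``(dim, dim, n)`` of per-vertex data blocks and ``S``
    the symmetric stiffness matrix of the smoothing term.
    Preconditioned conjugate gradients with the per-vertex block inverse
    as preconditioner; iterates to ``sweep_tol`` relative residual or
    ``sweeps`` steps.
    """
    d, _, n = A_diag.shape
    Sd = S.diagonal()
    block = A_diag.copy()
    for a in range(d):
        block[a, a] = block[a, a] + alpha * Sd + 1e-12
    inv = np.linalg.inv(np.moveaxis(block, 2, 0))  # (n, d, d)

    def mv(X):
        return (np.einsum("ijn,jn->in", A_diag, X)
                + alpha * np.stack([S @ X[a] for a in range(d)])
                + 1e-12 * X)

    def prec(R):
        return np.einsum("nij,jn->in", inv, R)

    X = np.zeros((d, n))
    R = rhs.copy()
    rhs_norm = np.linalg.norm(rhs) + 1e-30
    Z = prec(R)
    P = Z.copy()
    rz = float((R * Z).sum())
    for _ in range(params.sweeps):
        if np.linalg.norm(R) < params.sweep_tol * rhs_norm:
            break
        AP = mv(P)
        a_step = rz / max(float((P * AP).sum()), 1e-300)
        X += a_step * P
        R -= a_step * AP
        Z = prec(R)
        rz_new = float((R * Z).sum())
        P = Z + (rz_new / max(rz, 1e-300)) * P
        rz = rz_new
    return X


def _level_fields(tree, I_prev, I_curr):
    if isinstance(I_prev, NodeField):
        return I_prev, I_curr
    return (node_values_from_image(tree, I_prev),
            node_values_from_image(tree, I_curr))


def solve_flow_and_G(I_prev, I_curr, params: RegistrationParams = None,
                     tree: AdaptiveTree = None,
                     init_flow: FlowField = None,
                     init_G: SparseError = None,
                     coupling: CouplingTerm = None):
    """Coarse-to-fine solve of the coupled flow / sparse-error system.

    ``I_prev`` and ``I_curr`` are pixel arrays (averaged onto capped
    copies of ``tree`` for the pyramid) or node fields on ``tree`` (then
    the solve runs on that single level).  Returns ``(FlowField,
    SparseError)`` on ``tree``; the flow is in physical (pixel) units
    and ``G`` in the input intensity units.
    """
    params = params or RegistrationParams()
    as_fields = isinstance(I_prev, NodeField)
    if as_fields:
        tree = I_prev.tree
    if tree is None:
        raise ValueError("a tree is required when images are pixel arrays")

    if params.normalize:
        if as_fields:
            lo = min(I_prev.values.min(), I_curr.values.min())
            hi = max(I_prev.values.max(), I_curr.values.max())
        else:
            lo = min(np.min(I_prev), np.min(I_curr))
            hi = max(np.max(I_prev), np.max(I_curr))
        scale = max(hi - lo, 1e-12)
    else:
        scale = 1.0

    # pyramid of capped trees, coarse first
    finest = tree.max_level
    if params.pyramid_levels is not None:
        n_levels = max(1, int(params.pyramid_levels))
    elif as_fields:
        n_levels = 1
    else:
        n_levels = 1
        extent = min(tree.domain.pixel_counts)
        while extent / (1 << n_levels) >= params.min_coarse_pixels:
            n_levels += 1
    caps = [finest - k for k in range(n_levels - 1, -1, -1)]
    caps = [c for c in caps if c >= 1]

    flow = None
    G = None
    for cap in caps:
        t_l = coarsen_tree(tree, cap)
        ops = get_ops(t_l)
        if as_fields and cap == finest:
            Ip, Ic = I_prev, I_curr
        else:
            if as_fields:
                Ip, Ic = _transfer(I_prev, t_l), _transfer(I_curr, t_l)
            else:
                Ip, Ic = _level_fields(t_l, I_prev, I_curr)
        Ip = NodeField(t_l, Ip.values / scale)
        Ic = NodeField(t_l, Ic.values / scale)
        if flow is None:
            if init_flow is not None:
                flow = FlowField([_transfer(c, t_l)
                                  for c in init_flow.components])
            else:
                flow = FlowField.zero(t_l)
            if init_G is not None:
                G = NodeField(t_l, _transfer(init_G.G, t_l).values / scale)
            else:
                G = NodeField(t_l, np.zeros(t_l.n_vertices))
        else:
            flow = FlowField([_transfer(c, t_l) for c in flow.components])
            G = _transfer(G, t_l)
        flow, G = _solve_level(t_l, ops, Ip, Ic, flow, G, params, coupling)

    G_out = SparseError(NodeField(flow.tree, G.values * scale))
    return flow, G_out


def _solve_level(tree, ops, Ip, Ic, flow, G, params, coupling):
    dim = tree.dim
    x = tree.vertex_positions()

    band = phi_cur_grad = None
    if coupling is not None and coupling.weight > 0:
        phi_c = coupling.current_shape.interpolate(x)
        gmag = np.linalg.norm(
            np.stack([ops.d_central(phi_c, a) for a in range(dim)]), axis=0)
        band = smoothed_dirac(phi_c, coupling.eps_h) * gmag

    for _ in range(params.inner_iters):
        U = flow.as_array()
        Iw = ops.interpolate(Ic.values, x + U.T)
        Ig = np.stack([ops.d_central(Iw, a) for a in range(dim)])
        Id = Iw - Ip.values - G.values
        rho_d = rho_prime(Id ** 2, params.epsilon)
        grad_sq = np.zeros(tree.n_vertices)
        for a in range(dim):
            for c in range(dim):
                grad_sq += ops.d_central(U[c], a) ** 2
        rho_s = rho_prime(grad_sq, params.epsilon)
        S = ops.stiffness(rho_s)
        vol = ops.dual_volumes

        # per-vertex data blocks and right-hand side (volume-weighted so
        # the system is the gradient of the discrete energy, hence SPD)
        A = np.zeros((dim, dim, tree.n_vertices))
        rhs = np.zeros((dim, tree.n_vertices))
        for a in range(dim):
            for b in range(dim):
                A[a, b] = vol * rho_d * Ig[a] * Ig[b]
            rhs[a] = -vol * rho_d * Id * Ig[a] - params.alpha_u * (S @ U[a])
        if band is not None:
            phi_w = coupling.prev_shape.interpolate(x + U.T)
            pg = np.stack([ops.d_central(phi_w, a) for a in range(dim)])
            w = vol * coupling.weight * band
            for a in range(dim):
                for b in range(dim):
                    A[a, b] += w * pg[a] * pg[b]
                rhs[a] += -w * phi_w * pg[a]
        dU = _solve_coupled(A, S, params.alpha_u, rhs, params)
        U = U + dU
        flow = FlowField([NodeField(tree, U[a]) for a in range(dim)])

        # G update: (rho_d + a1 rho_g1) G - a2 div(rho_g2 grad G) = rho_d (Iw - Ip)
        Iw = ops.interpolate(Ic.values, x + U.T)
        Id0 = Iw - Ip.values
        rho_d = rho_prime((Id0 - G.values) ** 2, params.epsilon)
        rho_g1 = rho_prime(G.values ** 2, params.epsilon)
        gsq = np.zeros(tree.n_vertices)
        for a in range(dim):
            gsq += ops.d_central(G.values, a) ** 2
        rho_g2 = rho_prime(gsq, params.epsilon)
        Sg = ops.stiffness(rho_g2)
        diag = vol * (rho_d + params.alpha_g1 * rho_g1)
        rhs_g = vol * rho_d * Id0
        Gv = _solve_scalar(diag, Sg, params.alpha_g2, rhs_g, G.values, params)
        G = NodeField(tree, Gv)
    return flow, G


def _solve_scalar(diag, S, alpha, rhs, x0, params):
    """Jacobi-preconditioned CG for ``diag x + alpha S x = rhs``."""
    d_full = diag + alpha * S.diagonal() + 1e-12
    x = x0.copy()
    R = rhs - (diag * x + alpha * (S @ x))
    rhs_norm = np.linalg.norm(rhs) + 1e-30
    Z = R / d_full
    P = Z.copy()
    rz = float(R @ Z)
    for _ in range(params.sweeps):
        if np.linalg.norm(R) < params.sweep_tol * rhs_norm:
            break
        AP = diag * P + alpha * (S @ P) + 1e-12 * P
        a_step = rz / max(float(P @ AP), 1e-300)
        x += a_step * P
        R -= a_step * AP
        Z = R / d_full
        rz_new = float(R @ Z)
        P = Z + (rz_new / max(rz, 1e-300)) * P
        rz = rz_new
    return x


def energy_rg(I_prev: NodeField, I_curr: NodeField, flow: FlowField,
              G: SparseError, params: RegistrationParams = None) -> float:
    """Quadrature of the registration energy over the tree."""
    params = params or RegistrationParams()
    tree = I_prev.tree
    ops = get_ops(tree)
    if params.normalize:
        scale = max(max(I_prev.values.max(), I_curr.values.max())
                    - min(I_prev.values.min(), I_curr.values.min()), 1e-12)
    else:
        scale = 1.0
    Id, _ = residual(NodeField(tree, I_prev.values / scale),
                     NodeField(tree, I_curr.values / scale), flow,
                     SparseError(NodeField(tree, G.G.values / scale)))
    dens = rho(Id.values ** 2, params.epsilon)
    grad_sq = np.zeros(tree.n_vertices)
    for c in flow.components:
        for a in range(tree.dim):
            grad_sq += ops.d_central(c.values, a) ** 2
    dens = dens + params.alpha_u * rho(grad_sq, params.epsilon)
    Gn = G.G.values / scale
    dens = dens + params.alpha_g1 * rho(Gn ** 2, params.epsilon)
    gsq = np.zeros(tree.n_vertices)
    for a in range(tree.dim):
        gsq += ops.d_central(Gn, a) ** 2
    dens = dens + params.alpha_g2 * rho(gsq, params.epsilon)
    return ops.integrate(dens)
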