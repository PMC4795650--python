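"""Ghost-node interpolation and derivative stencils on nonuniform spacings.

All formulas are third-order interpolations or central/one-sided
differences that are exact on quadratic polynomials for arbitrary
positive spacings.  They are written for a single 1D stencil or a single
T-junction record; the tree operators assemble them into sparse matrices
over whole node fields.

Conventions for the T-junction records (see the field docstrings): the
node ``v0`` carries value ``u0``; a neighbor is missing along one
Cartesian axis and its ghost value is reconstructed from the nodes
bounding the ghost position transversally, minus a curvature correction
formed from ``v0``'s own transverse neighbors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Stencil1D", "TJunction2D", "TJunction3D",
    "ghost_value_2d", "ghost_values_3d",
    "d_central", "d_second", "d_one_sided", "minmod",
]


def _check_positive(**named):
    for name, value in named.items():
        if not np.all(np.asarray(value) > 0):
            raise ValueError(f"distance {name} must be positive")


@dataclass
class Stencil1D:
    """Three collinear samples: ``u1`` at distance ``s1`` on the left of
    ``u0`` and ``u2`` at distance ``s2`` on the right."""

    u0: float
    u1: float
    u2: float
    s1: float
    s2: float

    def __post_init__(self):
        _check_positive(s1=self.s1, s2=self.s2)


@dataclass
class TJunction2D:
    """2D T-junction: the neighbor of ``v0`` along one axis is missing.

    The ghost position is bracketed transversally by ``u3`` (distance
    ``s3``) and ``u4`` (distance ``s4``); ``u1``/``u2`` are ``v0``'s own
    transverse neighbors at distances ``s1``/``s2`` on the ``u3``/``u4``
    sides respectively.
    """

    u0: float
    u1: float
    u2: float
    u3: float
    u4: float
    s1: float
    s2: float
    s3: float
    s4: float

    def __post_init__(self):
        _check_positive(s1=self.s1, s2=self.s2, s3=self.s3, s4=self.s4)


@dataclass
class TJunction3D:
    """3D T-junction at a coarse-cell face, with a nested edge ghost.

    Let the missing neighbor of ``v0`` lie across a coarse face spanned
    by transverse axes A and B.  Fields:

    - ``u1``/``u2``: ``v0``'s A-neighbors at ``s1``/``s2`` (minus/plus side);
    - ``u5``: ``v0``'s existing B-neighbor at ``s5`` (minus side); the plus
      B-neighbor at distance ``s6`` is itself missing and replaced by the
      edge ghost ``u6G``, bracketed along A by ``u7`` (minus, ``s7``) and
      ``u8`` (plus, ``s8``);
    - ``u9 .. u12``: face samples around the main ghost, at A-offsets
      ``-s10``/``+s11`` and B-offsets ``-s9``/``+s12``: ``u11`` at
      ``(-s10, -s9)``, ``u12`` at ``(-s10, +s12)``, ``u9`` at
      ``(+s11, -s9)``, ``u10`` at ``(+s11, +s12)``.
    """

    u0: float
    u1: float
    u2: float
    u5: float
    u7: float
    u8: float
    u9: float
    u10: float
    u11: float
    u12: float
    s1: float
    s2: float
    s5: float
    s6: float
    s7: float
    s8: float
    s9: float
    s10: float
    s11: float
    s12: float

    def __post_init__(self):
        _check_positive(**{f"s{k}": getattr(self, f"s{k}")
                           for k in (1, 2, 5, 6, 7, 8, 9, 10, 11, 12)})


def ghost_value_2d(tj: TJunction2D) -> float:
    """Third-order ghost value at a 2D T-junction; exact on quadratics."""
    interp = (tj.u3 * tj.s4 + tj.u4 * tj.s3) / (tj.s3 + tj.s4)
    corr = (tj.s3 * tj.s4 / (tj.s1 + tj.s2)
            * ((tj.u1 - tj.u0) / tj.s1 + (tj.u2 - tj.u0) / tj.s2))
    return interp - corr


def ghost_values_3d(tj: TJunction3D) -> tuple:
    """Edge and face ghost values ``(u6G, u4G)`` at a 3D T-junction.

    ``u6G`` is computed first and substituted into the face ghost's
    second curvature correction; both are exact on quadratics.
    """
    u6g = ((tj.s8 * tj.u7 + tj.s7 * tj.u8) / (tj.s8 + tj.s7)
           - tj.s8 * tj.s7 / (tj.s2 + tj.s1)
           * ((tj.u2 - tj.u0) / tj.s2 + (tj.u1 - tj.u0) / tj.s1))
    bilinear = ((tj.s11 * tj.s12 * tj.u11 + tj.s11 * tj.s9 * tj.u12
                 + tj.s10 * tj.s12 * tj.u9 + tj.s10 * tj.s9 * tj.u10)
                / ((tj.s10 + tj.s11) * (tj.s9 + tj.s12)))
    corr_a = (tj.s10 * tj.s11 / (tj.s2 + tj.s1)
              * ((tj.u2 - tj.u0) / tj.s2 + (tj.u1 - tj.u0) / tj.s1))
    corr_b = (tj.s9 * tj.s12 / (tj.s5 + tj.s6)
              * ((tj.u5 - tj.u0) / tj.s5 + (u6g - tj.u0) / tj.s6))
    return float(u6g), float(bilinear - corr_a - corr_b)


def d_central(st: Stencil1D) -> float:
    """Central first derivative on a nonuniform stencil (exact on quadratics)."""
    return ((st.u2 - st.u0) / st.s2 * st.s1 / (st.s1 + st.s2)
            + (st.u0 - st.u1) / st.s1 * st.s2 / (st.s1 + st.s2))


def d_second(st: Stencil1D) -> float:
    """Second derivative on a nonuniform stencil (exact on quadratics)."""
    return ((st.u2 - st.u0) / st.s2 * 2.0 / (st.s1 + st.s2)
            - (st.u0 - st.u1) / st.s1 * 2.0 / (st.s1 + st.s2))


def minmod(x, y):
    """Slope limiter returning the smaller-magnitude argument (ties: x).

    Used so one-sided derivatives never difference across kinks where the
    other candidate slope is steeper.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    out = np.where(np.abs(y) < np.abs(x), y, x)
    if out.ndim == 0:
        return float(out)
    return out


def d_one_sided(st: Stencil1D, side: str, order: int = 1,
                dxx_center: float = None, dxx_neighbor: float = None) -> float:
    """Forward/backward first derivative, first or second order accurate.

    ``side`` is ``"+"`` (uses ``u2, s2``) or ``"-"`` (uses ``u1, s1``).
    For ``order=2`` the second derivatives at the center and at the
    neighbor node must be supplied; the correction is
    ``-/+ s/2 * minmod(dxx_center, dxx_neighbor)``.
    """
    if side not in ("+", "-"):
        raise ValueError("side must be '+' or '-'")
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    if side == "+":
        d1 = (st.u2 - st.u0) / st.s2
        if order == 1:
            return d1
        if dxx_center is None or dxx_neighbor is None:
            raise ValueError("order 2 requires the second-derivative values")
        return d1 - st.s2 / 2.0 * minmod(dxx_center, dxx_neighbor)
    d1 = (st.u0 - st.u1) / st.s1
    if order == 1:
        return d1
    if dxx_center is None or dxx_neighbor is None:
        raise ValueError("order 2 requires the second-derivative values")
    return d1 + st.s1 / 2.0 * minmod(dxx_center, dxx_neighbor)
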