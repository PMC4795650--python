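"""Physical domain description for 2D/3D image grids.

The tracker works in pixel units by default: an image of shape
``(n0, n1[, n2])`` lives on the rectangle ``[0, n0] x [0, n1]`` with unit
spacing, pixel centers at half-integers.  The adaptive tree embeds this
rectangle in the smallest dyadic square/cube (side ``2**L`` pixels).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Domain", "max_level_for_image", "uniform_cell_count"]


def max_level_for_image(pixel_counts) -> int:
    """Smallest tree depth ``L`` with ``2**L >= max(pixel_counts)``.

    At that depth the finest cells coincide with pixels; e.g. a
    1024 x 1024 image maps to a quadtree of maximum level 10.
    """
    counts = [int(c) for c in np.atleast_1d(pixel_counts)]
    if any(c < 1 for c in counts):
        raise ValueError(f"pixel counts must be positive, got {pixel_counts}")
    return max(int(np.ceil(np.log2(c))) for c in counts)


def uniform_cell_count(pixel_counts) -> int:
    """Number of cells of the uniform (non-adaptive) grid over an image."""
    counts = [int(c) for c in np.atleast_1d(pixel_counts)]
    if any(c < 1 for c in counts):
        raise ValueError(f"pixel counts must be positive, got {pixel_counts}")
    return int(np.prod(counts))


@dataclass(frozen=True)
class Domain:
    """Axis-aligned image domain.

    Parameters
    ----------
    pixel_counts:
        Number of pixels per axis (length 2 or 3).
    lower:
        Physical coordinate of the domain's lower corner (default origin).
    spacing:
        Physical length of one pixel per axis (default 1, i.e. pixel units).
    """

    pixel_counts: tuple
    lower: tuple = None
    spacing: tuple = None

    def __post_init__(self):
        counts = tuple(int(c) for c in self.pixel_counts)
        if len(counts) not in (2, 3):
            raise ValueError("domain must be 2D or 3D")
        if any(c < 1 for c in counts):
            raise ValueError("pixel counts must be positive")
        object.__setattr__(self, "pixel_counts", counts)
        lower = self.lower if self.lower is not None else (0.0,) * len(counts)
        spacing = self.spacing if self.spacing is not None else (1.0,) * len(counts)
        lower = tuple(float(x) for x in lower)
        spacing = tuple(float(s) for s in spacing)
        if len(lower) != len(counts) or len(spacing) != len(counts):
            raise ValueError("lower/spacing length must match dimension")
        if any(s <= 0 for s in spacing):
            raise ValueError("spacing must be positive")
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "spacing", spacing)

    @property
    def dim(self) -> int:
        return len(self.pixel_counts)

    @property
    def upper(self) -> tuple:
        return tuple(l + c * s for l, c, s in
                     zip(self.lower, self.pixel_counts, self.spacing))

    @property
    def extent(self) -> tuple:
        return tuple(c * s for c, s in zip(self.pixel_counts, self.spacing))

    @classmethod
    def for_image(cls, shape) -> "Domain":
        """Pixel-unit domain for an image array shape."""
        return cls(pixel_counts=tuple(int(s) for s in shape))
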