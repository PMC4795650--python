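"""Fully specified synthetic sequences with analytic ground truth.

The main generator reproduces the two-disk vortex benchmark: two disks
(radii 0.15 and 0.1, centers (0.5, 0.75) and (0.2, 0.2) in the unit
square) textured with uniform random intensities in [200, 255] inside
and [50, 155] outside, ramping to 200 (inside) and 50 (outside) near
the contour, and deformed by the divergence-free vortex field

    u(x, y) = -sin^2(pi x) sin(2 pi y),
    v(x, y) =  sin^2(pi y) sin(2 pi x).

Ground truth is obtained by RK4 characteristic tracing of the same
field, which also serves as the independent oracle for the tracker.
Additional generators build translation/occlusion pairs for the
registration tests and 3D sphere phantoms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "VortexSpec", "vortex_velocity", "make_vortex_sequence",
    "make_translation_pair", "make_sphere_sequence",
]


@dataclass
class VortexSpec:
    """Parameters of the two-disk vortex benchmark sequence."""

    n_frames: int = 50
    size: int = 100
    dt: float = 0.002
    radii: tuple = (0.15, 0.1)
    centers: tuple = ((0.5, 0.75), (0.2, 0.2))
    interior_range: tuple = (200.0, 255.0)
    exterior_range: tuple = (50.0, 155.0)
    ramp_px: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 1 or self.size < 8:
            raise ValueError("need at least one frame and 8 px")
        if any(r <= 0 for r in self.radii):
            raise ValueError("radii must be positive")
        if any(not (0 < c < 1) for ctr in self.centers for c in ctr):
            raise ValueError("centers must lie inside the unit square")
        if min(self.interior_range) <= max(self.exterior_range):
            raise ValueError("interior intensities must exceed exterior")

    def sdf(self, pts_unit: np.ndarray) -> np.ndarray:
        """Signed distance (positive inside) to the union of the disks."""
        vals = []
        for r, c in zip(self.radii, self.centers):
            d = np.linalg.norm(pts_unit - np.asarray(c), axis=-1)
            vals.append(r - d)
        return np.max(vals, axis=0)


def vortex_velocity(x, y):
    """Divergence-free single-vortex field on the unit square.

    Zero normal component on the boundary; vanishes at the corners.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    u = -np.sin(np.pi * x) ** 2 * np.sin(2.0 * np.pi * y)
    v = np.sin(np.pi * y) ** 2 * np.sin(2.0 * np.pi * x)
    return u, v


def _trace_back(pts: np.ndarray, t_total: float, substeps: int) -> np.ndarray:
    """RK4 backward characteristic tracing through the vortex field."""
    if t_total == 0 or substeps == 0:
        return pts.copy()
    p = pts.copy()
    dt = -t_total / substeps

    def vel(q):
        u, v = vortex_velocity(q[:, 0], q[:, 1])
        return np.stack([u, v], axis=1)

    for _ in range(substeps):
        k1 = vel(p)
        k2 = vel(p + 0.5 * dt * k1)
        k3 = vel(p + 0.5 * dt * k2)
        k4 = vel(p + dt * k3)
        p = p + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
    return p


def _textured_frame0(spec: VortexSpec) -> np.ndarray:
    rng = np.random.default_rng(spec.seed)
    n = spec.size
    tex_in = rng.uniform(*spec.interior_range, (n, n))
    tex_out = rng.uniform(*spec.exterior_range, (n, n))
    ii, jj = np.meshgrid(np.arange(n) + 0.5, np.arange(n) + 0.5,
                         indexing="ij")
    pts = np.stack([ii / n, jj / n], axis=-1)
    sd = spec.sdf(pts) * n  # in pixels
    ramp = np.clip(np.abs(sd) / spec.ramp_px, 0.0, 1.0)
    inside = sd > 0
    lo_in, lo_out = spec.interior_range[0], spec.exterior_range[0]
    img = np.where(inside,
                   lo_in + ramp * (tex_in - lo_in),
                   lo_out + ramp * (tex_out - lo_out))
    return img


def make_vortex_sequence(spec: VortexSpec, substeps_per_frame: int = 4):
    """Frames and ground-truth masks of the deforming two-disk pattern.

    Frame ``k`` carries the frame-0 texture advected for ``k * dt`` by
    RK4 characteristic tracing (backward, ``substeps_per_frame`` RK4
    steps per frame interval); the truth mask applies the same tracing
    to the initial signed distance.  The texture is resampled from
    frame 0 by bilinear interpolation.  Returns ``(frames, masks)`` as
    arrays of shape ``(n_frames, size, size)``.
    """
    n = spec.size
    img0 = _textured_frame0(spec)
    ii, jj = np.meshgrid(np.arange(n) + 0.5, np.arange(n) + 0.5,
                         indexing="ij")
    pts = np.stack([ii.ravel() / n, jj.ravel() / n], axis=1)
    frames = [img0]
    masks = [spec.sdf(pts).reshape(n, n) > 0]
    for k in range(1, spec.n_frames):
        back = _trace_back(pts, k * spec.dt, substeps_per_frame * k)
        coords = np.stack([back[:, 0] * n - 0.5, back[:, 1] * n - 0.5])
        img = ndimage.map_coordinates(img0, coords, order=1,
                                      mode="nearest").reshape(n, n)
        frames.append(img)
        masks.append(spec.sdf(back).reshape(n, n) > 0)
    return np.stack(frames), np.stack(masks)


def make_translation_pair(shift, occlusion_box=None, seed: int = 0,
                          size: int = 64, n_blobs: int = 6):
    """Smooth random blob image and its exactly shifted copy.

    The blobs are Gaussian bumps evaluated analytically, so the second
    frame is an exact (not resampled) translation by ``shift`` pixels.
    ``occlusion_box = (i0, i1, j0, j1)`` pastes a constant-intensity
    rectangle into the second frame; its support is returned.  Returns
    ``(frame0, frame1, info)`` with ``info`` holding the shift and the
    occluder mask.
    """
    shift = np.asarray(shift, dtype=float)
    if np.abs(shift).max() >= size / 4:
        raise ValueError("shift too large for the frame size")
    rng = np.random.default_rng(seed)
    centers = rng.uniform(size * 0.2, size * 0.8, (n_blobs, 2))
    amps = rng.uniform(0.4, 1.0, n_blobs)
    sigmas = rng.uniform(size / 12, size / 6, n_blobs)

    def render(offset):
        ii, jj = np.meshgrid(np.arange(size) + 0.5, np.arange(size) + 0.5,
                             indexing="ij")
        out = np.zeros((size, size))
        for c, a, s in zip(centers, amps, sigmas):
            out += a * np.exp(-(((ii - offset[0]) - c[0]) ** 2
                                + ((jj - offset[1]) - c[1]) ** 2)
                              / (2.0 * s * s))
        return 50.0 + 150.0 * out

    frame0 = render((0.0, 0.0))
    frame1 = render(shift)
    occ_mask = np.zeros((size, size), dtype=bool)
    if occlusion_box is not None:
        i0, i1, j0, j1 = occlusion_box
        frame1[i0:i1, j0:j1] = 240.0
        occ_mask[i0:i1, j0:j1] = True
    info = {"shift": shift, "occlusion": occ_mask}
    return frame0, frame1, info


def _value_noise(rng, size: int, scale: int = 4):
    coarse = rng.uniform(0.0, 1.0, (size // scale + 2,) * 3)
    return ndimage.zoom(coarse, scale, order=1)[:size, :size, :size]


def make_sphere_sequence(size: int = 48, radius: float = 12.0,
                         motion: str = "static", n_frames: int = 2,
                         amplitude: float = 0.2, translation=(2.0, 0.0, 0.0),
                         seed: int = 0):
    """3D two-level sphere phantom with analytic masks.

    ``motion`` is ``"static"``, ``"translate"`` (center moves by
    ``translation`` voxels per frame) or ``"oscillate"`` (radius
    ``r0 * (1 + amplitude sin t)`` with one period over the sequence).
    The interior texture moves rigidly with the center so consecutive
    frames are related by a true displacement field.  Returns
    ``(frames, masks)``, each ``(n_frames, size, size, size)``.
    """
    if radius <= 0 or radius * (1 + abs(amplitude)) >= size / 2 - 2:
        raise ValueError("radius does not fit in the volume")
    rng = np.random.default_rng(seed)
    noise_in = _value_noise(rng, size)
    noise_out = _value_noise(rng, size)
    grids = np.meshgrid(*[np.arange(size) + 0.5] * 3, indexing="ij")
    frames = []
    masks = []
    center0 = np.full(3, size / 2.0)
    for k in range(n_frames):
        if motion == "translate":
            center = center0 + k * np.asarray(translation, dtype=float)
        else:
            center = center0
        if motion == "oscillate":
            t = 2.0 * np.pi * k / max(n_frames, 1)
            r = radius * (1.0 + amplitude * np.sin(t))
        else:
            r = radius
        d = np.sqrt(sum((g - c) ** 2 for g, c in zip(grids, center)))
        sd = r - d
        inside = sd > 0
        # sample the interior texture in body coordinates (moves rigidly)
        off = (center - center0).astype(int)
        tex_in = np.roll(noise_in, off, axis=(0, 1, 2))
        img = np.where(inside,
                       200.0 + np.clip(np.abs(sd) / 2.0, 0, 1)
                       * (55.0 * tex_in),
                       50.0 + np.clip(np.abs(sd) / 2.0, 0, 1)
                       * (105.0 * noise_out))
        frames.append(img)
        masks.append(inside)
    return np.stack(frames), np.stack(masks)
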