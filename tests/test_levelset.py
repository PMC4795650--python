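import numpy as np
import pytest

from adaptivetrack.geometry import Domain
from adaptivetrack.levelset import (LevelSetField, advect, interpolate,
                                    mask_to_sdf, pixel_sdf, reinitialize,
                                    sdf_to_mask, smoothed_dirac,
                                    smoothed_heaviside)
from adaptivetrack.operators import get_ops
from adaptivetrack.synthetic import vortex_velocity
from adaptivetrack.tree import NodeField, build_uniform_tree
from conftest import circle_sdf


def _field(tree, fn):
    return NodeField(tree, fn(tree.vertex_positions()))


# ---------------------------------------------------------------------------
# interpolation


def test_interpolate_at_vertices_is_exact(circle_tree):
    rng = np.random.default_rng(0)
    f = NodeField(circle_tree, rng.uniform(-1, 1, circle_tree.n_vertices))
    pos = circle_tree.vertex_positions()
    sample = rng.choice(circle_tree.n_vertices, 100, replace=False)
    got = interpolate(f, pos[sample])
    assert np.allclose(got, f.values[sample], atol=1e-13)


def test_interpolate_affine_exact(circle_tree):
    f = _field(circle_tree, lambda p: 2 * p[:, 0] - 3 * p[:, 1] + 1)
    rng = np.random.default_rng(1)
    pts = rng.uniform(0.02, 0.98, (300, 2))
    got = interpolate(f, pts)
    assert np.allclose(got, 2 * pts[:, 0] - 3 * pts[:, 1] + 1, atol=1e-12)


def test_interpolate_matches_per_leaf_oracle(circle_tree):
    """Brute-force bilinear evaluation inside the containing leaf."""
    tree = circle_tree
    rng = np.random.default_rng(2)
    f = NodeField(tree, rng.uniform(0, 1, tree.n_vertices))
    pts = rng.uniform(0.01, 0.99, (50, 2))
    got = interpolate(f, pts)
    for k, p in enumerate(pts):
        t = tree.physical_to_ticks(p[None])[0]
        cell = np.floor(t).astype(int)
        lid = int(tree.leafmap[cell[0], cell[1]])
        o = tree.leaf_origins[lid]
        s = int(tree.leaf_sizes[lid])
        xi = (t - o) / s
        cids = tree.leaf_corner_ids[lid]
        # corner order: bit a of index k selects upper face along axis a
        v = 0.0
        for ci in range(4):
            wx = xi[0] if (ci >> 0) & 1 else 1 - xi[0]
            wy = xi[1] if (ci >> 1) & 1 else 1 - xi[1]
            v += wx * wy * f.values[cids[ci]]
        assert got[k] == pytest.approx(v, rel=1e-12)


def test_interpolate_clamps_outside(circle_tree):
    f = _field(circle_tree, lambda p: p[:, 0])
    out = interpolate(f, np.array([[-5.0, 0.5], [7.0, 0.5]]))
    assert out[0] == pytest.approx(0.0, abs=1e-12)
    assert out[1] == pytest.approx(1.0, abs=1e-12)


# ---------------------------------------------------------------------------
# advection


def test_advect_zero_velocity_identity(circle_tree):
    phi = LevelSetField(_field(circle_tree, circle_sdf()))
    zero = [NodeField(circle_tree, np.zeros(circle_tree.n_vertices))] * 2
    out = advect(phi, zero, 0.1)
    assert np.allclose(out.values, phi.values)


def test_advect_uniform_velocity_affine_field(circle_tree):
    tree = circle_tree
    phi = LevelSetField(_field(tree, lambda p: p[:, 0]))
    vel = [NodeField(tree, np.full(tree.n_vertices, 0.5)),
           NodeField(tree, np.zeros(tree.n_vertices))]
    out = advect(phi, vel, 0.02)
    pos = tree.vertex_positions()
    interior = (pos > 0.05).all(axis=1) & (pos < 0.95).all(axis=1)
    assert np.allclose(out.values[interior], (pos[:, 0] - 0.01)[interior],
                       atol=1e-10)


def test_advect_rejects_nonfinite_velocity(circle_tree):
    phi = LevelSetField(_field(circle_tree, circle_sdf()))
    bad = np.zeros(circle_tree.n_vertices)
    bad[0] = np.nan
    with pytest.raises(ValueError):
        advect(phi, [NodeField(circle_tree, bad),
                     NodeField(circle_tree, np.zeros_like(bad))], 0.01)


def test_advect_translates_disk_centroid():
    dom = Domain(pixel_counts=(128, 128), spacing=(1 / 128, 1 / 128))
    phi_fn = circle_sdf((0.4, 0.5), 0.2)
    tree = build_uniform_tree(dom, level=7)
    phi = LevelSetField(_field(tree, phi_fn))
    vel = [NodeField(tree, np.full(tree.n_vertices, 0.3)),
           NodeField(tree, np.zeros(tree.n_vertices))]
    for _ in range(10):
        phi = advect(phi, vel, 0.005)
    mask = sdf_to_mask(phi)
    cx = ((np.arange(128) + 0.5) / 128)
    centroid = (mask * cx[:, None]).sum() / mask.sum()
    assert centroid - 0.4 == pytest.approx(0.015, abs=1 / 128)


def test_vortex_advection_reversibility():
    """Forward then reversed advection restores the disk (Dice >= 0.95)."""
    from adaptivetrack.metrics import dice
    dom = Domain(pixel_counts=(128, 128), spacing=(1 / 128, 1 / 128))
    tree = build_uniform_tree(dom, level=7)
    pos = tree.vertex_positions()
    phi_fn = circle_sdf((0.5, 0.75), 0.15)
    phi = LevelSetField(NodeField(tree, phi_fn(pos)))
    u, v = vortex_velocity(pos[:, 0], pos[:, 1])
    vel_f = [NodeField(tree, u), NodeField(tree, v)]
    vel_b = [NodeField(tree, -u), NodeField(tree, -v)]
    dt, steps = 0.002, 25
    for _ in range(steps):
        phi = advect(phi, vel_f, dt)
    for _ in range(steps):
        phi = advect(phi, vel_b, dt)
    mask0 = sdf_to_mask(LevelSetField(NodeField(tree, phi_fn(pos))))
    mask1 = sdf_to_mask(phi)
    assert dice(mask0, mask1) >= 0.95


# ---------------------------------------------------------------------------
# reinitialization


def test_reinit_line_sdf_stationary(circle_tree):
    tree = circle_tree
    pos = tree.vertex_positions()
    phi = LevelSetField(NodeField(tree, pos[:, 0] - 0.47))
    out = reinitialize(phi, n_iter=10)
    interior = (pos[:, 0] > 0.1) & (pos[:, 0] < 0.9)
    assert np.abs(out.values - phi.values)[interior].max() < 1e-6
    assert out.is_signed_distance


def test_reinit_idempotent_on_exact_sdf(circle_tree):
    tree = circle_tree
    pos = tree.vertex_positions()
    sd = circle_sdf()(pos)
    out = reinitialize(LevelSetField(NodeField(tree, sd)), n_iter=10)
    h = tree.min_spacing
    band = np.abs(sd) < 5 * h
    assert np.abs(out.values - sd)[band].max() < 5e-4


def test_reinit_restores_gradient_from_scaled_sdf(circle_tree):
    tree = circle_tree
    ops = get_ops(tree)
    pos = tree.vertex_positions()
    sd = circle_sdf()(pos)
    out = reinitialize(LevelSetField(NodeField(tree, 5.0 * sd)), n_iter=20)
    g = np.linalg.norm(np.stack([ops.d_central(out.values, a)
                                 for a in range(2)]), axis=0)
    h = tree.min_spacing
    band = np.abs(sd) < 3 * h
    assert g[band].min() > 0.9
    assert g[band].max() < 1.1


def test_reinit_zero_level_stays_put(circle_tree):
    tree = circle_tree
    pos = tree.vertex_positions()
    out = reinitialize(
        LevelSetField(NodeField(tree, 5.0 * circle_sdf()(pos))), n_iter=20)
    h = tree.min_spacing
    # radius of the zero crossing along many rays
    for theta in np.linspace(0, 2 * np.pi, 37)[:-1]:
        rr = np.linspace(0.15, 0.35, 300)
        pts = np.stack([0.5 + rr * np.cos(theta),
                        0.5 + rr * np.sin(theta)], axis=1)
        vals = out.interpolate(pts)
        idx = np.where(np.diff(np.sign(vals)))[0]
        assert len(idx) > 0
        i = idx[0]
        r0 = rr[i] - vals[i] * (rr[i + 1] - rr[i]) / (vals[i + 1] - vals[i])
        assert abs(r0 - 0.25) < h


def test_reinit_requires_iterations(circle_tree):
    phi = LevelSetField(NodeField(circle_tree,
                                  np.ones(circle_tree.n_vertices)))
    with pytest.raises(ValueError):
        reinitialize(phi, n_iter=0)


# ---------------------------------------------------------------------------
# mollified Heaviside / Dirac


def test_heaviside_symmetry_and_support():
    eps = 0.1
    assert smoothed_heaviside(0.0, eps) == pytest.approx(0.5)
    assert smoothed_heaviside(2 * eps, eps) == 1.0
    assert smoothed_heaviside(-2 * eps, eps) == 0.0
    assert smoothed_dirac(2 * eps, eps) == 0.0
    assert smoothed_dirac(-2 * eps, eps) == 0.0
    x = np.linspace(-3 * eps, 3 * eps, 1001)
    h = smoothed_heaviside(x, eps)
    assert ((h >= 0) & (h <= 1)).all()
    assert (np.diff(h) >= -1e-15).all()


def test_dirac_integrates_to_one():
    eps = 0.07
    x = np.linspace(-0.5, 0.5, 40001)
    integral = np.trapezoid(smoothed_dirac(x, eps), x)
    assert integral == pytest.approx(1.0, abs=1e-6)


def test_heaviside_requires_positive_width():
    with pytest.raises(ValueError):
        smoothed_heaviside(0.0, 0.0)
    with pytest.raises(ValueError):
        smoothed_dirac(0.0, -1.0)


# ---------------------------------------------------------------------------
# mask <-> signed distance


def test_mask_to_sdf_disk(circle_tree):
    n = 128
    ii, jj = np.meshgrid(np.arange(n) + 0.5, np.arange(n) + 0.5,
                         indexing="ij")
    mask = ((ii / n - 0.5) ** 2 + (jj / n - 0.5) ** 2) < 0.25 ** 2
    phi = mask_to_sdf(mask, circle_tree)
    h = circle_tree.min_spacing
    # interior positive; center value close to the radius
    assert phi.interpolate(np.array([[0.5, 0.5]]))[0] == pytest.approx(
        0.25, abs=2 * h)
    assert phi.interpolate(np.array([[0.05, 0.05]]))[0] < 0


def test_mask_sdf_mask_roundtrip(circle_tree):
    from adaptivetrack.metrics import dice
    n = 128
    ii, jj = np.meshgrid(np.arange(n) + 0.5, np.arange(n) + 0.5,
                         indexing="ij")
    mask = ((ii / n - 0.5) ** 2 + (jj / n - 0.5) ** 2) < 0.25 ** 2
    phi = mask_to_sdf(mask, circle_tree)
    back = sdf_to_mask(phi)
    assert dice(mask, back) >= 0.99
    # sign convention: interior is {phi > 0}
    assert phi.values[np.argmax(phi.values)] > 0


def test_mask_to_sdf_empty_mask_errors(circle_tree):
    with pytest.raises(ValueError):
        mask_to_sdf(np.zeros((128, 128), dtype=bool), circle_tree)


def test_full_mask_positive_inside():
    mask = np.ones((16, 16), dtype=bool)
    sd = pixel_sdf(mask)
    assert (sd > 0).all()
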