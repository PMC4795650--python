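import itertools

import numpy as np
import pytest

from adaptivetrack.geometry import Domain
from adaptivetrack.tree import (AdaptiveTree, NodeField, build_tree,
                                build_uniform_tree, cell_average,
                                cell_values_from_image, enforce_grading,
                                load_tree, save_tree,
                                vertex_neighborhood)
from conftest import circle_sdf


# ---------------------------------------------------------------------------
# independent oracle: direct recursion applying the Whitney rule


def brute_force_leaf_count(domain, phi, max_level, lip):
    spacing = np.asarray(domain.spacing)
    lower = np.asarray(domain.lower)
    counts = np.asarray(domain.pixel_counts)

    def recurse(level, origin):
        size = 1 << (max_level - level)
        corners = [np.asarray(origin) + np.asarray(off) * size
                   for off in itertools.product((0, 1), repeat=domain.dim)]
        vals = [abs(float(phi((lower + c * spacing)[None])[0]))
                for c in corners]
        diag = np.sqrt(((size * spacing) ** 2).sum())
        inside = all(origin[a] < counts[a] for a in range(domain.dim))
        if min(vals) <= 0.5 * lip * diag and level < max_level and inside:
            half = size // 2
            return sum(recurse(level + 1,
                               tuple(origin[a] + off[a] * half
                                     for a in range(domain.dim)))
                       for off in itertools.product((0, 1),
                                                    repeat=domain.dim))
        return 1

    return recurse(0, (0,) * domain.dim)


def test_trivial_field_keeps_root_only():
    dom = Domain(pixel_counts=(64, 64), spacing=(1 / 64, 1 / 64))
    tree = build_tree(dom, lambda p: np.full(len(np.atleast_2d(p)), 10.0),
                      max_level=6, lip=1.0, grade=False)
    assert tree.n_leaves == 1
    assert tree.leaf_levels[0] == 0


def test_sign_change_leaves_are_finest(circle_tree):
    phi = circle_sdf()
    vals = phi(circle_tree.ticks_to_physical(circle_tree.vertices))
    corner_vals = vals[circle_tree.leaf_corner_ids]
    has_sign_change = (corner_vals.min(axis=1) < 0) & (corner_vals.max(axis=1) > 0)
    assert has_sign_change.any()
    assert (circle_tree.leaf_levels[has_sign_change]
            == circle_tree.max_level).all()


def test_leaf_count_matches_brute_force_recursion():
    dom = Domain(pixel_counts=(64, 64), spacing=(1 / 64, 1 / 64))
    phi = circle_sdf()
    tree = build_tree(dom, phi, max_level=6, lip=1.2, grade=False)
    assert tree.n_leaves == brute_force_leaf_count(dom, phi, 6, 1.2)


def test_nonfinite_phi_rejected():
    dom = Domain(pixel_counts=(16, 16))
    with pytest.raises(ValueError):
        build_tree(dom, lambda p: np.full(len(np.atleast_2d(p)), np.nan),
                   max_level=4, lip=1.0)


def test_partition_volume(circle_tree):
    assert circle_tree.leaf_volumes().sum() == pytest.approx(1.0, rel=1e-12)


def test_partition_volume_random_trees():
    rng = np.random.default_rng(3)
    dom = Domain(pixel_counts=(32, 32))
    for seed in range(5):
        c = rng.uniform(5, 27, 2)
        r = rng.uniform(3, 10)
        tree = build_tree(dom, lambda p: r - np.linalg.norm(
            np.atleast_2d(p) - c, axis=1), max_level=5, lip=1.2)
        assert tree.leaf_volumes().sum() == pytest.approx(32 * 32, rel=1e-12)
        lm = tree.leafmap  # also asserts full cover without overlap
        assert lm.min() >= 0


def test_raising_max_level_never_coarsens():
    phi = circle_sdf()
    coarse = build_tree(Domain(pixel_counts=(32, 32), spacing=(1 / 32,) * 2),
                        phi, max_level=5, lip=1.2, grade=False)
    fine = build_tree(Domain(pixel_counts=(64, 64), spacing=(1 / 64,) * 2),
                      phi, max_level=6, lip=1.2, grade=False)
    # every coarse-tree cell is a union of fine-tree cells: the fine tree
    # refines at least as deep everywhere
    fine_map = fine.leafmap
    for lid in range(coarse.n_leaves):
        o = coarse.leaf_origins[lid] * 2  # ticks double when depth grows
        s = int(coarse.leaf_sizes[lid]) * 2
        sub = fine_map[o[0]:o[0] + s, o[1]:o[1] + s]
        sizes = fine.leaf_sizes[np.unique(sub)]
        assert sizes.max() <= s


def test_whitney_band_diagonal_bound(circle_tree):
    # contrapositive of the split rule: a leaf's diagonal never exceeds
    # 2 |phi| / Lip at its center, up to one finest diagonal of slack
    phi = circle_sdf()
    ctr = circle_tree.ticks_to_physical(
        circle_tree.leaf_origins + circle_tree.leaf_sizes[:, None] / 2.0)
    diag = circle_tree.leaf_diag()
    bound = 2.0 * np.abs(phi(ctr)) / 1.2 + diag.min()
    assert (diag <= bound).all()


def test_whitney_compression():
    # far fewer leaves than the uniform grid at the same depth
    dom = Domain(pixel_counts=(256, 256), spacing=(1 / 256, 1 / 256))
    tree = build_tree(dom, circle_sdf(), max_level=8, lip=1.2)
    assert tree.n_leaves < 0.10 * 256 ** 2


# ---------------------------------------------------------------------------
# cell averaging


def test_cell_average_constant_image():
    dom = Domain.for_image((16, 16))
    tree = build_uniform_tree(dom, level=2)
    img = np.full((16, 16), 37.0)
    assert cell_average(tree, img, 0) == pytest.approx(37.0)


def test_cell_average_of_root_is_global_mean():
    dom = Domain.for_image((2, 2))
    tree = build_uniform_tree(dom, level=0)
    img = np.array([[0.0, 0.0], [100.0, 100.0]])
    assert cell_average(tree, img, 0) == pytest.approx(50.0)


def test_cell_average_matches_direct_summation():
    rng = np.random.default_rng(0)
    img = rng.uniform(0, 255, (16, 16))
    dom = Domain.for_image(img.shape)
    tree = build_tree(dom, circle_sdf((8, 8), 4.0), max_level=4, lip=1.2)
    vals = cell_values_from_image(tree, img)
    for lid in range(tree.n_leaves):
        o = tree.leaf_origins[lid]
        s = int(tree.leaf_sizes[lid])
        direct = img[o[0]:o[0] + s, o[1]:o[1] + s].mean()
        assert vals[lid] == pytest.approx(direct, rel=1e-12)
        assert cell_average(tree, img, lid) == pytest.approx(direct, rel=1e-12)


def test_cell_average_outside_image_errors():
    # 10x10 image embedded in a 16x16 dyadic square
    dom = Domain.for_image((10, 10))
    tree = build_uniform_tree(dom, level=2)  # 4x4 cells of 4 px
    outside = [i for i in range(tree.n_leaves)
               if (tree.leaf_origins[i] >= 10).any()]
    assert outside
    img = np.zeros((10, 10))
    with pytest.raises(ValueError):
        cell_average(tree, img, outside[0])
    # the bulk routine instead clamps to the nearest pixel
    vals = cell_values_from_image(tree, img + 5.0)
    assert np.allclose(vals, 5.0)


def test_finest_level_reproduces_image():
    rng = np.random.default_rng(1)
    img = rng.uniform(0, 255, (8, 8))
    tree = build_uniform_tree(Domain.for_image(img.shape))
    vals = cell_values_from_image(tree, img)
    lm = tree.leafmap
    assert np.allclose(vals[lm], img)


# ---------------------------------------------------------------------------
# grading and vertex neighborhoods


def _two_level_tree():
    """One coarse level-1 cell next to level-2 cells (graded, T-junctions)."""
    dom = Domain.for_image((4, 4))
    levels = [1]
    origins = [(0, 0)]
    for i in range(4):
        for j in range(4):
            if i < 2 and j < 2:
                continue
            levels.append(2)
            origins.append((i, j))
    return AdaptiveTree(dom, 2, np.array(levels), np.array(origins))


def test_grading_idempotent_on_graded_tree():
    tree = _two_level_tree()
    graded = enforce_grading(tree)
    assert graded.n_leaves == tree.n_leaves


def test_grading_splits_coarse_neighbor():
    # level-0 leaf adjacent to level-2 leaves must be split
    dom = Domain.for_image((8, 8))
    levels = [1]
    origins = [(0, 0)]
    for i in range(8):
        for j in range(8):
            if i < 4 and j < 4:
                continue
            levels.append(3)
            origins.append((i, j))
    tree = AdaptiveTree(dom, 3, np.array(levels), np.array(origins))
    graded = enforce_grading(tree)
    assert _is_graded(graded)
    assert graded.leaf_volumes().sum() == tree.leaf_volumes().sum()
    # only refinement happened
    assert graded.n_leaves > tree.n_leaves


def _is_graded(tree):
    lm = tree.leafmap
    lv = tree.leaf_levels
    dim = tree.dim
    for axis in range(dim):
        a = np.moveaxis(lm, axis, 0)
        l0, l1 = lv[a[:-1]], lv[a[1:]]
        if np.abs(l0 - l1).max() > 1:
            return False
    if dim == 3:  # edge-adjacency across two axes
        for ax1, ax2 in [(0, 1), (0, 2), (1, 2)]:
            a = np.moveaxis(lm, (ax1, ax2), (0, 1))
            l0, l1 = lv[a[:-1, :-1]], lv[a[1:, 1:]]
            if np.abs(l0 - l1).max() > 1:
                return False
            l0, l1 = lv[a[:-1, 1:]], lv[a[1:, :-1]]
            if np.abs(l0 - l1).max() > 1:
                return False
    return True


def test_grading_property_random_trees():
    rng = np.random.default_rng(7)
    dom = Domain(pixel_counts=(64, 64), spacing=(1 / 64, 1 / 64))
    for seed in range(4):
        c = rng.uniform(0.2, 0.8, 2)
        r = rng.uniform(0.05, 0.3)
        tree = build_tree(dom, circle_sdf(c, r), max_level=6, lip=1.2,
                          grade=True)
        assert _is_graded(tree)


def test_interior_vertex_of_uniform_tree():
    tree = build_uniform_tree(Domain.for_image((8, 8)), level=3)
    nb = vertex_neighborhood(tree, (4, 4))
    assert all(info.kind == "node" for info in nb.values())
    assert all(info.distance == pytest.approx(1.0) for info in nb.values())
    assert len(nb) == 4


def test_tjunction_classification_and_record():
    tree = _two_level_tree()
    # hanging node at the midpoint of the coarse cell's right edge
    nb = vertex_neighborhood(tree, (1, 2))
    info = nb[(1, -1)]  # towards the coarse cell's interior
    assert info.kind == "tjunction"
    assert len(info.interp) == 2       # two bounding nodes on the far edge
    assert len(info.transverse) == 1   # one correction axis
    axis, vm, sm, vp, sp_ = info.transverse[0]
    assert axis == 0 and sm == pytest.approx(1.0) and sp_ == pytest.approx(1.0)
    # distance spans the whole coarse cell
    assert info.distance == pytest.approx(2.0)
    # boundary vertex: outward directions are missing
    nb0 = vertex_neighborhood(tree, (0, 0))
    assert nb0[(0, -1)].kind == "missing"
    assert nb0[(1, -1)].kind == "missing"


def test_vertex_neighborhood_matches_brute_force(circle_tree):
    """Independent check: nearest existing vertex along each grid line."""
    tree = circle_tree
    verts = tree.vertices
    rng = np.random.default_rng(5)
    sample = rng.choice(tree.n_vertices, size=200, replace=False)
    vset = {}
    for i, v in enumerate(verts):
        vset[tuple(v)] = i
    for vi in sample:
        nb = vertex_neighborhood(tree, int(vi))
        v = verts[vi]
        for axis in range(2):
            for sgn in (-1, 1):
                info = nb[(axis, sgn)]
                # brute force: scan ticks outward along the axis
                found = None
                for step in range(1, tree.side + 1):
                    q = v.copy()
                    q[axis] += sgn * step
                    if q[axis] < 0 or q[axis] > tree.side:
                        break
                    if tuple(q) in vset:
                        found = step
                        break
                ticks = None if info.kind == "missing" else int(
                    round(info.distance / tree.spacing[axis]))
                if info.kind == "missing":
                    assert found is None or v[axis] in (0, tree.side)
                elif info.kind == "node":
                    assert found == ticks
                else:  # tjunction: the next vertex is farther or absent
                    assert found is None or found >= ticks


def test_vertex_neighborhood_invalid_vertex(circle_tree):
    with pytest.raises(ValueError):
        vertex_neighborhood(circle_tree, (3, 3))


# ---------------------------------------------------------------------------
# dump / restore


def test_tree_roundtrip_bit_exact(tmp_path, circle_tree):
    path = tmp_path / "tree.txt"
    save_tree(circle_tree, path)
    back = load_tree(path)
    assert back.max_level == circle_tree.max_level
    assert back.domain == circle_tree.domain
    assert np.array_equal(back.leaf_levels, circle_tree.leaf_levels)
    assert np.array_equal(back.leaf_origins, circle_tree.leaf_origins)


def test_node_field_validation(circle_tree):
    with pytest.raises(ValueError):
        NodeField(circle_tree, np.zeros(3))
    f = NodeField(circle_tree, np.zeros(circle_tree.n_vertices))
    f.values[0] = np.nan
    with pytest.raises(ValueError):
        f.check_finite()
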