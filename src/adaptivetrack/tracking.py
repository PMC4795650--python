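"""Per-frame tracking: tree rebuild, joint flow/segmentation, hand-off.

Each frame is processed on a fresh Whitney tree built around the
previous frame's contour (finest cells on the front, 2:1 graded).  Both
frames are averaged onto the tree; then, twice per frame, the flow and
sparse error are re-estimated with the shape-coupling term and the
relaxed indicator is re-solved with the edge, dynamic-prior and
combination TV weights.  The indicator is thresholded at 0.5, converted
back to a signed distance, and handed to the next frame.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .config import RunConfig
from .geometry import Domain, max_level_for_image
from .levelset import (LevelSetField, mask_to_sdf, pixel_sdf, reinitialize,
                       sample_pixel_field, sdf_to_mask, smoothed_heaviside)
from .registration import (CouplingTerm, FlowField, SparseError,
                           solve_flow_and_G, warp)
from .segmentation import (IntensityModel, RelaxedIndicator, combo_weight,
                           edge_function, prior_weight, solve_segmentation)
from .tree import AdaptiveTree, NodeField, build_tree, node_values_from_image

__all__ = [
    "TrackingState", "EmptySegmentationError",
    "init_state", "track_frame", "track_sequence", "init_3d_from_2d",
]


class EmptySegmentationError(RuntimeError):
    """Raised when a frame's segmentation contains no foreground."""

    def __init__(self, message, frame_index=None):
        super().__init__(message)
        self.frame_index = frame_index


@dataclass
class TrackingState:
    """Per-frame bundle: shape, indicator, flow, sparse error, tree."""

    frame_index: int
    tree: AdaptiveTree
    shape: LevelSetField            # signed distance, interior positive
    indicator: Optional[RelaxedIndicator]
    flow: Optional[FlowField]
    sparse_error: Optional[SparseError]
    mask: np.ndarray                # pixel-grid binary mask
    frame: np.ndarray               # pixel-grid intensities of this frame

    def __post_init__(self):
        if not self.shape.is_signed_distance:
            raise ValueError("state shape must be a signed distance")
        for f in (self.indicator, self.flow, self.sparse_error):
            if f is not None:
                t = f.tree if hasattr(f, "tree") else f.G.tree
                if t is not self.tree:
                    raise ValueError("state fields must share one tree")

    @property
    def leaf_count(self) -> int:
        return self.tree.n_leaves


def _refine_boundary_pixels(mask: np.ndarray,
                            eta_pixels: np.ndarray) -> np.ndarray:
    """Re-assign the one-pixel boundary band by the pixel-level region term.

    The relaxed indicator lives on cell corners, half a pixel off the
    pixel-center mask convention, so the thresholded contour is
    ambiguous within one pixel.  Inside that band the full-resolution
    log-likelihood ratio is decisive and unbiased, so boundary pixels
    take its sign (negative = foreground).
    """
    from scipy import ndimage as ndi
    inner = mask & ~ndi.binary_erosion(mask)
    outer = ndi.binary_dilation(mask) & ~mask
    band = inner | outer
    out = np.where(band, eta_pixels < 0, mask)
    return out if out.any() else mask


def _build_front_tree(mask: np.ndarray, domain: Domain,
                      config: RunConfig) -> AdaptiveTree:
    sd = pixel_sdf(mask, spacing=domain.spacing)

    def phi_fn(pts):
        return sample_pixel_field(sd, pts, domain, extend=True)

    level = config.max_level if config.max_level is not None \
        else max_level_for_image(domain.pixel_counts)
    return build_tree(domain, phi_fn, level, config.lip,
                      grade=config.grading)


def init_state(frame: np.ndarray, mask: np.ndarray,
               config: RunConfig = None) -> TrackingState:
    """Initial tracking state from frame 0 and its a-priori mask."""
    config = config or RunConfig()
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptySegmentationError("initial mask is empty", 0)
    domain = Domain.for_image(frame.shape)
    tree = _build_front_tree(mask, domain, config)
    shape = mask_to_sdf(mask, tree, n_iter=config.reinit_iters)
    eps_h = config.eps_h_cells * tree.min_spacing
    ind_vals = smoothed_heaviside(shape.values, eps_h)
    indicator = RelaxedIndicator(NodeField(tree, ind_vals),
                                 NodeField(tree, ind_vals.copy()))
    return TrackingState(0, tree, shape, indicator,
                         FlowField.zero(tree), SparseError.zero(tree),
                         mask, np.asarray(frame, dtype=float))


def track_frame(state_prev: TrackingState, frame: np.ndarray,
                config: RunConfig = None,
                model: IntensityModel = None) -> TrackingState:
    """Advance the tracker by one frame.

    Rebuilds the tree around the previous contour, averages both frames
    onto it, and alternates flow/sparse-error estimation (with the
    shape-coupling term) and relaxed segmentation ``updates_per_frame``
    times before thresholding and reinitialising.
    """
    config = config or RunConfig()
    frame = np.asarray(frame, dtype=float)
    if frame.shape != state_prev.frame.shape:
        raise ValueError("frame shape changed mid-sequence")
    if model is None:
        model = IntensityModel.from_frames(state_prev.frame, state_prev.mask)
    domain = Domain.for_image(frame.shape)
    tree = _build_front_tree(state_prev.mask, domain, config)
    h = tree.min_spacing
    eps_h = config.eps_h_cells * h

    prev_sd = pixel_sdf(state_prev.mask, spacing=domain.spacing)
    phi_prev = LevelSetField(
        NodeField(tree, sample_pixel_field(prev_sd, tree.vertex_positions(),
                                           domain, extend=True)),
        is_signed_distance=True)

    reg_params = config.registration_params()
    seg_params = config.segmentation_params()
    g_edge = edge_function(tree, frame, config.gamma, config.sigma)
    # evaluate the log-likelihood ratio per pixel, then average onto the
    # tree: averaging intensities first would push boundary-mixed values
    # into the wrong histogram and bias the region term
    eta_field = node_values_from_image(tree, model.log_ratio(frame))

    phi_cur_est = phi_prev
    flow: Optional[FlowField] = None
    G: Optional[SparseError] = None
    indicator = None
    init_ind = NodeField(tree, smoothed_heaviside(phi_prev.values, eps_h))
    for _ in range(config.updates_per_frame):
        coupling = CouplingTerm(prev_shape=phi_prev,
                                current_shape=phi_cur_est,
                                weight=config.combo_weight, eps_h=eps_h)
        flow, G = solve_flow_and_G(state_prev.frame, frame, reg_params,
                                   tree=tree, init_flow=flow, init_G=G,
                                   coupling=coupling)
        prior_field = warp(phi_prev.field, flow) if config.warp_prior \
            else phi_prev.field
        dp2 = prior_weight(prior_field)
        dc2 = combo_weight(phi_prev, flow)
        w_total = NodeField(tree, g_edge.values
                            + config.prior_weight * dp2.values
                            + config.combo_weight * dc2.values)
        indicator = solve_segmentation(eta_field, w_total, seg_params,
                                       init=init_ind)
        init_ind = indicator.phi0
        phi_cur_est = reinitialize(
            LevelSetField(NodeField(tree, indicator.phi0.values - 0.5)),
            n_iter=5)

    mask = sdf_to_mask(LevelSetField(
        NodeField(tree, indicator.phi0.values - 0.5)), frame.shape)
    if config.pixel_refine:
        mask = _refine_boundary_pixels(mask, model.log_ratio(frame))
    if not mask.any():
        raise EmptySegmentationError(
            f"segmentation of frame {state_prev.frame_index + 1} is empty "
            "(all background); check the intensity model and weights",
            state_prev.frame_index + 1)
    shape = mask_to_sdf(mask, tree, n_iter=config.reinit_iters)
    return TrackingState(state_prev.frame_index + 1, tree, shape, indicator,
                         flow, G, mask, frame)


def track_sequence(frames, initial_mask: np.ndarray,
                   config: RunConfig = None, truth_masks=None,
                   keep_states: bool = False, progress=None):
    """Fold :func:`track_frame` over a sequence.

    Returns a dict with per-frame ``masks``, ``diagnostics`` (leaf
    count, vertex count, segmentation energy, Dice against
    ``truth_masks`` when given) and optionally the full ``states``.
    """
    config = config or RunConfig()
    frames = [np.asarray(f, dtype=float) for f in frames]
    if len(frames) < 2:
        raise ValueError("need at least two frames")
    model_frames = frames[:max(1, config.histogram_frames)]
    model = IntensityModel.from_frames(model_frames,
                                       [np.asarray(initial_mask, bool)]
                                       * len(model_frames))
    state = init_state(frames[0], initial_mask, config)
    masks = [state.mask]
    states = [state] if keep_states else None
    diagnostics = [_diag_row(state, truth_masks, 0, config)]
    for k, frame in enumerate(frames[1:], start=1):
        try:
            state = track_frame(state, frame, config, model)
        except EmptySegmentationError as err:
            err.frame_index = k
            raise
        masks.append(state.mask)
        diagnostics.append(_diag_row(state, truth_masks, k, config))
        if keep_states:
            states.append(state)
        if progress is not None:
            progress(k, state)
    out = {"masks": masks, "diagnostics": diagnostics}
    if keep_states:
        out["states"] = states
    return out


def _diag_row(state: TrackingState, truth_masks, k: int,
              config: RunConfig) -> dict:
    from .metrics import dice
    row = {
        "frame": k,
        "leaf_count": state.leaf_count,
        "n_vertices": state.tree.n_vertices,
        "mask_pixels": int(state.mask.sum()),
    }
    if truth_masks is not None:
        row["dice"] = dice(state.mask, truth_masks[k])
    return row


# ---------------------------------------------------------------------------
# 3D initialisation from a single 2D cross-section


def init_3d_from_2d(volume: np.ndarray, slice_index: int,
                    config: RunConfig = None, init_mask_2d=None,
                    mode: str = "propagate") -> TrackingState:
    """Initial 3D segmentation grown from one 2D cross-section.

    The 2D pipeline segments the chosen slice (last axis); the result is
    extruded along the third axis and, in ``"propagate"`` mode,
    intersected with per-slice 2D segmentations seeded by each
    neighbouring slice's result.  ``"extrude"`` mode keeps the plain
    extrusion.  The combined mask is reinitialised on a 3D tree.

    ``init_mask_2d`` seeds the slice segmentation; by default an Otsu
    threshold of the slice is used.
    """
    from skimage.filters import threshold_otsu

    config = config or RunConfig()
    volume = np.asarray(volume, dtype=float)
    if volume.ndim != 3:
        raise ValueError("a 3D volume is required")
    nz = volume.shape[2]
    if not 0 <= slice_index < nz:
        raise ValueError("slice index out of range")
    sl = volume[:, :, slice_index]
    if init_mask_2d is None:
        thr = threshold_otsu(sl)
        init_mask_2d = sl > thr
    init_mask_2d = np.asarray(init_mask_2d, dtype=bool)
    if not init_mask_2d.any():
        raise EmptySegmentationError("slice contains no object", None)

    model = IntensityModel.from_frames(sl, init_mask_2d)
    ref_mask = _segment_slice(sl, init_mask_2d, model, config)
    if not ref_mask.any():
        raise EmptySegmentationError("slice segmentation is empty", None)

    extruded = np.repeat(ref_mask[:, :, None], nz, axis=2)
    if mode == "extrude":
        mask3d = extruded
    elif mode == "propagate":
        per_slice = np.zeros_like(extruded)
        per_slice[:, :, slice_index] = ref_mask
        for direction in (1, -1):
            seed = ref_mask
            z = slice_index + direction
            while 0 <= z < nz and seed.any():
                seg = _segment_slice(volume[:, :, z], seed, model, config)
                per_slice[:, :, z] = seg
                seed = seg
                z += direction
        mask3d = extruded & per_slice
    else:
        raise ValueError("mode must be 'extrude' or 'propagate'")
    if not mask3d.any():
        raise EmptySegmentationError("3D initialisation is empty", None)
    return init_state(volume, mask3d, config)


def _segment_slice(image: np.ndarray, seed_mask: np.ndarray,
                   model: IntensityModel, config: RunConfig) -> np.ndarray:
    """One 2D relaxed segmentation seeded by a neighbouring mask."""
    if not seed_mask.any():
        return np.zeros_like(seed_mask)
    domain = Domain.for_image(image.shape)
    tree = _build_front_tree(seed_mask, domain, config)
    shape = mask_to_sdf(seed_mask, tree, n_iter=config.reinit_iters)
    g_edge = edge_function(tree, image, config.gamma, config.sigma)
    w_total = NodeField(tree, g_edge.values
                        + config.prior_weight * shape.values ** 2)
    eps_h = config.eps_h_cells * tree.min_spacing
    init = NodeField(tree, smoothed_heaviside(shape.values, eps_h))
    eta_field = node_values_from_image(tree, model.log_ratio(image))
    ind = solve_segmentation(eta_field, w_total,
                             config.segmentation_params(), init=init)
    return sdf_to_mask(LevelSetField(
        NodeField(tree, ind.phi0.values - 0.5)), image.shape)
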