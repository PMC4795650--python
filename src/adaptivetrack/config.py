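"""Run configuration: one flat record of every tunable parameter.

Defaults reproduce the constants used for all experiments: flow weights
``alpha_u = 8e-4``, ``alpha_g1 = 9e-5``, ``alpha_g2 = 3e-3``, Charbonnier
``epsilon = 1e-3``, dynamic-prior and combination weights ``2e-5``, edge
constant ``gamma = 600`` and region weight ``alpha_s1`` drawn once per
run from [0.02, 0.05] with a fixed seed.  Configurations round-trip
losslessly through YAML.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from typing import Optional

import yaml

from .registration import RegistrationParams
from .segmentation import SegmentationParams, draw_alpha_s1

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # registration
    alpha_u: float = 8e-4
    alpha_g1: float = 9e-5
    alpha_g2: float = 3e-3
    epsilon: float = 1e-3
    pyramid_levels: Optional[int] = None
    inner_iters: int = 5
    sweeps: int = 200
    sweep_tol: float = 1e-4
    # segmentation
    alpha_s1: Optional[float] = None     # None: drawn from [0.02, 0.05]
    alpha_hat: Optional[float] = None    # None: just above the bound
    beta: float = 0.1
    prior_weight: float = 2e-5
    combo_weight: float = 2e-5
    gamma: float = 600.0
    sigma: float = 1.0
    seg_outer_iters: int = 40
    dual_iters: int = 30
    warp_prior: bool = True              # warp the prior shape by the flow
    # tree
    max_level: Optional[int] = None      # None: from the image size
    lip: float = 1.2
    grading: bool = True
    # pipeline
    updates_per_frame: int = 2
    pixel_refine: bool = True            # pixel-level boundary re-assignment
    reinit_iters: int = 10
    eps_h_cells: float = 1.5             # Heaviside width, in finest cells
    seed: int = 0
    histogram_frames: int = 1

    def __post_init__(self):
        if self.alpha_s1 is None:
            self.alpha_s1 = draw_alpha_s1(self.seed)

    # -- views ---------------------------------------------------------------

    def registration_params(self) -> RegistrationParams:
        return RegistrationParams(
            alpha_u=self.alpha_u, alpha_g1=self.alpha_g1,
            alpha_g2=self.alpha_g2, epsilon=self.epsilon,
            pyramid_levels=self.pyramid_levels,
            inner_iters=self.inner_iters, sweeps=self.sweeps,
            sweep_tol=self.sweep_tol)

    def segmentation_params(self) -> SegmentationParams:
        return SegmentationParams(
            alpha_s1=self.alpha_s1, alpha_hat=self.alpha_hat,
            beta=self.beta, prior_weight=self.prior_weight,
            combo_weight=self.combo_weight, gamma=self.gamma,
            sigma=self.sigma, seed=self.seed,
            outer_iters=self.seg_outer_iters, dual_iters=self.dual_iters)

    # -- file round-trip ------------------------------------------------------

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        if hasattr(source, "read"):
            data = yaml.safe_load(source.read())
        else:
            try:
                with open(source) as fh:
                    data = yaml.safe_load(fh.read())
            except (OSError, ValueError):
                data = yaml.safe_load(source)
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def with_overrides(self, pairs) -> "RunConfig":
        """Apply ``key=value`` strings (YAML-typed) on top of this config."""
        data = asdict(self)
        for pair in pairs:
            key, _, value = pair.partition("=")
            if key not in data:
                raise ValueError(f"unknown config key: {key}")
            data[key] = yaml.safe_load(value)
        return RunConfig(**data)
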