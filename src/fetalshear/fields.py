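"""Volumetric flow-field container shared by the solvers and post-processing."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class FlowField:
    """Velocity / vorticity samples at 3D points (mm, mm/s, 1/s).

    ``weights`` are quadrature volumes (mm^3) for volume integrals;
    ``wall_mask`` flags samples lying on the wall; ``meta`` keeps the
    structured-grid shape and provenance so post-processing can reshape.
    """

    points: np.ndarray     # (M,3)
    velocity: np.ndarray   # (M,3)
    vorticity: np.ndarray  # (M,3)
    weights: np.ndarray | None = None
    wall_mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        m = len(self.points)
        if self.velocity.shape != (m, 3) or self.vorticity.shape != (m, 3):
            raise ValueError("velocity/vorticity must match points")

    def speed(self) -> np.ndarray:
        return np.linalg.norm(self.velocity, axis=1)

    def vorticity_magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.vorticity, axis=1)
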