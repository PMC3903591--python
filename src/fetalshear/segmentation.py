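"""Lumen segmentation of filtered EFIC-like stacks.

Default method: Otsu's global two-class threshold, followed by
largest-connected-component selection (6-connectivity) and a morphological
closing to heal voxel-scale noise.  The threshold choice is deliberately
parameter-free so segmentations are reproducible; a stack whose histogram has
no separable classes is rejected explicitly rather than returning an empty or
arbitrary mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .imaging import ImageStack

#: 6-connected structuring element
STRUCT_6 = ndimage.generate_binary_structure(3, 1)


class SegmentationError(ValueError):
    """Raised when no lumen/tissue separation exists in the stack."""


@dataclass
class SegmentationMask:
    """Boolean lumen mask aligned to its source stack."""

    voxels: np.ndarray            # (nz, ny, nx) bool
    spacing: np.ndarray           # µm, inherited
    origin: np.ndarray            # mm
    component_labels: np.ndarray  # int labels of connected lumen components
    threshold: float = float("nan")
    provenance: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.voxels.shape

    def spacing_mm(self) -> np.ndarray:
        return np.asarray(self.spacing, float) / 1000.0

    def volume_mm3(self) -> float:
        return float(self.voxels.sum() * np.prod(self.spacing_mm()))

    def to_stack(self) -> ImageStack:
        """Render the mask as a binary-valued ImageStack (for idempotence)."""
        return ImageStack(
            voxels=self.voxels.astype(np.float32), spacing=self.spacing.copy(),
            origin=self.origin.copy(), provenance={"mask_render": True},
        )


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap of two boolean masks."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = a.sum() + b.sum()
    return float(2.0 * np.logical_and(a, b).sum() / denom) if denom else 1.0


def _count_modes(img: np.ndarray, bins: int = 128, smooth_bins: float = 2.0) -> int:
    """Number of modes of the intensity histogram (Gaussian-smoothed)."""
    from scipy.signal import find_peaks

    hist, _ = np.histogram(img.ravel(), bins=bins)
    hist = ndimage.gaussian_filter1d(hist.astype(float), smooth_bins)
    peaks, _ = find_peaks(hist, prominence=0.02 * hist.max())
    # a mode pinned at either end of the range has no flanking minimum; count it
    if hist[0] > hist[1]:
        peaks = np.append(peaks, 0)
    if hist[-1] > hist[-2]:
        peaks = np.append(peaks, bins - 1)
    return len(peaks)


def segment_lumen(
    stack: ImageStack,
    method: str = "otsu",
    closing_radius: int = 1,
    keep: str = "largest",
) -> SegmentationMask:
    """Two-class segmentation of the lumen from a (filtered) stack.

    ``keep``: 'largest' retains only the largest 6-connected component (the
    great-artery lumen is a single component); 'all' keeps every component.
    Raises SegmentationError on single-mode (non-separable) histograms.
    """
    img = np.asarray(stack.voxels, dtype=np.float64)
    lo, hi = float(img.min()), float(img.max())
    if hi - lo < 1e-12 * max(abs(hi), 1.0):
        raise SegmentationError("constant stack: no separable intensity classes")
    if method != "otsu":
        raise ValueError(f"unknown segmentation method {method!r}")
    if _count_modes(img) < 2:
        raise SegmentationError(
            "intensity histogram is single-mode: no separable lumen/tissue classes"
        )
    thr = float(threshold_otsu(img))
    fg = img > thr
    if fg.sum() == 0 or fg.all():
        raise SegmentationError("threshold produced an empty/full mask")

    if closing_radius > 0:
        fg = ndimage.binary_closing(fg, structure=STRUCT_6, iterations=closing_radius)
    labels, n = ndimage.label(fg, structure=STRUCT_6)
    if n == 0:
        raise SegmentationError("no connected lumen component found")
    if keep == "largest":
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        main = int(np.argmax(sizes)) + 1
        fg = labels == main
        labels = np.where(fg, 1, 0)
    prov = dict(stack.provenance)
    prov["segmentation"] = {"method": method, "threshold": thr, "keep": keep}
    return SegmentationMask(
        voxels=fg, spacing=stack.spacing.copy(), origin=stack.origin.copy(),
        component_labels=labels, threshold=thr, provenance=prov,
    )
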