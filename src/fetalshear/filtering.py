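"""Edge-preserving speckle filtering of image stacks (Perona-Malik diffusion).

Anisotropic diffusion smooths speckle inside homogeneous regions while
preserving the tissue/lumen boundary: the diffusive flux between neighboring
voxels is attenuated where the local gradient is large.  Classic Perona-Malik
on the 6-neighborhood with the exponential conductance

    g(d) = exp(-(d / kappa)^2)

explicit updates I += step * sum_neighbors g(dI) dI, and zero-flux borders.
With step <= 1/6 the scheme satisfies a discrete maximum principle (no new
extrema) and conserves total intensity exactly up to floating-point roundoff.
"""

from __future__ import annotations

import numpy as np

from .imaging import ImageStack

STABILITY_LIMIT = 1.0 / 6.0


def _diffuse_once(img: np.ndarray, kappa: float, step: float) -> np.ndarray:
    out = img.copy()
    for axis in range(3):
        d = np.diff(img, axis=axis)                 # forward differences
        g = np.exp(-((d / kappa) ** 2))
        flux = g * d
        # zero-flux borders: pad flux with zeros at both ends of the axis
        pad = [(0, 0)] * 3
        pad[axis] = (1, 1)
        fpad = np.pad(flux, pad)
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[axis] = slice(0, img.shape[axis])
        sl_hi[axis] = slice(1, img.shape[axis] + 1)
        out += step * (fpad[tuple(sl_hi)] - fpad[tuple(sl_lo)])
    return out


def speckle_filter(
    stack: ImageStack,
    iterations: int = 12,
    conductance: float | None = None,
    step: float = STABILITY_LIMIT,
) -> ImageStack:
    """Perona-Malik anisotropic diffusion of an image stack.

    ``conductance`` (kappa) is the gradient scale separating "noise" (diffused)
    from "edge" (preserved); the default is 60% of the stack's recorded
    tissue/lumen contrast, falling back to half the intensity range.  Returns a
    new stack; ``iterations=0`` returns an identical copy.
    """
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    if not 0.0 < step <= STABILITY_LIMIT:
        raise ValueError(f"step must be in (0, {STABILITY_LIMIT:.4f}] for stability")
    img = np.asarray(stack.voxels, dtype=np.float64)
    if not np.all(np.isfinite(img)):
        raise ValueError("non-finite intensities")
    if conductance is None:
        contrast = stack.provenance.get("contrast")
        if contrast:
            conductance = 0.6 * float(contrast)
        else:
            rng_ = float(img.max() - img.min())
            conductance = 0.5 * rng_ if rng_ > 0 else 1.0
    if conductance <= 0:
        raise ValueError("conductance must be positive")

    for _ in range(iterations):
        img = _diffuse_once(img, conductance, step)

    prov = dict(stack.provenance)
    prov["filter"] = {"iterations": iterations, "conductance": conductance, "step": step}
    return ImageStack(
        voxels=img.astype(np.float32), spacing=stack.spacing.copy(),
        origin=stack.origin.copy(), provenance=prov, mask=stack.mask,
    )
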