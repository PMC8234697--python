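"""Drusen-shadow compensation of the en face flow slab.

Drusen and drusenoid PEDs attenuate the OCT beam, darkening both the flow
and the structure slab beneath them.  Left uncorrected, these shadows are
misread as flow deficits.  The compensation used here is the standard
invert-blur-multiply scheme: the structure slab is inverted (so shadowed
areas become bright), smoothed with a Gaussian, and multiplied pixelwise
into the flow slab, boosting the flow signal exactly where the structural
signal says the beam was attenuated.  The product is min-max rescaled to
[0, 1], the analog of accumulating the product at full precision and then
autoscaling on conversion to a display bit depth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image_io import EnFaceImage

__all__ = ["CompensationParams", "invert", "gaussian_blur", "compensate"]


@dataclass(frozen=True)
class CompensationParams:
    """Parameters of the invert-blur-multiply compensation.

    blur_sigma_px
        Standard deviation (pixels) of the Gaussian applied to the
        inverted structure slab.  Default 2.0 px: enough to suppress
        speckle in the structural signal without washing out the extent
        of individual drusen shadows.
    """

    blur_sigma_px: float = 2.0

    def __post_init__(self) -> None:
        if self.blur_sigma_px < 0:
            raise ValueError(f"blur_sigma_px must be >= 0, got {self.blur_sigma_px}")


def invert(image: EnFaceImage) -> EnFaceImage:
    """Intensity complement ``v -> 1 - v``; an involution on [0, 1]."""
    return image.with_pixels(1.0 - image.pixels)


def gaussian_blur(image: EnFaceImage, sigma_px: float) -> EnFaceImage:
    """2-D Gaussian smoothing with reflective (edge-duplicating) boundaries.

    ``sigma_px == 0`` returns the input unchanged.  The output is clipped
    to [0, 1] to absorb floating-point undershoot.
    """
    if sigma_px < 0:
        raise ValueError(f"sigma_px must be >= 0, got {sigma_px}")
    if sigma_px == 0:
        return image.with_pixels(image.pixels.copy())
    blurred = ndimage.gaussian_filter(image.pixels, sigma=sigma_px, mode="reflect")
    return image.with_pixels(np.clip(blurred, 0.0, 1.0))


def compensate(
    flow: EnFaceImage,
    structure: EnFaceImage,
    params: CompensationParams = CompensationParams(),
) -> EnFaceImage:
    """Shadow-compensate a flow slab with its co-registered structure slab.

    Returns the min-max rescaled pixelwise product
    ``flow * blur(1 - structure)``.  A constant product (possible only in
    degenerate scenes) rescales to all zeros.  Geometry and flow metadata
    are preserved.
    """
    if flow.pixels.shape != structure.pixels.shape:
        raise ValueError(
            "flow and structure dimensions differ: "
            f"{flow.pixels.shape} vs {structure.pixels.shape}"
        )
    if flow.pixel_pitch_um != structure.pixel_pitch_um:
        raise ValueError(
            "flow and structure pixel pitch differ: "
            f"{flow.pixel_pitch_um} vs {structure.pixel_pitch_um}"
        )
    if flow.modality != "flow":
        raise ValueError(f"first argument must be the flow slab, got {flow.modality!r}")
    if structure.modality != "structure":
        raise ValueError(
            f"second argument must be the structure slab, got {structure.modality!r}"
        )
    multiplier = gaussian_blur(invert(structure), params.blur_sigma_px)
    product = flow.pixels * multiplier.pixels
    lo = product.min()
    span = product.max() - lo
    if span == 0.0:
        rescaled = np.zeros_like(product)
    else:
        rescaled = (product - lo) / span
    return flow.with_pixels(rescaled)
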