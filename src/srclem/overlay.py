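"""LM-SEM overlay merging.

The fluorescence channels are binarized with a local threshold on a
circular neighbourhood of radius 5 px (plain local mean for actin,
Phansalkar for the sparser vinculin and zyxin signals), the foreground is
set to intensity 90 (out of 255), blurred with a Gaussian of sigma 10 px,
pushed through a colour lookup table (cyan / green / magenta), and blended
additively onto the registered grayscale SEM image.

Local statistics use windows clipped at the image border; the blur uses
reflective padding.
"""
from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
from scipy import ndimage

__all__ = [
    "OverlayRecipe",
    "local_threshold_mean",
    "local_threshold_phansalkar",
    "prepare_layer",
    "composite",
    "LUT_RGB",
]

#: which RGB components each lookup table feeds
LUT_RGB: dict[str, tuple[int, ...]] = {
    "cyan": (1, 2),
    "green": (1,),
    "magenta": (0, 2),
}


@dataclasses.dataclass
class OverlayRecipe:
    """Parameters of the figure-style merge."""

    threshold_method: dict = dataclasses.field(
        default_factory=lambda: {"actin": "mean", "vinculin": "phansalkar",
                                 "zyxin": "phansalkar"})
    threshold_radius: int = 5
    mask_value: float = 90.0
    blur_radius: float = 10.0
    lut: dict = dataclasses.field(
        default_factory=lambda: {"actin": "cyan", "vinculin": "green",
                                 "zyxin": "magenta"})

    def __post_init__(self) -> None:
        if self.threshold_radius < 1:
            raise ValueError("threshold_radius must be >= 1")
        if not (0 < self.mask_value <= 255):
            raise ValueError("mask_value must lie in (0, 255]")
        for m in self.threshold_method.values():
            if m not in ("mean", "phansalkar"):
                raise ValueError(f"unknown threshold method {m!r}")
        luts = list(self.lut.values())
        if len(set(luts)) != len(luts):
            raise ValueError("lookup tables must be assigned bijectively")
        for c in luts:
            if c not in LUT_RGB:
                raise ValueError(f"unknown lookup table {c!r}")


# ---------------------------------------------------------------------------
# local statistics on a circular window, clipped at the border
# ---------------------------------------------------------------------------

def _disk(radius: int) -> np.ndarray:
    r = int(radius)
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    return (yy * yy + xx * xx) <= r * r


def _local_mean_std(image: np.ndarray, radius: int) -> tuple[np.ndarray, np.ndarray]:
    foot = _disk(radius).astype(float)
    counts = ndimage.correlate(np.ones_like(image), foot, mode="constant")
    sums = ndimage.correlate(image, foot, mode="constant")
    sqsums = ndimage.correlate(image * image, foot, mode="constant")
    mean = sums / counts
    var = np.clip(sqsums / counts - mean * mean, 0.0, None)
    return mean, np.sqrt(var)


def local_threshold_mean(image: np.ndarray, radius: int = 5) -> np.ndarray:
    """Foreground where a pixel exceeds the mean of its circular window.

    The window is clipped to the image at borders.  A constant image is all
    background; because the comparison is equivariant under positive affine
    intensity rescaling, the mask is invariant to brightness/contrast.
    Exact ties count as background: the comparison carries a 1e-9 relative
    guard band so that floating-point summation order cannot flip it.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    img = np.asarray(image, dtype=float)
    mean, _ = _local_mean_std(img, int(radius))
    tol = 1e-9 * max(1.0, float(np.abs(img).max()))
    return img - mean > tol


def local_threshold_phansalkar(
    image: np.ndarray,
    radius: int = 5,
    k: float = 0.25,
    r: float = 0.5,
    p: float = 2.0,
    q: float = 10.0,
) -> np.ndarray:
    """Phansalkar local threshold for low-contrast, sparse foreground.

    The image is min-max rescaled to [0, 1]; a pixel is foreground iff its
    value exceeds ``m * (1 + p*exp(-q*m) + k*((s/r) - 1))`` with ``m``/``s``
    the local mean and standard deviation over the circular window.  The
    constants default to the canonical values (k=0.25, r=0.5, p=2, q=10).
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    if r == 0:
        raise ValueError("normalization constant r must be nonzero")
    img = np.asarray(image, dtype=float)
    lo, hi = float(img.min()), float(img.max())
    if hi == lo:
        return np.zeros(img.shape, dtype=bool)
    norm = (img - lo) / (hi - lo)
    m, s = _local_mean_std(norm, int(radius))
    threshold = m * (1.0 + p * np.exp(-q * m) + k * ((s / r) - 1.0))
    return norm > threshold


# ---------------------------------------------------------------------------
# layer preparation and compositing
# ---------------------------------------------------------------------------

def prepare_layer(mask: np.ndarray, recipe: OverlayRecipe | None = None) -> np.ndarray:
    """Turn a binary mask into a soft fluorescence layer.

    Foreground becomes ``mask_value`` (default 90 out of 255), background 0,
    then a Gaussian blur of sigma ``blur_radius`` px with reflective edges.
    The result never exceeds ``mask_value``.
    """
    recipe = recipe or OverlayRecipe()
    layer = np.asarray(mask, dtype=bool).astype(float) * recipe.mask_value
    return ndimage.gaussian_filter(layer, recipe.blur_radius, mode="reflect")


def composite(
    sem_image: np.ndarray,
    layers: Mapping[str, np.ndarray],
    max_value: float = 1.0,
) -> np.ndarray:
    """Additive RGB blend of colour layers over the grayscale SEM.

    ``layers`` maps a LUT name (cyan/green/magenta) to a layer image on the
    same grid as ``sem_image``; all inputs share the intensity scale
    ``[0, max_value]``.  The SEM contributes equally to R, G and B; each
    layer adds to its LUT's components; the result is clipped to
    ``max_value``.
    """
    sem = np.asarray(sem_image, dtype=float)
    rgb = np.repeat(sem[..., None], 3, axis=-1)
    for name, layer in layers.items():
        layer = np.asarray(layer, dtype=float)
        if layer.shape != sem.shape:
            raise ValueError(
                f"layer {name!r} shape {layer.shape} does not match the SEM "
                f"grid {sem.shape}")
        if name not in LUT_RGB:
            raise ValueError(f"unknown lookup table {name!r}")
        for comp in LUT_RGB[name]:
            rgb[..., comp] += layer
    return np.clip(rgb, 0.0, max_value)
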