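"""Per-pixel ORR and 100 um-disk regional averaging.

The optical redox ratio is ORR = I_FAD / (I_NAD(P)H + I_FAD) per pixel. The
regional analysis replaces each pixel by the average of a signal over the
disk of radius 100 um centred on it — the generally accepted oxygen
diffusion limit — which also absorbs small registration errors between the
autofluorescence and IHC modalities.

The disk kernel is a pillbox with exact fractional coverage at the rim: each
weight is the analytic area of intersection between the pixel square and the
disk. Regional averaging is mask-normalised: both the masked signal and the
mask itself are convolved with the summation kernel and divided, so
masked-out pixels and image borders contribute neither to the numerator nor
the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .calibration import SectionImage
from .registration import RegisteredStack

__all__ = [
    "ORRMap",
    "DiskKernel",
    "RegionalStack",
    "compute_orr",
    "make_disk_kernel",
    "regional_average",
]


@dataclass
class ORRMap:
    pixels: np.ndarray  # [0, 1] where mask is true
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.pixels.shape != self.mask.shape:
            raise ValueError("pixels and mask must share one shape")


def compute_orr(nadh: SectionImage, fad: SectionImage) -> ORRMap:
    """Per-pixel FAD / (NAD(P)H + FAD); zero-denominator pixels are masked out."""
    if nadh.shape != fad.shape:
        raise ValueError("NAD(P)H and FAD images must share one shape")
    if np.any(nadh.pixels[nadh.mask] < 0) or np.any(fad.pixels[fad.mask] < 0):
        raise ValueError("negative intensities are not physical")
    denom = nadh.pixels + fad.pixels
    mask = nadh.mask & fad.mask & (denom > 0)
    orr = np.zeros(denom.shape)
    np.divide(fad.pixels, denom, out=orr, where=mask)
    return ORRMap(orr, mask)


def _circle_quadrant_area(x: float, y: float, r: float) -> float:
    """Area of {u <= x, v <= y, u^2 + v^2 <= r^2} for a disk at the origin."""
    x = min(max(x, -r), r)
    y = min(max(y, -r), r)
    if x == -r or y == -r:
        return 0.0

    def F(u: float) -> float:
        # antiderivative of sqrt(r^2 - u^2)
        return 0.5 * (u * np.sqrt(max(r * r - u * u, 0.0)) + r * r * np.arcsin(u / r))

    def below(t: float) -> float:
        # area of the disk with one coordinate <= t
        return np.pi * r * r - (r * r * np.arccos(t / r) - t * np.sqrt(max(r * r - t * t, 0.0)))

    if x == r and y == r:
        return np.pi * r * r
    if x == r:
        return below(y)
    if y == r:
        return below(x)
    c = np.sqrt(max(r * r - y * y, 0.0))
    if y >= 0:
        # upper bound of v is min(y, sqrt(r^2-u^2)); lower bound -sqrt(r^2-u^2)
        part = 0.0
        x1 = min(x, -c)
        if x1 > -r:
            part += F(x1) - F(-r)
        if x > -c:
            part += y * (min(x, c) + c)
        if x > c:
            part += F(x) - F(c)
        return part + (F(x) - F(-r))
    # y < 0: slab between -sqrt(r^2-u^2) and y, only where |u| <= c
    if x <= -c:
        return 0.0
    xm = min(x, c)
    return y * (xm + c) + (F(xm) - F(-c))


def _pixel_coverage(radius_px: float) -> np.ndarray:
    """Fractional disk coverage of each unit pixel square on the kernel grid."""
    r = radius_px
    k = int(np.ceil(r + 0.5))
    offs = np.arange(-k, k + 1, dtype=float)
    n = offs.size
    cov = np.zeros((n, n))
    for i, oy in enumerate(offs):
        for j, ox in enumerate(offs):
            # quick classification by corner distances
            corners = np.hypot(
                np.array([ox - 0.5, ox - 0.5, ox + 0.5, ox + 0.5]),
                np.array([oy - 0.5, oy + 0.5, oy - 0.5, oy + 0.5]),
            )
            if corners.max() <= r:
                cov[i, j] = 1.0
                continue
            if np.hypot(max(abs(ox) - 0.5, 0.0), max(abs(oy) - 0.5, 0.0)) >= r:
                continue
            x0, x1 = ox - 0.5, ox + 0.5
            y0, y1 = oy - 0.5, oy + 0.5
            cov[i, j] = (
                _circle_quadrant_area(x1, y1, r)
                - _circle_quadrant_area(x0, y1, r)
                - _circle_quadrant_area(x1, y0, r)
                + _circle_quadrant_area(x0, y0, r)
            )
    return cov


@dataclass
class DiskKernel:
    """Pillbox kernel with analytic fractional rim coverage.

    ``normalization='averaging'`` sums to 1; ``'summation'`` is the averaging
    kernel scaled by the disk area pi*r^2 (in pixel^2), i.e. the raw coverage
    map, so convolving a mask with it counts the (fractionally weighted)
    in-mask pixels per disk.
    """

    radius_px: float
    weights: np.ndarray
    normalization: str
    radius_um: float | None = None

    def to_mode(self, mode: str) -> "DiskKernel":
        if mode == self.normalization:
            return self
        area = np.pi * self.radius_px**2
        if mode == "summation":
            return DiskKernel(self.radius_px, self.weights * area, "summation", self.radius_um)
        if mode == "averaging":
            return DiskKernel(self.radius_px, self.weights / area, "averaging", self.radius_um)
        raise ValueError(f"unknown normalization {mode!r}")


def make_disk_kernel(
    radius_um: float, pixel_size: float, mode: str = "summation"
) -> DiskKernel:
    """Build the disk kernel for a physical radius.

    100 um at the native 1.140625 um/pixel sampling (512 px over 584 um)
    gives a 87.67 px radius. Radii below half a pixel (a disk that no longer
    covers its centre pixel) are rejected.
    """
    if radius_um <= 0 or pixel_size <= 0:
        raise ValueError("radius_um and pixel_size must be positive")
    if mode not in ("averaging", "summation"):
        raise ValueError(f"unknown normalization {mode!r}")
    r = radius_um / pixel_size
    if r < 0.5:
        raise ValueError(f"disk radius {r:.3f} px is below half a pixel")
    cov = _pixel_coverage(r)
    if mode == "summation":
        return DiskKernel(r, cov, "summation", radius_um)
    return DiskKernel(r, cov / cov.sum(), "averaging", radius_um)


@dataclass
class RegionalStack:
    """Disk-averaged layers: mean ORR and positive-pixel fractions.

    Layers are defined (finite) only where ``region_size`` — the weighted
    count of in-mask pixels under the disk — is positive.
    """

    orr_mean: np.ndarray
    pimo_frac: np.ndarray
    hif_frac: np.ndarray
    region_size: np.ndarray
    radius_um: float
    mask: np.ndarray  # pixels with a non-empty region

    @property
    def defined(self) -> np.ndarray:
        return self.mask


def regional_average(
    stack: RegisteredStack, kernel: DiskKernel, radius_um: float | None = None
) -> RegionalStack:
    """Mask-normalised disk averages of the ORR, pimo+ and HIF-1a+ layers.

    Each layer is zeroed outside the stack mask, convolved with the
    summation kernel, and divided element-wise by the convolved mask (the
    region-size map), yielding the regional mean ORR and regional positive
    fractions. FFT convolution is used; it matches a direct weighted-loop
    evaluation to ~1e-12 relative.
    """
    ksum = kernel.to_mode("summation")
    kh, kw = ksum.weights.shape
    h, w = stack.mask.shape
    if kh > h or kw > w:
        raise ValueError("kernel is larger than the image")
    mask_f = stack.mask.astype(float)
    region_size = fftconvolve(mask_f, ksum.weights, mode="same")
    # FFT roundoff can leave tiny negatives where the true value is 0
    region_size[region_size < 1e-9] = 0.0
    defined = region_size > 0

    def avg(layer: np.ndarray, clip01: bool) -> np.ndarray:
        num = fftconvolve(np.asarray(layer, dtype=float) * mask_f, ksum.weights, mode="same")
        out = np.full(layer.shape, np.nan)
        np.divide(num, region_size, out=out, where=defined)
        if clip01:
            np.clip(out, 0.0, 1.0, out=out)
        return out

    if radius_um is None:
        radius_um = ksum.radius_um if ksum.radius_um is not None else ksum.radius_px
    return RegionalStack(
        orr_mean=avg(stack.orr, clip01=True),
        pimo_frac=avg(stack.pimo, clip01=True),
        hif_frac=avg(stack.hif, clip01=True),
        region_size=region_size,
        radius_um=radius_um,
        mask=defined,
    )
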