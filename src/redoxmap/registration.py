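"""Two-point landmark registration of IHC maps onto autofluorescence maps.

Serial imaging sessions (autofluorescence first, IHC after staining) leave
the two modalities related by an approximate similarity transform. Two
corresponding landmark pairs define a line segment in each frame; the unique
similarity mapping the moving segment onto the fixed one is scale = ratio of
segment lengths, rotation = difference of segment angles, and a translation
aligning the first endpoints. The transform is applied as scale, then
rotation, then translation, and the translation is rounded to whole pixels
to respect the discrete grid (binary maps are resampled nearest-neighbour,
so binarization survives the warp).

Point coordinates are (x, y) = (col, row); the rotation pivot is the first
fixed landmark (any pivot yields the same line mapping; fixing one makes the
stored parameters reproducible).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import SimilarityTransform as _SkSimilarity
from skimage.transform import warp as _sk_warp

__all__ = [
    "SimilarityTransform",
    "RegisteredStack",
    "estimate_similarity",
    "apply_transform",
    "build_stack",
]


@dataclass(frozen=True)
class SimilarityTransform:
    """scale -> rotate (about ``center``) -> translate, in (x, y) pixels."""

    scale: float
    rotation: float  # radians
    translation: tuple[float, float]  # (dx, dy) pixels
    center: tuple[float, float] = (0.0, 0.0)
    rounded: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite(self.scale) or self.scale <= 0:
            raise ValueError("scale must be finite and positive")
        if not np.isfinite(self.rotation):
            raise ValueError("rotation must be finite")
        if not all(np.isfinite(t) for t in self.translation):
            raise ValueError("translation must be finite")

    @property
    def matrix(self) -> np.ndarray:
        """3x3 homogeneous matrix acting on (x, y, 1) column vectors."""
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        A = self.scale * np.array([[c, -s], [s, c]])
        cx, cy = self.center
        dx, dy = self.translation
        offset = np.array([cx, cy]) - A @ np.array([cx, cy]) + np.array([dx, dy])
        M = np.eye(3)
        M[:2, :2] = A
        M[:2, 2] = offset
        return M

    def __call__(self, points: np.ndarray) -> np.ndarray:
        """Map (N, 2) or (2,) point arrays from the moving to the fixed frame."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = pts @ self.matrix[:2, :2].T + self.matrix[:2, 2]
        return out[0] if np.ndim(points) == 1 else out

    def inverse(self) -> "SimilarityTransform":
        """Exact inverse (its translation is not re-rounded)."""
        Minv = np.linalg.inv(self.matrix)
        angle = float(np.arctan2(Minv[1, 0], Minv[0, 0]))
        scale = float(np.hypot(Minv[0, 0], Minv[1, 0]))
        return SimilarityTransform(
            scale=scale,
            rotation=angle,
            translation=(float(Minv[0, 2]), float(Minv[1, 2])),
            center=(0.0, 0.0),
            rounded=False,
        )


def estimate_similarity(
    pair_fixed: np.ndarray,
    pair_moving: np.ndarray,
    round_translation: bool = True,
) -> SimilarityTransform:
    """Closed-form two-point similarity mapping the moving line onto the fixed one.

    ``pair_fixed`` and ``pair_moving`` are (2, 2) arrays of (x, y) points;
    row i of one corresponds to row i of the other. With
    ``round_translation`` (the default) the translation is rounded to whole
    pixels after the scale and rotation are applied, matching the discrete
    pixel grid.
    """
    f = np.asarray(pair_fixed, dtype=float).reshape(2, 2)
    m = np.asarray(pair_moving, dtype=float).reshape(2, 2)
    vf, vm = f[1] - f[0], m[1] - m[0]
    lf, lm = np.hypot(*vf), np.hypot(*vm)
    if lf == 0 or lm == 0:
        raise ValueError("coincident landmark points define a zero-length line")
    scale = lf / lm
    rotation = float(np.arctan2(vf[1], vf[0]) - np.arctan2(vm[1], vm[0]))
    rotation = float((rotation + np.pi) % (2 * np.pi) - np.pi)  # wrap to (-pi, pi]
    center = (float(f[0, 0]), float(f[0, 1]))
    # translation aligning first endpoints after scale+rotation about `center`
    base = SimilarityTransform(scale, rotation, (0.0, 0.0), center=center)
    t = f[0] - base(m[0])
    if round_translation:
        t = np.round(t)
    return SimilarityTransform(
        scale=scale,
        rotation=rotation,
        translation=(float(t[0]), float(t[1])),
        center=center,
        rounded=round_translation,
    )


def apply_transform(
    raster: np.ndarray,
    transform: SimilarityTransform,
    output_shape: tuple[int, int] | None = None,
) -> np.ndarray:
    """Resample ``raster`` from the moving frame into the fixed frame.

    Boolean rasters use nearest-neighbour interpolation (values stay exactly
    binary); float rasters use bilinear. Regions mapping outside the input
    frame are filled with 0 / False.
    """
    raster = np.asarray(raster)
    if output_shape is None:
        output_shape = raster.shape
    # skimage's warp(inverse_map=...) wants output (x, y) -> input (x, y)
    inv = _SkSimilarity(matrix=np.linalg.inv(transform.matrix))
    if raster.dtype == bool:
        out = _sk_warp(
            raster.astype(float), inv, order=0, output_shape=output_shape,
            cval=0.0, preserve_range=True,
        )
        return out > 0.5
    return _sk_warp(
        raster.astype(float), inv, order=1, output_shape=output_shape,
        cval=0.0, preserve_range=True,
    )


@dataclass
class RegisteredStack:
    """Co-registered per-pixel layers sharing one intersected validity mask."""

    orr: np.ndarray  # [0, 1] raster
    pimo: np.ndarray  # binary raster
    hif: np.ndarray  # binary raster
    mask: np.ndarray  # binary raster, intersection of the source masks
    pixel_size: float = 1.0  # um / pixel

    def __post_init__(self) -> None:
        self.orr = np.asarray(self.orr, dtype=float)
        self.pimo = np.asarray(self.pimo, dtype=bool)
        self.hif = np.asarray(self.hif, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        shapes = {self.orr.shape, self.pimo.shape, self.hif.shape, self.mask.shape}
        if len(shapes) != 1:
            raise ValueError("all layers and the mask must share one shape")

    @property
    def is_empty(self) -> bool:
        return not bool(self.mask.any())


def build_stack(
    orr_map: np.ndarray,
    pimo_map: np.ndarray,
    hif_map: np.ndarray,
    masks: list[np.ndarray],
    pixel_size: float = 1.0,
) -> RegisteredStack:
    """Stack registered layers; the stack mask is the AND of all supplied masks."""
    if not masks:
        raise ValueError("at least one mask is required")
    mask = np.ones(np.asarray(orr_map).shape, dtype=bool)
    for m in masks:
        m = np.asarray(m, dtype=bool)
        if m.shape != mask.shape:
            raise ValueError("mask shape mismatch")
        mask &= m
    return RegisteredStack(orr_map, pimo_map, hif_map, mask, pixel_size=pixel_size)
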