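"""Binarized IHC signal maps and validity masks.

Pimonidazole (hypoxia) staining is read from the red emission channel at
755 nm excitation; HIF-1a staining from the *product* of the red and green
channels at 950 nm excitation, which suppresses background staining that
appears in only one of the two channels. Thresholds are supplied, not
auto-estimated: in practice they are set by averaging manually chosen
cutoffs over a subset of images, a step that cannot be reproduced in code.

Comparisons at the cutoff are strictly greater-than, so raising a threshold
never adds positive pixels and binarization is idempotent.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely

from .calibration import SectionImage

__all__ = [
    "IHCThresholds",
    "BinarySignalMap",
    "PolygonMask",
    "extract_pimo",
    "extract_hif",
    "build_mask",
    "polygons_from_json",
    "polygons_to_json",
]


@dataclass(frozen=True)
class IHCThresholds:
    """Cutoffs in fluorescein-equivalent units.

    ``lp`` applies to the 755 nm red channel (uM); ``lh`` to the red*green
    product at 950 nm (uM^2); ``low_signal`` is the autofluorescence floor
    below which pixels are considered background.
    """

    lp: float
    lh: float
    low_signal: float = 0.0

    def __post_init__(self) -> None:
        if self.lp < 0 or self.lh < 0 or self.low_signal < 0:
            raise ValueError("thresholds must be non-negative")


@dataclass
class BinarySignalMap:
    pixels: np.ndarray  # boolean raster
    label: str  # "pimo+" or "HIF-1a+"
    source_channels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)

    @property
    def positive_fraction(self) -> float:
        return float(self.pixels.mean())

    def positive_fraction_in(self, mask: np.ndarray) -> float:
        mask = np.asarray(mask, dtype=bool)
        n = int(mask.sum())
        if n == 0:
            raise ValueError("empty mask")
        return float(self.pixels[mask].sum()) / n


@dataclass
class PolygonMask:
    """A simple polygon in pixel coordinates, (x, y) = (col, row).

    ``sense='exclude'`` removes the covered pixels from the validity mask;
    ``sense='include'`` restricts the mask to the union of include polygons.
    """

    vertices: list[tuple[float, float]]
    sense: str = "exclude"

    def __post_init__(self) -> None:
        if self.sense not in ("exclude", "include"):
            raise ValueError("sense must be 'exclude' or 'include'")
        self.vertices = [(float(x), float(y)) for x, y in self.vertices]
        if len(self.vertices) < 3:
            raise ValueError("polygon needs at least 3 vertices")
        ring = shapely.LinearRing(self.vertices)
        if not ring.is_simple:
            raise ValueError("polygon must be simple (non-self-intersecting)")

    def as_shapely(self) -> shapely.Polygon:
        return shapely.Polygon(self.vertices)


def _check_normalized(image: SectionImage, name: str) -> None:
    if image.units != "uM":
        raise ValueError(f"{name} must be fluorescein-normalized (units='uM')")


def extract_pimo(red_755: SectionImage, thresholds: IHCThresholds) -> BinarySignalMap:
    """Binarize hypoxia staining: red 755 nm intensity strictly above ``lp``.

    Masked-out pixels are never positive.
    """
    if red_755.emission_channel != "red" or round(red_755.excitation_nm) != 755:
        raise ValueError(
            "pimo extraction expects the red channel of 755 nm excitation, got "
            f"{red_755.emission_channel!r} at {red_755.excitation_nm} nm"
        )
    _check_normalized(red_755, "red_755")
    positive = (red_755.pixels > thresholds.lp) & red_755.mask
    return BinarySignalMap(positive, "pimo+", ("red@755",))


def extract_hif(
    red_950: SectionImage, green_950: SectionImage, thresholds: IHCThresholds
) -> BinarySignalMap:
    """Binarize HIF-1a staining: red*green product at 950 nm strictly above ``lh``."""
    for img, ch in ((red_950, "red"), (green_950, "green")):
        if img.emission_channel != ch or round(img.excitation_nm) != 950:
            raise ValueError(
                f"HIF extraction expects the {ch} channel of 950 nm excitation, "
                f"got {img.emission_channel!r} at {img.excitation_nm} nm"
            )
        _check_normalized(img, f"{ch}_950")
    if red_950.shape != green_950.shape:
        raise ValueError("red and green 950 nm channels must share one shape")
    product = red_950.pixels * green_950.pixels
    positive = (product > thresholds.lh) & red_950.mask & green_950.mask
    return BinarySignalMap(positive, "HIF-1a+", ("red@950", "green@950"))


def _rasterize(poly: PolygonMask, shape: tuple[int, int]) -> np.ndarray:
    """Pixels whose centre lies strictly inside the polygon (even-odd rule).

    Centres exactly on the boundary count as outside. Only the polygon's
    bounding box is tested; parts outside the image are clipped with a
    warning.
    """
    geom = poly.as_shapely()
    x0, y0, x1, y1 = geom.bounds
    h, w = shape
    if x0 < -0.5 or y0 < -0.5 or x1 > w - 0.5 or y1 > h - 0.5:
        warnings.warn("polygon extends outside image bounds; clipping", stacklevel=3)
    c0 = max(int(np.floor(x0)), 0)
    c1 = min(int(np.ceil(x1)) + 1, w)
    r0 = max(int(np.floor(y0)), 0)
    r1 = min(int(np.ceil(y1)) + 1, h)
    out = np.zeros(shape, dtype=bool)
    if c1 <= c0 or r1 <= r0:
        return out
    cols, rows = np.meshgrid(np.arange(c0, c1), np.arange(r0, r1))
    inside = shapely.contains_xy(geom, cols.ravel().astype(float), rows.ravel().astype(float))
    out[r0:r1, c0:c1] = inside.reshape(rows.shape)
    return out


def build_mask(
    image: SectionImage,
    polygons: list[PolygonMask] | None,
    thresholds: IHCThresholds,
) -> np.ndarray:
    """Validity mask: adequate signal AND outside every exclude polygon.

    A pixel is kept when its intensity is >= ``low_signal``, it is inside the
    image's own validity mask, it is not covered by any exclude polygon, and
    (if include polygons are given) it is covered by at least one of them.
    """
    mask = (image.pixels >= thresholds.low_signal) & image.mask
    if polygons:
        for poly in polygons:
            covered = _rasterize(poly, image.shape)
            if poly.sense == "exclude":
                mask &= ~covered
        includes = [p for p in polygons if p.sense == "include"]
        if includes:
            union = np.zeros(image.shape, dtype=bool)
            for poly in includes:
                union |= _rasterize(poly, image.shape)
            mask &= union
    return mask


def polygons_from_json(path) -> list[PolygonMask]:
    """Load ``{"polygons": [{"sense": ..., "vertices": [[x, y], ...]}]}``."""
    with open(path) as fh:
        data = json.load(fh)
    return [
        PolygonMask(vertices=[tuple(v) for v in p["vertices"]], sense=p.get("sense", "exclude"))
        for p in data["polygons"]
    ]


def polygons_to_json(polygons: list[PolygonMask], path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "polygons": [
                    {"sense": p.sense, "vertices": [list(v) for v in p.vertices]}
                    for p in polygons
                ]
            },
            fh,
            indent=2,
        )
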