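"""Uni-, bi- and trivariate histograms with low/high cutoffs.

Histograms are normalised to the percentage of pixels counted, so
distributions from tumors of different sizes are directly comparable. A
trivariate histogram bins two variables (e.g. the regional percentage of
pimo+ and HIF-1a+ pixels) and colours each bin by the mean of a third (the
ORR), which preserves the spatial co-localization of the three quantities
without plotting three dimensions of coordinates.

Cutoffs split a variable into "low" (strictly below) and "high" (strictly
above) classes; values exactly at the cutoff belong to neither and are
reported. The median is the default for heavily zero-skewed regional
fractions; Otsu's method (maximum between-class variance on a 256-bin
histogram) and the mean are available for the ORR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_otsu

from .regional import RegionalStack

__all__ = [
    "HistogramND",
    "TrivariateHistogram",
    "CutoffSpec",
    "histogram",
    "trivariate",
    "cutoff",
    "select_regions",
    "conditional_distribution",
]


@dataclass
class HistogramND:
    """Binned counts as raw totals and as percent of counted pixels."""

    edges: list[np.ndarray]
    counts: np.ndarray  # raw counts
    counts_percent: np.ndarray  # sums to 100 over counted pixels
    n_total: int  # pixels counted
    n_excluded: int = 0  # in-mask pixels outside the edge range

    @property
    def dims(self) -> int:
        return len(self.edges)

    @property
    def centers(self) -> list[np.ndarray]:
        return [(e[:-1] + e[1:]) / 2 for e in self.edges]


@dataclass
class TrivariateHistogram:
    """2-D histogram of (x, y) with the per-bin mean of a third variable z."""

    base: HistogramND
    z_mean: np.ndarray  # NaN where the bin is empty
    z_name: str = "z"

    @property
    def counts_percent(self) -> np.ndarray:
        return self.base.counts_percent


@dataclass(frozen=True)
class CutoffSpec:
    method: str  # median | otsu | mean
    value: float
    scope: str = "pooled"
    n: int = 0


def _masked_values(values: np.ndarray, mask: np.ndarray | None) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != values.shape:
            raise ValueError("mask shape must match values")
        values = values[mask]
    else:
        values = values.ravel()
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("no in-mask values to histogram")
    return values


def histogram(
    values: np.ndarray,
    edges: np.ndarray,
    mask: np.ndarray | None = None,
    clip_out_of_range: bool = False,
) -> HistogramND:
    """1-D histogram as percent of counted pixels.

    Out-of-range values are excluded and reported in ``n_excluded`` by
    default; with ``clip_out_of_range`` they are counted in the end bins.
    """
    vals = _masked_values(values, mask)
    edges = np.asarray(edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("edges must be strictly increasing with >= 2 values")
    if clip_out_of_range:
        # nudge into the closed range; np.histogram's last bin is closed anyway
        vals = np.clip(vals, edges[0], edges[-1])
    counts, _ = np.histogram(vals, bins=edges)
    n_counted = int(counts.sum())
    if n_counted == 0:
        raise ValueError("all values fall outside the histogram range")
    return HistogramND(
        edges=[edges],
        counts=counts,
        counts_percent=100.0 * counts / n_counted,
        n_total=n_counted,
        n_excluded=int(vals.size - n_counted),
    )


def trivariate(
    x: np.ndarray,
    y: np.ndarray,
    z: np.ndarray,
    edges_x: np.ndarray,
    edges_y: np.ndarray,
    mask: np.ndarray | None = None,
    z_name: str = "z",
) -> TrivariateHistogram:
    """Bivariate histogram of (x, y) with the mean of ``z`` within each bin.

    The count-weighted average of ``z_mean`` over occupied bins equals the
    global mean of ``z`` over the counted pixels (conservation).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if not (x.shape == y.shape == z.shape):
        raise ValueError("x, y, z must be aligned rasters")
    keep = np.isfinite(x) & np.isfinite(y) & np.isfinite(z)
    if mask is not None:
        keep &= np.asarray(mask, dtype=bool)
    xv, yv, zv = x[keep], y[keep], z[keep]
    if xv.size == 0:
        raise ValueError("no in-mask values")
    edges_x = np.asarray(edges_x, dtype=float)
    edges_y = np.asarray(edges_y, dtype=float)
    counts, _, _ = np.histogram2d(xv, yv, bins=[edges_x, edges_y])
    if counts.sum() == 0:
        raise ValueError("all bins empty: values fall outside the edges")
    z_sum, _, _ = np.histogram2d(xv, yv, bins=[edges_x, edges_y], weights=zv)
    occupied = counts > 0
    z_mean = np.full(counts.shape, np.nan)
    np.divide(z_sum, counts, out=z_mean, where=occupied)
    n_counted = int(counts.sum())
    base = HistogramND(
        edges=[edges_x, edges_y],
        counts=counts,
        counts_percent=100.0 * counts / n_counted,
        n_total=n_counted,
        n_excluded=int(xv.size - n_counted),
    )
    return TrivariateHistogram(base=base, z_mean=z_mean, z_name=z_name)


def cutoff(values: np.ndarray, method: str = "median", mask: np.ndarray | None = None,
           scope: str = "pooled") -> CutoffSpec:
    """Low/high threshold of pooled values by median, mean, or Otsu's method."""
    vals = _masked_values(values, mask)
    if method == "median":
        value = float(np.median(vals))
    elif method == "mean":
        value = float(np.mean(vals))
    elif method == "otsu":
        if np.unique(vals).size < 2:
            raise ValueError("Otsu's method needs at least 2 distinct values")
        value = float(threshold_otsu(vals, nbins=256))
    else:
        raise ValueError(f"unknown cutoff method {method!r}")
    return CutoffSpec(method=method, value=value, scope=scope, n=int(vals.size))


_LAYERS = {"pimo": "pimo_frac", "hif": "hif_frac", "orr": "orr_mean"}


def select_regions(
    stack: RegionalStack,
    criteria: dict[str, str],
    cutoffs: dict[str, CutoffSpec | float],
) -> np.ndarray:
    """Boolean map of pixels whose regional values satisfy every criterion.

    ``criteria`` maps layer names ('pimo', 'hif', 'orr') to 'low' or 'high';
    low means strictly below the layer's cutoff, high strictly above.
    """
    selection = stack.mask.copy()
    for name, side in criteria.items():
        if name not in _LAYERS:
            raise KeyError(f"unknown layer {name!r} (expected one of {sorted(_LAYERS)})")
        if side not in ("low", "high"):
            raise ValueError("criteria values must be 'low' or 'high'")
        cut = cutoffs[name]
        value = cut.value if isinstance(cut, CutoffSpec) else float(cut)
        layer = getattr(stack, _LAYERS[name])
        with np.errstate(invalid="ignore"):
            selection &= (layer < value) if side == "low" else (layer > value)
    return selection


def conditional_distribution(
    stack: RegionalStack,
    criteria: dict[str, str],
    cutoffs: dict[str, CutoffSpec | float],
    target: str = "orr",
    edges: np.ndarray | None = None,
) -> HistogramND:
    """Histogram of a regional layer restricted to criteria-satisfying pixels.

    E.g. the distribution of regional mean ORR within low-pimo/high-HIF
    regions. Raises with a selection summary when nothing qualifies.
    """
    selection = select_regions(stack, criteria, cutoffs)
    if not selection.any():
        detail = ", ".join(f"{k}={v}" for k, v in criteria.items())
        raise ValueError(
            f"empty selection for criteria ({detail}); "
            f"{int(stack.mask.sum())} defined pixels considered"
        )
    if target not in _LAYERS:
        raise KeyError(f"unknown target {target!r}")
    layer = getattr(stack, _LAYERS[target])
    if edges is None:
        edges = np.linspace(0.0, 1.0, 51)  # 50 bins for the unit-interval ORR
    return histogram(layer, edges, mask=selection)
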