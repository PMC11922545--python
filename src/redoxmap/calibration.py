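"""Fluorescein-based intensity calibration for two-photon images.

Raw two-photon intensities depend on the laser power delivered to the sample
and on the PMT gain setting, both of which are adjusted per image to maximise
SNR. To make intensities comparable across images and days, solutions of
known fluorescein concentration are imaged over a range of power and gain
settings; a separable power-law response

    I = concentration * power**a * gain**b * c_day

is fitted in log space, and every image is divided by ``power**a * gain**b *
c_day`` so that its pixels are expressed in fluorescein-equivalent uM.

Raster convention used throughout the package: 2-D arrays are indexed
``(row, col)``, 0-based, with pixel centres at integer coordinates. Point
coordinates are ``(x, y) = (col, row)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SectionImage",
    "CalibrationRecord",
    "CalibrationModel",
    "fit_calibration",
    "normalize_image",
    "records_from_csv",
    "records_to_csv",
]


@dataclass
class SectionImage:
    """A single-channel intensity raster with its acquisition metadata.

    ``pixels`` holds either raw detector counts (``units='counts'``) or
    calibrated fluorescein-equivalent uM (``units='uM'``). ``mask`` marks
    valid pixels; invalid pixels are carried but ignored by every analysis
    step downstream.
    """

    pixels: np.ndarray
    pixel_size: float  # um / pixel
    excitation_nm: float
    emission_channel: str  # one of {"blue", "green", "red"}
    power: float = 1.0  # mW at sample
    gain: float = 1.0  # PMT gain, arbitrary units
    day: str = "day0"
    mask: np.ndarray | None = None
    units: str = "counts"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D raster")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.emission_channel not in ("blue", "green", "red"):
            raise ValueError(f"unknown emission channel {self.emission_channel!r}")
        if self.mask is None:
            self.mask = np.ones(self.pixels.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.pixels.shape:
                raise ValueError("mask shape must match pixels")
        if np.any(self.pixels[self.mask] < 0):
            raise ValueError("masked-in pixels must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class CalibrationRecord:
    """One fluorescein measurement: settings and the mean image intensity."""

    day: str
    power: float  # mW
    gain: float  # arbitrary units
    concentration: float  # uM fluorescein
    mean_intensity: float  # detector counts

    def __post_init__(self) -> None:
        for name in ("power", "gain", "concentration", "mean_intensity"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class CalibrationModel:
    """Fitted power-law response of the detection chain.

    ``scale_per_day`` maps each acquisition day to its multiplicative factor
    (fluorescein-equivalent uM per normalised count), absorbing day-to-day
    laser drift.
    """

    power_exponent: float
    gain_exponent: float
    scale_per_day: dict[str, float] = field(default_factory=dict)
    residual_std: float = 0.0
    r_squared: float = 1.0
    n_records: int = 0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.power_exponent) and np.isfinite(self.gain_exponent)):
            raise ValueError("exponents must be finite")
        if any(c <= 0 for c in self.scale_per_day.values()):
            raise ValueError("per-day scale factors must be positive")

    def denominator(self, power: float, gain: float, day: str) -> float:
        if day not in self.scale_per_day:
            raise KeyError(
                f"day {day!r} absent from calibration model "
                f"(known: {sorted(self.scale_per_day)})"
            )
        return (
            power**self.power_exponent
            * gain**self.gain_exponent
            * self.scale_per_day[day]
        )


def fit_calibration(records: Sequence[CalibrationRecord]) -> CalibrationModel:
    """Least-squares fit of the separable power-law response in log space.

    Solves ``log I - log conc = a log P + b log G + log c_day`` for the
    exponents ``(a, b)`` and one scale factor per acquisition day. Requires
    at least three distinct power values and three distinct gain values so
    that both exponents are identifiable.
    """
    records = list(records)
    if len(records) < 3:
        raise ValueError("need at least 3 calibration records")
    powers = {r.power for r in records}
    gains = {r.gain for r in records}
    if len(powers) < 2:
        raise ValueError(
            "rank-deficient calibration design: all records share one laser "
            "power; vary the power to identify the power exponent"
        )
    if len(gains) < 2:
        raise ValueError(
            "rank-deficient calibration design: all records share one PMT "
            "gain; vary the gain to identify the gain exponent"
        )
    if len(powers) < 3 or len(gains) < 3:
        raise ValueError("need >=3 distinct power and >=3 distinct gain values")

    days = sorted({r.day for r in records})
    n, k = len(records), 2 + len(days)
    X = np.zeros((n, k))
    y = np.empty(n)
    for i, r in enumerate(records):
        X[i, 0] = np.log(r.power)
        X[i, 1] = np.log(r.gain)
        X[i, 2 + days.index(r.day)] = 1.0
        y[i] = np.log(r.mean_intensity) - np.log(r.concentration)
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < k:
        raise ValueError("rank-deficient calibration design")
    resid = y - X @ coef
    dof = max(n - k, 1)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return CalibrationModel(
        power_exponent=float(coef[0]),
        gain_exponent=float(coef[1]),
        scale_per_day={d: float(np.exp(coef[2 + i])) for i, d in enumerate(days)},
        residual_std=float(np.sqrt(np.sum(resid**2) / dof)),
        r_squared=r2,
        n_records=n,
    )


def normalize_image(image: SectionImage, model: CalibrationModel) -> SectionImage:
    """Convert raw counts to fluorescein-equivalent uM.

    Divides by ``power**a * gain**b * c_day`` using the image's recorded
    settings; the validity mask is preserved. Raises ``KeyError`` if the
    image's acquisition day is not in the model.
    """
    denom = model.denominator(image.power, image.gain, image.day)
    return replace(image, pixels=image.pixels / denom, units="uM")


_CSV_COLUMNS = ["day", "power_mW", "gain", "conc_uM", "mean_intensity"]


def records_from_csv(path) -> list[CalibrationRecord]:
    """Read calibration records (columns: day, power_mW, gain, conc_uM, mean_intensity)."""
    df = pd.read_csv(path)
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"calibration CSV missing columns: {sorted(missing)}")
    return [
        CalibrationRecord(
            day=str(row.day),
            power=float(row.power_mW),
            gain=float(row.gain),
            concentration=float(row.conc_uM),
            mean_intensity=float(row.mean_intensity),
        )
        for row in df.itertuples()
    ]


def records_to_csv(records: Sequence[CalibrationRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "day": r.day,
                "power_mW": r.power,
                "gain": r.gain,
                "conc_uM": r.concentration,
                "mean_intensity": r.mean_intensity,
            }
            for r in records
        ],
        columns=_CSV_COLUMNS,
    ).to_csv(path, index=False)
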