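"""Ground-truthed synthetic tumor sections.

Generates everything the analysis pipeline consumes — two-channel
autofluorescence intensities, three IHC channels, TCSPC decay cubes, a known
misregistration and its landmark pairs, and fluorescein calibration records
— with the statistical structure the analysis assumes, so every downstream
stage is testable without image downloads.

Spatial structure comes from thresholded Gaussian random fields: white noise
smoothed with a Gaussian kernel of the configured correlation length, the
simplest generator with controllable spatial co-localization at the
oxygen-diffusion scale. Subpopulations (e.g. pimo-/HIF+ foci with elevated
ORR) are carved from independent fields at exact area fractions. The
elevated/depressed redox zone of each subpopulation extends one
oxygen-diffusion length (``orr_halo_um``) beyond its stained focus, so the
metabolic signature survives disk-regional averaging at the same scale.

Intensity noise is Poisson on expected photon counts; decays are Poisson
per time bin around a two-exponential periodic model. Everything is
deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as _dc_replace

import numpy as np
from scipy.ndimage import distance_transform_edt, gaussian_filter

from .calibration import CalibrationRecord, SectionImage
from .ihc import IHCThresholds
from .phasor import DecayCube, DEFAULT_BIN_WIDTH_NS, DEFAULT_REP_RATE_MHZ
from .registration import SimilarityTransform, apply_transform

__all__ = [
    "SubpopSpec",
    "GeneratorConfig",
    "SectionGroundTruth",
    "SyntheticSection",
    "generate_section",
    "generate_flim_cube",
    "misregister",
    "generate_calibration_records",
    "default_thresholds",
]


@dataclass(frozen=True)
class SubpopSpec:
    """One implanted subpopulation: stain labels, redox state, area share."""

    name: str
    pimo: bool
    hif: bool
    mean_orr: float
    mean_alpha2: float
    area_fraction: float  # of in-tissue pixels


def _default_subpops() -> list[SubpopSpec]:
    # Area shares follow the printed group fractions of the study system:
    # ~2.4% pimo+ and ~6.2% HIF+ overall; the hif-only focus carries the
    # elevated redox state attributed to ROS-stabilized HIF-1a.
    return [
        SubpopSpec("hypoxic", pimo=True, hif=True, mean_orr=0.30, mean_alpha2=0.40,
                   area_fraction=0.024),
        SubpopSpec("ros", pimo=False, hif=True, mean_orr=0.70, mean_alpha2=0.50,
                   area_fraction=0.038),
    ]


def _default_acquisition() -> dict[str, tuple[float, float]]:
    return {
        "nadh": (20.0, 2.0),
        "fad": (25.0, 2.2),
        "ihc_red_755": (10.0, 1.8),
        "ihc_red_950": (12.0, 1.6),
        "ihc_green_950": (12.0, 1.5),
    }


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic section.

    Defaults mirror the native acquisition geometry: 512 x 512 px over
    584 um (1.140625 um/px). ``correlation_length`` is the standard
    deviation (um) of the Gaussian smoothing kernel behind every random
    field — a free parameter of the generator, set to 200 um so that
    stained foci span a few hundred um, the inter-vessel scale over which
    hypoxic territories form. ``photon_budget`` is the expected photon count
    per pixel at unit normalized intensity.
    """

    shape: tuple[int, int] = (512, 512)
    pixel_size: float = 1.140625  # um / px (584 um / 512 px)
    correlation_length: float = 200.0  # um
    subpop_spec: list[SubpopSpec] = field(default_factory=_default_subpops)
    photon_budget: float = 5000.0
    seed: int = 0
    noise: bool = True
    # bulk tissue state
    background_orr: float = 0.40
    background_alpha2: float = 0.45
    tau_pair: tuple[float, float] = (0.4, 2.5)  # ns (free, bound)
    orr_halo_um: float = 100.0  # redox zone margin beyond each stained focus
    subpop_separation_um: float = 100.0  # minimum gap between distinct foci
    texture_sigma: float = 0.02  # within-region ORR / alpha2 jitter (zero mean)
    texture_corr_um: float = 10.0  # cellular-scale correlation of the jitter
    # intensities (fluorescein-equivalent uM scale)
    total_intensity: float = 1.0
    off_tissue_intensity: float = 0.02
    stain_level: float = 5.0
    stain_background: float = 0.05
    # calibration ground truth
    power_exponent: float = 2.0
    gain_exponent: float = 4.0
    day: str = "day0"
    day_scale: float = 1.0
    acquisition: dict[str, tuple[float, float]] = field(default_factory=_default_acquisition)
    # misregistration of the IHC modality (moving -> fixed)
    misreg_scale: float = 1.03
    misreg_rotation_deg: float = 5.0
    misreg_translation: tuple[float, float] = (18.0, -11.0)

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.photon_budget <= 0:
            raise ValueError("photon_budget must be positive")
        total = sum(s.area_fraction for s in self.subpop_spec)
        if total > 1.0 + 1e-9:
            raise ValueError("subpopulation area fractions must sum to <= 1")
        for s in self.subpop_spec:
            if not (0 <= s.mean_orr <= 1 and 0 <= s.mean_alpha2 <= 1):
                raise ValueError("subpopulation ORR and alpha2 must lie in [0, 1]")

    def transform_true(self) -> SimilarityTransform:
        h, w = self.shape
        return SimilarityTransform(
            scale=self.misreg_scale,
            rotation=float(np.deg2rad(self.misreg_rotation_deg)),
            translation=self.misreg_translation,
            center=(w / 2.0, h / 2.0),
        )


@dataclass
class SectionGroundTruth:
    """True per-pixel state of a generated section, all on the fixed frame."""

    orr_field: np.ndarray
    pimo_field: np.ndarray  # binary
    hif_field: np.ndarray  # binary
    alpha2_field: np.ndarray
    tau_pair: tuple[float, float]
    transform_true: SimilarityTransform
    landmarks: np.ndarray  # (2, 2) fixed-frame (x, y) points
    mask_true: np.ndarray  # tissue pixels
    region_label: np.ndarray  # 0 = bulk tissue, i = subpop_spec[i-1]

    def __post_init__(self) -> None:
        shapes = {
            self.orr_field.shape, self.pimo_field.shape, self.hif_field.shape,
            self.alpha2_field.shape, self.mask_true.shape, self.region_label.shape,
        }
        if len(shapes) != 1:
            raise ValueError("ground-truth fields must share one shape")
        if np.any((self.orr_field < 0) | (self.orr_field > 1)):
            raise ValueError("orr_field must lie in [0, 1]")
        if np.any((self.alpha2_field < 0) | (self.alpha2_field > 1)):
            raise ValueError("alpha2_field must lie in [0, 1]")
        if np.allclose(self.landmarks[0], self.landmarks[1]):
            raise ValueError("landmarks must be non-coincident")


@dataclass
class SyntheticSection:
    """Generated images (fixed frame, raw counts) plus the ground truth."""

    nadh: SectionImage
    fad: SectionImage
    ihc_red_755: SectionImage
    ihc_red_950: SectionImage
    ihc_green_950: SectionImage
    truth: SectionGroundTruth
    config: GeneratorConfig

    @property
    def ihc_images(self) -> tuple[SectionImage, SectionImage, SectionImage]:
        return (self.ihc_red_755, self.ihc_red_950, self.ihc_green_950)


def _grf(shape: tuple[int, int], sigma_px: float, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean unit-variance Gaussian random field (periodic FFT smoothing)."""
    noise = rng.standard_normal(shape)
    f = gaussian_filter(noise, sigma=sigma_px, mode="wrap")
    return (f - f.mean()) / f.std()


def _carve_labels(
    shape: tuple[int, int],
    tissue: np.ndarray,
    subpops: list[SubpopSpec],
    sigma_px: float,
    sep_px: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Assign subpopulation labels at exact in-tissue area fractions.

    Each subpopulation gets its own random field; its pixels are the
    top-valued unassigned tissue pixels, so fractions are exact and regions
    are spatially coherent blobs. Later subpopulations keep at least
    ``sep_px`` of clearance from earlier ones — hypoxic and well-oxygenated
    foci arise from opposite ends of the vascular supply and do not abut
    within a diffusion length.
    """
    label = np.zeros(shape, dtype=int)
    n_tissue = int(tissue.sum())
    unassigned = tissue.copy()
    for i, sub in enumerate(subpops, start=1):
        u = _grf(shape, sigma_px, rng)
        k = int(round(sub.area_fraction * n_tissue))
        if k == 0:
            continue
        vals = np.where(unassigned, u, -np.inf).ravel()
        idx = np.argpartition(vals, -k)[-k:]
        sel = np.zeros(vals.size, dtype=bool)
        sel[idx] = True
        sel = sel.reshape(shape)
        label[sel] = i
        unassigned &= ~sel
        if sep_px > 0 and i < len(subpops):
            unassigned &= distance_transform_edt(~sel) > sep_px
    return label


def _zone_values(
    label: np.ndarray,
    subpops: list[SubpopSpec],
    background: float,
    halo_px: float,
    attr: str,
) -> np.ndarray:
    """Per-pixel value with each subpopulation's zone dilated by ``halo_px``.

    Where dilated zones overlap, the nearest focus wins.
    """
    out = np.full(label.shape, background)
    best = np.full(label.shape, np.inf)
    for i, sub in enumerate(subpops, start=1):
        region = label == i
        if not region.any():
            continue
        dist = distance_transform_edt(~region)
        zone = (dist <= halo_px) & (dist < best)
        out[zone] = getattr(sub, attr)
        best[zone] = dist[zone]
    return out


def _poisson_intensity(
    norm: np.ndarray, budget: float, noise: bool, rng: np.random.Generator
) -> np.ndarray:
    """Measured normalized intensity after Poisson photon noise."""
    if not noise:
        return norm.copy()
    return rng.poisson(norm * budget).astype(float) / budget


def generate_section(config: GeneratorConfig) -> SyntheticSection:
    """Generate one synthetic tumor section on the fixed (autofluorescence) frame.

    Raw image values are ``normalized_intensity * power**a * gain**b *
    c_day`` with per-channel acquisition settings, so the calibration stage
    has real work to do; noise-free, FAD / (NADH + FAD) equals the true ORR
    field exactly.
    """
    h, w = config.shape
    if min(h, w) < 16:
        raise ValueError("degenerate shape: sides must be >= 16 px")
    ss = np.random.SeedSequence(config.seed)
    rng_fields, rng_noise = [np.random.default_rng(c) for c in ss.spawn(2)]
    sigma_px = config.correlation_length / config.pixel_size

    yy, xx = np.mgrid[0:h, 0:w]
    tissue = (
        ((xx - (w - 1) / 2) / (0.47 * w)) ** 2 + ((yy - (h - 1) / 2) / (0.47 * h)) ** 2
    ) <= 1.0

    sep_px = config.subpop_separation_um / config.pixel_size
    label = _carve_labels((h, w), tissue, config.subpop_spec, sigma_px, sep_px, rng_fields)
    pimo_field = np.zeros((h, w), dtype=bool)
    hif_field = np.zeros((h, w), dtype=bool)
    for i, sub in enumerate(config.subpop_spec, start=1):
        if sub.pimo:
            pimo_field |= label == i
        if sub.hif:
            hif_field |= label == i

    halo_px = config.orr_halo_um / config.pixel_size
    orr = _zone_values(label, config.subpop_spec, config.background_orr, halo_px, "mean_orr")
    alpha2 = _zone_values(label, config.subpop_spec, config.background_alpha2, 0.0, "mean_alpha2")
    tex_px = config.texture_corr_um / config.pixel_size
    if config.texture_sigma > 0:
        orr = orr + config.texture_sigma * _grf((h, w), tex_px, rng_fields)
        alpha2 = alpha2 + config.texture_sigma * _grf((h, w), tex_px, rng_fields)
    orr = np.clip(orr, 0.0, 1.0)
    alpha2 = np.clip(alpha2, 0.0, 1.0)

    # total autofluorescence with mild multiplicative texture; dim off tissue
    i_tot = config.total_intensity * (1.0 + 0.1 * _grf((h, w), tex_px, rng_fields))
    i_tot = np.clip(i_tot, 0.1 * config.total_intensity, None)
    i_tot = np.where(tissue, i_tot, config.off_tissue_intensity)

    norm_images = {
        "nadh": i_tot * (1.0 - orr),
        "fad": i_tot * orr,
        "ihc_red_755": config.stain_background + config.stain_level * pimo_field,
        "ihc_red_950": config.stain_background + config.stain_level * hif_field,
        "ihc_green_950": config.stain_background + config.stain_level * hif_field,
    }
    meta = {
        "nadh": (755.0, "blue"),
        "fad": (855.0, "green"),
        "ihc_red_755": (755.0, "red"),
        "ihc_red_950": (950.0, "red"),
        "ihc_green_950": (950.0, "green"),
    }
    images: dict[str, SectionImage] = {}
    for name, norm in norm_images.items():
        power, gain = config.acquisition[name]
        measured = _poisson_intensity(norm, config.photon_budget, config.noise, rng_noise)
        raw = measured * power**config.power_exponent * gain**config.gain_exponent * config.day_scale
        exc, ch = meta[name]
        images[name] = SectionImage(
            pixels=raw, pixel_size=config.pixel_size, excitation_nm=exc,
            emission_channel=ch, power=power, gain=gain, day=config.day,
        )

    landmarks = np.array(
        [[0.30 * w, 0.30 * h], [0.70 * w, 0.65 * h]], dtype=float
    )
    truth = SectionGroundTruth(
        orr_field=orr,
        pimo_field=pimo_field,
        hif_field=hif_field,
        alpha2_field=alpha2,
        tau_pair=config.tau_pair,
        transform_true=config.transform_true(),
        landmarks=landmarks,
        mask_true=tissue,
        region_label=label,
    )
    return SyntheticSection(
        nadh=images["nadh"],
        fad=images["fad"],
        ihc_red_755=images["ihc_red_755"],
        ihc_red_950=images["ihc_red_950"],
        ihc_green_950=images["ihc_green_950"],
        truth=truth,
        config=config,
    )


def misregister(
    images: list[SectionImage] | list[np.ndarray],
    transform_true: SimilarityTransform,
    landmarks_fixed: np.ndarray,
):
    """Move images into a misregistered frame and return exact landmark pairs.

    ``transform_true`` maps the moving frame onto the fixed frame, so each
    returned image is the input resampled through its inverse, and the
    returned ``(pair_fixed, pair_moving)`` satisfy
    ``transform_true(pair_moving) == pair_fixed`` to float precision.
    """
    inv = transform_true.inverse()
    moved = []
    for img in images:
        if isinstance(img, SectionImage):
            pixels = apply_transform(img.pixels, inv)
            mask = apply_transform(img.mask, inv)
            moved.append(_dc_replace(img, pixels=pixels, mask=mask))
        else:
            moved.append(apply_transform(np.asarray(img), inv))
    pair_fixed = np.asarray(landmarks_fixed, dtype=float).reshape(2, 2)
    pair_moving = inv(pair_fixed)
    return moved, (pair_fixed, pair_moving)


def generate_flim_cube(
    alpha2_field: np.ndarray,
    tau_pair: tuple[float, float],
    config: GeneratorConfig,
    n_bins: int = 256,
    bin_width_ns: float = DEFAULT_BIN_WIDTH_NS,
    rep_rate_mhz: float = DEFAULT_REP_RATE_MHZ,
) -> DecayCube:
    """Two-exponential TCSPC cube with Poisson noise.

    Each species decays as a periodic exponential (repetition period
    1e3/rep_rate ns) sampled at bin centres and normalised to unit sum over
    the acquisition window, so the expected total photons per pixel equal
    ``config.photon_budget`` and ``alpha2`` is an intensity fraction. Note
    the default window (256 x 0.0390625 ns = 10 ns) is shorter than the
    12.5 ns period, as in real acquisitions.
    """
    alpha2_field = np.asarray(alpha2_field, dtype=float)
    if np.any((alpha2_field < 0) | (alpha2_field > 1)):
        raise ValueError("alpha2_field must lie in [0, 1]")
    tau1, tau2 = tau_pair
    if not (0 < tau1 < tau2):
        raise ValueError("need 0 < tau1 < tau2")
    period = 1e3 / rep_rate_mhz
    if tau2 >= period:
        raise ValueError("lifetimes must be below the repetition period")
    if n_bins * bin_width_ns > period * (1 + 1e-9):
        raise ValueError("acquisition window exceeds the repetition period")

    t = (np.arange(n_bins) + 0.5) * bin_width_ns

    def profile(tau: float) -> np.ndarray:
        f = np.exp(-t / tau) / (1.0 - np.exp(-period / tau))
        return f / f.sum()

    f1, f2 = profile(tau1), profile(tau2)
    expected = config.photon_budget * (
        (1.0 - alpha2_field)[..., None] * f1 + alpha2_field[..., None] * f2
    )
    if config.noise:
        rng = np.random.default_rng([config.seed, 0xF11])
        counts = rng.poisson(expected)
    else:
        counts = expected
    return DecayCube(counts=counts, bin_width_ns=bin_width_ns, rep_rate_mhz=rep_rate_mhz)


def generate_calibration_records(
    config: GeneratorConfig,
    powers: tuple[float, ...] = (5.0, 10.0, 20.0, 40.0),
    gains: tuple[float, ...] = (1.0, 1.5, 2.0, 3.0),
    concentrations: tuple[float, ...] = (1.0, 5.0),
    days: tuple[str, ...] | None = None,
    noise_sigma: float = 0.0,
) -> list[CalibrationRecord]:
    """Fluorescein measurements drawn from the generator's true response.

    ``mean_intensity = conc * P**a * G**b * c_day`` with optional log-normal
    measurement noise of the given sigma.
    """
    if days is None:
        days = (config.day,)
    rng = np.random.default_rng([config.seed, 0xCA1])
    records = []
    for day in days:
        c_day = config.day_scale
        for p in powers:
            for g in gains:
                for conc in concentrations:
                    mean = conc * p**config.power_exponent * g**config.gain_exponent * c_day
                    if noise_sigma > 0:
                        mean *= float(np.exp(noise_sigma * rng.standard_normal()))
                    records.append(
                        CalibrationRecord(
                            day=day, power=p, gain=g,
                            concentration=conc, mean_intensity=mean,
                        )
                    )
    return records


def default_thresholds(config: GeneratorConfig) -> IHCThresholds:
    """Cutoffs midway between stain background and signal (normalized units)."""
    lp = config.stain_background + 0.5 * config.stain_level
    return IHCThresholds(
        lp=lp,
        lh=lp * lp,
        low_signal=5.0 * config.off_tissue_intensity,
    )
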