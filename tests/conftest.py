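import numpy as np
import pytest

import redoxmap as rm


@pytest.fixture(scope="session")
def small_config() -> rm.GeneratorConfig:
    """A fast, small-field section: 128 px (146 um) with 30 um foci."""
    return rm.GeneratorConfig(
        shape=(128, 128),
        correlation_length=30.0,
        subpop_separation_um=20.0,
        orr_halo_um=20.0,
        seed=0,
        photon_budget=3000.0,
    )


@pytest.fixture(scope="session")
def small_section(small_config) -> rm.SyntheticSection:
    return rm.generate_section(small_config)


@pytest.fixture(scope="session")
def calibration_model(small_config) -> rm.CalibrationModel:
    return rm.fit_calibration(rm.generate_calibration_records(small_config))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def regional_loop_oracle(layer, mask, weights):
    """Literal per-pixel weighted sums over the kernel footprint.

    Independent reference for the FFT-convolution regional average: for each
    pixel, slice the kernel window, accumulate the masked weighted sum and
    the weighted mask count, and divide.
    """
    h, w = layer.shape
    kh, kw = weights.shape
    ry, rx = kh // 2, kw // 2
    num = np.zeros((h, w))
    den = np.zeros((h, w))
    masked = np.where(mask, layer, 0.0)
    mf = mask.astype(float)
    for i in range(h):
        for j in range(w):
            y0, y1 = max(0, i - ry), min(h, i + ry + 1)
            x0, x1 = max(0, j - rx), min(w, j + rx + 1)
            wy0, wx0 = y0 - (i - ry), x0 - (j - rx)
            win = weights[wy0:wy0 + (y1 - y0), wx0:wx0 + (x1 - x0)]
            num[i, j] = np.sum(win * masked[y0:y1, x0:x1])
            den[i, j] = np.sum(win * mf[y0:y1, x0:x1])
    out = np.full((h, w), np.nan)
    np.divide(num, den, out=out, where=den > 0)
    return out
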