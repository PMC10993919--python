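import numpy as np
import pytest

from polorder import CorrectedStack, PolarizationStack, normalize_stack


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def random_stack(rng):
    """Random positive 32x32 raw stack."""
    return PolarizationStack(rng.uniform(1.0, 100.0, size=(4, 32, 32)))


def make_normalized(images):
    """Build a NormalizedStack from raw channel values via the real chain."""
    return normalize_stack(CorrectedStack(np.asarray(images, dtype=float)))


def forward_channels(mu_deg: float, sigma_deg: float) -> np.ndarray:
    """Noiseless four-channel response of a wrapped-normal dipole ensemble.

    Channel k is the ensemble average of cos^2(theta_k - phi) over
    phi ~ wrapped normal(mu, sigma): 0.5 * (1 + exp(-2 sigma^2) cos 2(theta_k - mu)).
    """
    s = np.radians(sigma_deg)
    c2 = np.exp(-2.0 * s * s)
    thetas = np.radians([0.0, 45.0, 90.0, 135.0])
    return 0.5 * (1.0 + c2 * np.cos(2.0 * (thetas - np.radians(mu_deg))))
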