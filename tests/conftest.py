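import numpy as np
import pytest

import myofat as mf


@pytest.fixture(scope="session")
def protocol():
    return mf.AcquisitionProtocol()


@pytest.fixture(scope="session")
def spectrum():
    return mf.make_default_spectrum()


@pytest.fixture(scope="session")
def small_truth():
    """Small two-muscle phantom shared across tests."""
    return mf.generate_phantom(shape=(24, 24, 9), seed=7)


@pytest.fixture(scope="session")
def small_series(small_truth, protocol, spectrum):
    return mf.simulate_signal(small_truth, protocol, spectrum, snr=None, seed=8)


@pytest.fixture(scope="session")
def small_maps(small_series, spectrum):
    return mf.separate(small_series, spectrum)


def random_voxel_signals(rng, protocol, spectrum, n, snr=None,
                         pdff_range=(0.0, 50.0), psi_range=(-100.0, 100.0),
                         r2s_range=(10.0, 100.0)):
    """Forward-simulate n random single-voxel echo trains; returns (signals, truth dict)."""
    te = protocol.echo_times
    c = spectrum.signal_coefficients(te, protocol.field_strength)
    pdff = rng.uniform(*pdff_range, size=n)
    psi = rng.uniform(*psi_range, size=n)
    r2s = rng.uniform(*r2s_range, size=n)
    phi0 = rng.uniform(-np.pi, np.pi, size=n)
    W = 1.0 - pdff / 100.0
    F = pdff / 100.0
    sig = (W[None, :] + F[None, :] * c[:, None]) * np.exp(
        (2j * np.pi * psi[None, :] - r2s[None, :]) * te[:, None]
    ) * np.exp(1j * phi0[None, :])
    if snr is not None:
        sigma = np.abs(sig[0]).mean() / snr
        noise = rng.normal(scale=sigma / np.sqrt(2), size=(2,) + sig.shape)
        sig = sig + noise[0] + 1j * noise[1]
    return sig, {"pdff": pdff, "psi": psi, "r2s": r2s, "phi0": phi0}
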