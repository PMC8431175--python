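import numpy as np
import pytest

import myofat as mf
from myofat.waterfat import _varpro_residual

from conftest import random_voxel_signals


def forward_voxel(protocol, spectrum, W, F, psi, r2s, phi0=0.0, theta=0.0):
    te = protocol.echo_times
    c = spectrum.signal_coefficients(te, protocol.field_strength)
    sig = (W + F * c) * np.exp((2j * np.pi * psi - r2s) * te) * np.exp(1j * phi0)
    if theta:
        sig = sig * np.exp(1j * protocol.eddy_signs * theta)
    return sig


class TestFitVoxel:
    def test_recovers_known_parameters(self, protocol, spectrum):
        sig = forward_voxel(protocol, spectrum, W=0.8, F=0.2, psi=40.0, r2s=30.0, phi0=0.7)
        fit = mf.fit_voxel(sig, protocol, spectrum)
        assert fit.water == pytest.approx(0.8, rel=1e-3)
        assert fit.fat == pytest.approx(0.2, rel=1e-3)
        assert fit.fieldmap_hz == pytest.approx(40.0, rel=1e-3)
        assert fit.r2star == pytest.approx(30.0, rel=1e-3)
        assert fit.converged

    def test_pure_water_zero_pdff(self, protocol, spectrum):
        sig = forward_voxel(protocol, spectrum, W=1.0, F=0.0, psi=0.0, r2s=0.0)
        fit = mf.fit_voxel(sig, protocol, spectrum)
        assert fit.pdff == pytest.approx(0.0, abs=1e-6)

    def test_zero_signal_flagged_not_converged(self, protocol, spectrum):
        fit = mf.fit_voxel(np.zeros(6, dtype=complex), protocol, spectrum)
        assert fit.water == 0.0 and fit.fat == 0.0
        assert not fit.converged

    def test_nan_input_rejected(self, protocol, spectrum):
        sig = np.ones(6, dtype=complex)
        sig[3] = np.nan
        with pytest.raises(ValueError):
            mf.fit_voxel(sig, protocol, spectrum)

    def test_too_few_echoes_rejected(self, spectrum):
        proto3 = mf.AcquisitionProtocol(n_echoes=3)
        with pytest.raises(ValueError):
            mf.fit_voxel(np.ones(3, dtype=complex), proto3, spectrum)

    def test_returned_misfit_not_worse_than_any_grid_candidate(self, protocol, spectrum):
        rng = np.random.default_rng(5)
        sig, _ = random_voxel_signals(rng, protocol, spectrum, n=5, snr=20)
        te = protocol.echo_times
        c = spectrum.signal_coefficients(te, protocol.field_strength)
        psi_grid = np.arange(-200.0, 201.0, 10.0)
        r2s_grid = np.arange(0.0, 301.0, 25.0)
        for v in range(sig.shape[1]):
            fit = mf.fit_voxel(sig[:, v], protocol, spectrum)
            pp, rr = np.meshgrid(psi_grid, r2s_grid, indexing="ij")
            resid, _, _ = _varpro_residual(
                np.repeat(sig[:, v:v + 1], pp.size, axis=1), te, c,
                pp.ravel(), rr.ravel())
            assert fit.residual <= resid.min() + 1e-12

    def test_pdff_monotone_in_true_fat_fraction(self, protocol, spectrum):
        estimates = []
        for f in np.linspace(0.0, 0.6, 7):
            sig = forward_voxel(protocol, spectrum, W=1 - f, F=f, psi=25.0, r2s=40.0)
            estimates.append(mf.fit_voxel(sig, protocol, spectrum).pdff)
        assert np.all(np.diff(estimates) >= -1e-9)

    def test_pdff_invariant_to_global_scale_and_phase(self, protocol, spectrum):
        sig = forward_voxel(protocol, spectrum, W=0.7, F=0.3, psi=-30.0, r2s=60.0)
        ref = mf.fit_voxel(sig, protocol, spectrum).pdff
        for factor in (5.0, 0.1, np.exp(1.3j), 2.0 * np.exp(-0.8j)):
            assert mf.fit_voxel(sig * factor, protocol, spectrum).pdff == pytest.approx(ref, abs=1e-6)


class TestSeparate:
    def test_noiseless_roundtrip_under_tenth_pp(self, small_truth, small_maps):
        union = small_truth.union_mask
        err = np.abs(small_maps.pdff - small_truth.pdff)[union]
        assert err.max() < 0.1

    def test_t2star_matches_truth(self, small_truth, small_maps):
        union = small_truth.union_mask
        t2s_true = 1000.0 / small_truth.r2star
        assert np.all(small_maps.t2star_valid[union])
        err = np.abs(small_maps.t2star - t2s_true)[union]
        assert err.max() < 0.5

    def test_uniform_pure_fat_pdff_100(self, protocol, spectrum):
        shape = (16, 16, 9)
        mask = mf.MuscleMask(np.ones(shape, dtype=bool), protocol.voxel_spacing)
        truth = mf.GroundTruth(
            water=np.zeros(shape), fat=np.ones(shape),
            fieldmap_hz=np.full(shape, 20.0), r2star=np.full(shape, 40.0),
            init_phase=np.zeros(shape), eddy_phase=0.0,
            masks={"fat": mask}, voxel_spacing=protocol.voxel_spacing,
        )
        series = mf.simulate_signal(truth, protocol, spectrum, snr=None)
        maps = mf.separate(series, spectrum)
        assert np.all(maps.pdff > 99.9)

    def test_echo_protocol_mismatch_rejected(self, small_series, protocol):
        with pytest.raises(ValueError):
            mf.EchoSeries(signal=small_series.signal[:4], protocol=protocol)

    def test_fieldmap_recovered(self, small_truth, small_maps):
        union = small_truth.union_mask
        err = np.abs(small_maps.fieldmap - small_truth.fieldmap_hz)[union]
        assert err.max() < 0.5


class TestEddyPhase:
    @pytest.mark.parametrize("theta_true,tol", [(0.0, 0.02), (0.3, 0.01), (-0.2, 0.01)])
    def test_recovers_simulated_theta(self, protocol, spectrum, theta_true, tol):
        truth = mf.generate_phantom(shape=(16, 16, 9), seed=21, eddy_phase=theta_true)
        series = mf.simulate_signal(truth, protocol, spectrum, snr=None)
        theta = mf.estimate_eddy_phase(series, spectrum)
        assert theta == pytest.approx(theta_true, abs=tol)

    def test_estimate_invariant_to_global_initial_phase(self, protocol, spectrum):
        truth = mf.generate_phantom(shape=(16, 16, 9), seed=22, eddy_phase=0.25)
        series = mf.simulate_signal(truth, protocol, spectrum, snr=None)
        shifted = mf.EchoSeries(signal=series.signal * np.exp(0.9j), protocol=protocol)
        t0 = mf.estimate_eddy_phase(series, spectrum)
        t1 = mf.estimate_eddy_phase(shifted, spectrum)
        assert t1 == pytest.approx(t0, abs=1e-3)

    def test_monopolar_returns_zero_with_notice(self, spectrum):
        proto = mf.AcquisitionProtocol(bipolar=False)
        truth = mf.generate_phantom(shape=(16, 16, 9), seed=23, protocol=proto)
        series = mf.simulate_signal(truth, proto, spectrum, snr=None)
        with pytest.warns(UserWarning):
            assert mf.estimate_eddy_phase(series, spectrum) == 0.0

    def test_correction_recovers_pdff_under_eddy(self, protocol, spectrum):
        truth = mf.generate_phantom(shape=(16, 16, 9), seed=24, eddy_phase=0.3)
        series = mf.simulate_signal(truth, protocol, spectrum, snr=None)
        maps_corr = mf.separate(series, spectrum, eddy="estimate")
        union = truth.union_mask
        err_corr = np.abs(maps_corr.pdff - truth.pdff)[union].max()
        resid_corr = maps_corr.residual[union].mean()
        maps_raw = mf.separate(series, spectrum, eddy="off")
        resid_raw = maps_raw.residual[union].mean()
        assert err_corr < 0.1
        assert resid_corr < resid_raw
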