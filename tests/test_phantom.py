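"""Forward model of the digital perfusion phantom."""

import numpy as np
import pytest

from perfsyn.errors import BoundsError, InvalidParameterError
from perfsyn.maps import signal_to_concentration
from perfsyn.phantom import (
    AcquisitionParams,
    AifParams,
    LesionSpec,
    VoxelHemodynamics,
    build_phantom,
    concentration_to_signal,
    gamma_variate_aif,
    residue_function,
    tissue_concentration,
)

TR = 2.22


def times(n=64, dt=TR):
    return np.arange(n) * dt


class TestAif:
    def test_causal_zero_before_onset(self):
        p = AifParams(t0=10.0)
        t = times(40, 1.0)
        curve = gamma_variate_aif(p, t)
        assert np.all(curve[t <= 10.0] == 0)
        assert np.all(curve >= 0)

    def test_peak_location_analytic(self):
        # gamma-variate peaks at t0 + alpha*beta = 10 + 4.5 s
        p = AifParams(alpha=3, beta=1.5, t0=10.0)
        t = np.arange(0, 40, 0.001)
        curve = gamma_variate_aif(p, t)
        assert t[np.argmax(curve)] == pytest.approx(14.5, abs=0.01)
        assert curve.max() == pytest.approx(p.amplitude, rel=1e-6)

    def test_linear_in_amplitude(self):
        t = times()
        a = gamma_variate_aif(AifParams(amplitude=2.0), t)
        b = gamma_variate_aif(AifParams(amplitude=4.0), t)
        assert np.allclose(b, 2 * a)

    @pytest.mark.parametrize("kw", [{"alpha": -1.0}, {"beta": 0.0}, {"t0": -1.0}])
    def test_invalid_parameters(self, kw):
        with pytest.raises(InvalidParameterError):
            AifParams(**kw)


class TestResidue:
    def test_starts_at_one_and_decreases(self):
        for model in ("exponential", "boxcar"):
            r = residue_function(model, 4.0, times())
            assert r[0] == 1.0
            assert np.all(np.diff(r) <= 0)

    def test_boxcar_area(self):
        r = residue_function("boxcar", 4.0, times(60, 1.0))
        assert r.sum() * 1.0 == pytest.approx(4.0)

    def test_exponential_area_fine_grid(self):
        t = np.arange(0, 60, 0.1)
        r = residue_function("exponential", 4.0, t)
        assert np.trapezoid(r, t) == pytest.approx(4.0, rel=0.02)

    def test_exponential_discrete_area_at_clinical_tr(self):
        # the calibrated decay keeps the rectangle-rule area = MTT at TR 2.22 s
        r = residue_function("exponential", 4.0, times(200))
        assert r.sum() * TR == pytest.approx(4.0, rel=1e-6)

    def test_invalid_mtt(self):
        with pytest.raises(InvalidParameterError):
            residue_function("exponential", 0.0, times())


class TestTissueConcentration:
    def test_zero_flow_gives_zero_curve(self):
        v = VoxelHemodynamics(cbf=0.0, mtt=4.0)
        aif = gamma_variate_aif(AifParams(), times())
        assert np.all(tissue_concentration(v, aif, times()) == 0)

    def test_delay_is_whole_frame_shift(self):
        aif = gamma_variate_aif(AifParams(t0=0.0), times(64, 1.0))
        base = tissue_concentration(VoxelHemodynamics(cbf=0.01, mtt=4.0), aif, times(64, 1.0))
        delayed = tissue_concentration(
            VoxelHemodynamics(cbf=0.01, mtt=4.0, delay=5.0), aif, times(64, 1.0)
        )
        assert np.allclose(delayed[5:], base[:-5])
        assert np.all(delayed[:5] == 0)

    def test_matches_direct_double_loop(self):
        t = times(48)
        aif = gamma_variate_aif(AifParams(), t)
        v = VoxelHemodynamics(cbf=0.01, mtt=4.0, delay=2 * TR)
        r = residue_function("exponential", v.mtt, t)
        direct = np.zeros(t.size)
        for i in range(t.size):
            acc = 0.0
            for j in range(i + 1):
                acc += aif[j] * r[i - j]
            direct[i] = v.cbf * acc * TR
        direct = np.concatenate([np.zeros(2), direct[:-2]])
        assert np.allclose(tissue_concentration(v, aif, t), direct, atol=1e-10)


class TestSignalModel:
    def test_zero_concentration_gives_baseline(self):
        acq = AcquisitionParams()
        s = concentration_to_signal(np.zeros(10), acq)
        assert np.allclose(s, acq.s0)

    def test_log_linearity(self):
        acq = AcquisitionParams()
        c = np.linspace(0, 0.3, 20)
        drop1 = np.log(acq.s0 / concentration_to_signal(c, acq))
        drop2 = np.log(acq.s0 / concentration_to_signal(2 * c, acq))
        assert np.allclose(drop2, 2 * drop1)

    def test_round_trip_with_concentration_recovery(self):
        acq = AcquisitionParams(n_frames=40, grid=(1, 2, 2), noise_sd=0.0)
        aif = gamma_variate_aif(AifParams(t0=acq.n_prebolus * acq.tr), acq.times)
        v = VoxelHemodynamics(cbf=0.01, mtt=4.0, delay=TR)
        c = tissue_concentration(v, aif, acq.times)
        sig = np.broadcast_to(concentration_to_signal(c, acq), (1, 2, 2, 40)).copy()
        series = signal_to_concentration(sig, acq)
        assert np.allclose(series.conc[0, 0, 0], c, atol=1e-10)

    def test_invalid_s0(self):
        with pytest.raises(InvalidParameterError):
            concentration_to_signal(np.zeros(4), AcquisitionParams(s0=0.0))


class TestBuildPhantom:
    def test_seeded_determinism(self, noiseless_acq):
        a = build_phantom(seed=5, acq=noiseless_acq)
        b = build_phantom(seed=5, acq=noiseless_acq)
        assert np.array_equal(a.signal, b.signal)
        for k in a.truth:
            assert np.array_equal(a.truth[k], b.truth[k])

    def test_noiseless_voxel_matches_composed_forward_model(self, noiseless_phantom):
        ph = noiseless_phantom
        acq = ph.acquisition
        idx = tuple(np.argwhere(ph.brain_mask & ~ph.lesion_mask)[10])
        v = VoxelHemodynamics(
            cbf=ph.truth["cbf"][idx], mtt=ph.truth["mtt"][idx], delay=ph.truth["delay"][idx]
        )
        expected = concentration_to_signal(
            tissue_concentration(v, ph.aif_curve, acq.times), acq
        )
        assert np.allclose(ph.signal[idx], expected, atol=1e-9)

    def test_prebolus_frames_are_baseline(self, noiseless_phantom):
        ph = noiseless_phantom
        pre = ph.signal[ph.brain_mask][:, : ph.acquisition.n_prebolus]
        assert np.allclose(pre, ph.acquisition.s0)
        assert np.all(ph.signal[~ph.brain_mask] == 0)

    def test_lesion_has_longer_tmax_and_lower_cbf(self, noiseless_phantom):
        ph = noiseless_phantom
        les, bg = ph.lesion_mask, ph.brain_mask & ~ph.lesion_mask
        assert ph.truth["tmax"][les].min() > np.median(ph.truth["tmax"][bg])
        assert np.median(ph.truth["cbf"][les]) < 0.6 * np.median(ph.truth["cbf"][bg])

    def test_area_conservation(self, noiseless_phantom):
        # area under C / area under AIF recovers relative CBV within 2%
        ph = noiseless_phantom
        acq = ph.acquisition
        series = signal_to_concentration(ph.signal, acq)
        aif_area = np.trapezoid(ph.aif_curve, acq.times)
        ratio = np.trapezoid(series.conc[ph.brain_mask], acq.times, axis=-1) / aif_area
        rel = np.abs(ratio - ph.truth["cbv"][ph.brain_mask]) / ph.truth["cbv"][ph.brain_mask]
        assert np.median(rel) < 0.02
        assert rel.max() < 0.02

    def test_delay_shifts_peak_by_whole_frames(self, noiseless_acq):
        t = noiseless_acq.times
        aif = gamma_variate_aif(AifParams(t0=8 * TR), t)
        peaks = []
        for d in (0, 1, 2, 3):
            c = tissue_concentration(
                VoxelHemodynamics(cbf=0.01, mtt=4.0, delay=d * TR), aif, t
            )
            peaks.append(np.argmax(c))
        assert np.all(np.diff(peaks) == 1)

    def test_lesion_outside_grid_raises(self, noiseless_acq):
        with pytest.raises(BoundsError):
            LesionSpec(center=(1.5, 0.5, 0.5))
        with pytest.raises(BoundsError):
            build_phantom(seed=0, acq=noiseless_acq,
                          lesion=LesionSpec(center=(0.5, 0.02, 0.02), radii=(0.01, 0.01, 0.01)))

    def test_central_volume_theorem_in_truth(self, noiseless_phantom):
        ph = noiseless_phantom
        m = ph.brain_mask
        assert np.allclose(ph.truth["cbv"][m], ph.truth["cbf"][m] * ph.truth["mtt"][m])
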