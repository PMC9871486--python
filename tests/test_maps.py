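"""Classical cSVD perfusion-map engine against analytic and phantom oracles."""

import numpy as np
import pytest

from perfsyn.errors import EmptyResultError, SingularInputError
from perfsyn.maps import (
    DeconvolutionConfig,
    compute_all_maps,
    compute_cbf,
    compute_cbv,
    compute_mtt,
    compute_tmax,
    compute_ttp,
    csvd_deconvolve,
    signal_to_concentration,
)
from perfsyn.phantom import AcquisitionParams, AifParams, build_phantom, gamma_variate_aif

TR = 2.22
CFG0 = DeconvolutionConfig(svd_threshold_fraction=0.0)


class TestSignalToConcentration:
    def test_baseline_signal_maps_to_zero(self):
        acq = AcquisitionParams(n_frames=20, grid=(1, 2, 2), noise_sd=0)
        sig = np.full((1, 2, 2, 20), acq.s0)
        series = signal_to_concentration(sig, acq)
        assert np.allclose(series.conc, 0.0)
        assert series.mask.all()

    def test_halving_signal_adds_log2_over_kte(self):
        acq = AcquisitionParams(n_frames=20, grid=(1, 1, 1), noise_sd=0)
        sig = np.full((1, 1, 1, 20), acq.s0)
        sig[0, 0, 0, 12] = acq.s0 / 2
        series = signal_to_concentration(sig, acq)
        assert series.conc[0, 0, 0, 12] == pytest.approx(
            np.log(2) / (acq.k_conversion * acq.te)
        )

    def test_zero_baseline_voxel_masked_out(self):
        acq = AcquisitionParams(n_frames=20, grid=(1, 1, 2), noise_sd=0)
        sig = np.full((1, 1, 2, 20), acq.s0)
        sig[0, 0, 1] = 0.0
        series = signal_to_concentration(sig, acq)
        assert series.mask[0, 0, 0] and not series.mask[0, 0, 1]


def _smooth_curve(rng, t_len):
    from scipy.ndimage import gaussian_filter1d

    return np.abs(gaussian_filter1d(rng.standard_normal(t_len), 2.0))


class TestCsvd:
    def test_self_deconvolution_gives_scaled_delta(self):
        t = np.arange(16) * TR
        aif = gamma_variate_aif(AifParams(t0=2 * TR), t)
        k = csvd_deconvolve(aif, aif, TR, CFG0)
        assert k[0] == pytest.approx(1.0 / TR, rel=1e-8)
        assert np.allclose(np.delete(k, 0), 0.0, atol=1e-8)

    def test_zero_tissue_curve_gives_zero(self):
        t = np.arange(16) * TR
        aif = gamma_variate_aif(AifParams(t0=2 * TR), t)
        assert np.allclose(csvd_deconvolve(np.zeros(16), aif, TR, CFG0), 0.0)

    def test_zero_aif_is_singular(self):
        with pytest.raises(SingularInputError):
            csvd_deconvolve(np.ones(8), np.zeros(8), TR, CFG0)

    def test_matches_direct_pseudoinverse_oracle(self):
        # unregularized cSVD == pinv solve of the padded circulant system
        rng = np.random.default_rng(0)
        t_len = 16
        aif = _smooth_curve(rng, t_len)
        conc = _smooth_curve(rng, t_len)
        pad = 2 * t_len
        ca = np.zeros(pad)
        ca[:t_len] = aif
        a = TR * ca[(np.arange(pad)[:, None] - np.arange(pad)[None, :]) % pad]
        c_pad = np.zeros(pad)
        c_pad[:t_len] = conc
        oracle = (np.linalg.pinv(a) @ c_pad)[:t_len]
        assert np.allclose(csvd_deconvolve(conc, aif, TR, CFG0), oracle, atol=1e-8)

    def test_recovers_flow_and_delay_on_noiseless_voxel(self, noiseless_phantom):
        ph = noiseless_phantom
        acq = ph.acquisition
        series = signal_to_concentration(ph.signal, acq)
        idx = tuple(np.argwhere(ph.lesion_mask)[5])
        k = csvd_deconvolve(series.conc[idx], ph.aif_curve, acq.tr, CFG0)
        assert compute_cbf(k) == pytest.approx(ph.truth["cbf"][idx], rel=0.05)
        assert abs(compute_tmax(k, acq.tr) - ph.truth["delay"][idx]) <= acq.tr


class TestScalarOps:
    def test_cbv_ratio_cases(self):
        t = np.arange(32) * TR
        aif = gamma_variate_aif(AifParams(t0=2 * TR), t)
        assert compute_cbv(aif, aif, t) == pytest.approx(1.0)
        assert compute_cbv(np.zeros_like(aif), aif, t) == 0.0
        with pytest.raises(SingularInputError):
            compute_cbv(aif, np.zeros_like(aif), t)

    def test_cbf_and_tmax_read_the_residue_curve(self):
        k = np.zeros(20)
        assert compute_cbf(k) == 0.0
        k[3] = 0.7
        assert compute_cbf(k) == pytest.approx(0.7)
        assert compute_tmax(k, TR) == pytest.approx(3 * TR)
        assert compute_tmax(np.roll(k, 2), TR) == pytest.approx(5 * TR)

    def test_mtt_division_and_degenerate_flow(self):
        assert compute_mtt(0.04, 0.01) == pytest.approx(4.0)
        assert np.isnan(compute_mtt(0.04, 0.0))  # masked-invalid, no exception

    def test_ttp_peak_and_tie_break(self):
        c = np.zeros(30)
        c[12] = 1.0
        val, low = compute_ttp(c, TR)
        assert val == pytest.approx(12 * TR) and not low
        val, low = compute_ttp(np.ones(30), TR)
        assert val == 0.0 and low  # earliest frame on ties, flagged


class TestFullPipeline:
    def test_noiseless_parameter_recovery(self, noiseless_phantom, noiseless_maps):
        ph, m = noiseless_phantom, noiseless_maps
        msk = m.mask
        for name in ("cbv", "cbf"):
            est, tru = m.as_dict()[name][msk], ph.truth[name][msk]
            assert np.median(np.abs(est - tru) / tru) <= 0.05
        assert np.max(np.abs(m.tmax[msk] - ph.truth["tmax"][msk])) <= ph.acquisition.tr
        mtt_med = np.median(np.abs(m.mtt[msk] - ph.truth["mtt"][msk]) / ph.truth["mtt"][msk])
        assert mtt_med <= 0.07

    def test_mtt_is_cbv_over_cbf_exactly(self, noiseless_maps):
        m = noiseless_maps
        assert np.allclose(m.mtt[m.mask], m.cbv[m.mask] / m.cbf[m.mask], rtol=1e-12)

    def test_ttp_lesion_shift(self, noiseless_phantom, noiseless_maps):
        ph, m = noiseless_phantom, noiseless_maps
        les = ph.lesion_mask & m.mask
        bg = ph.brain_mask & ~ph.lesion_mask & m.mask
        delta = np.median(m.ttp[les]) - np.median(m.ttp[bg])
        assert delta >= 6.0 - ph.acquisition.tr

    def test_cbv_order_invariant_ttp_not(self, noiseless_phantom):
        ph = noiseless_phantom
        acq = ph.acquisition
        rng = np.random.default_rng(3)
        perm = rng.permutation(acq.n_frames)
        # keep the baseline frames in place so S0 is unchanged
        perm = np.concatenate([np.arange(acq.n_prebolus),
                               acq.n_prebolus + rng.permutation(acq.n_frames - acq.n_prebolus)])
        m1 = compute_all_maps(ph, cfg=CFG0)
        m2 = compute_all_maps(ph.signal[..., perm], aif_curve=ph.aif_curve,
                              acq=acq, cfg=CFG0, mask=ph.brain_mask)
        assert np.allclose(m1.cbv[m1.mask], m2.cbv[m1.mask], atol=1e-12)
        assert not np.allclose(m1.ttp[m1.mask], m2.ttp[m1.mask])

    def test_deterministic(self, noiseless_phantom):
        a = compute_all_maps(noiseless_phantom, cfg=CFG0)
        b = compute_all_maps(noiseless_phantom, cfg=CFG0)
        for k in ("cbf", "cbv", "mtt", "tmax", "ttp"):
            assert np.array_equal(a.as_dict()[k], b.as_dict()[k], equal_nan=True)

    def test_empty_mask_errors(self, noiseless_phantom):
        with pytest.raises(EmptyResultError):
            compute_all_maps(noiseless_phantom, mask=np.zeros_like(noiseless_phantom.brain_mask))

    def test_error_decreases_with_noise(self):
        # unregularized inversion so the error reflects noise, not SVD bias
        errs = {"cbf": [], "cbv": []}
        for sd in (0.0, 1.0, 4.0):
            acq = AcquisitionParams(n_frames=64, grid=(2, 24, 24), noise_sd=sd)
            ph = build_phantom(seed=9, acq=acq)
            m = compute_all_maps(ph, cfg=CFG0)
            msk = m.mask
            for name in errs:
                est, tru = m.as_dict()[name][msk], ph.truth[name][msk]
                errs[name].append(np.median(np.abs(est - tru) / tru))
        for name, e in errs.items():
            assert e[0] < e[1] < e[2], (name, e)
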