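"""MRCP and ERD feature tests, including analytic identities."""

import dataclasses

import numpy as np
import pytest

from mrcperd.config import ERDParams, MRCPParams, default_erd_params
from mrcperd.features import (
    compute_erd,
    compute_mrcp,
    erd_min,
    extract_features,
    mrcp_peak,
)

from conftest import make_epochs

FS = 256.0


def onset_epochs(data, movements=None):
    n_samp = data.shape[2]
    assert n_samp == int(5.0 * FS)
    return make_epochs(data, movements=movements, alignment="onset",
                       window=(-2.5, 2.5), sample_rate=FS, n_eeg=16)


class TestComputeMRCP:
    def test_mean_of_identical_trials_is_any_trial(self, rng):
        one = rng.standard_normal((1, 17, int(5 * FS)))
        ep = onset_epochs(np.repeat(one, 6, axis=0))
        wf = compute_mrcp(ep, MRCPParams())
        assert np.allclose(wf, one[0])

    def test_singleton_subset(self, rng):
        data = rng.standard_normal((5, 17, int(5 * FS)))
        ep = onset_epochs(data)
        wf = compute_mrcp(ep, MRCPParams(), trial_subset=np.array([3]))
        assert np.allclose(wf, data[3])

    def test_empty_subset_rejected(self, rng):
        ep = onset_epochs(rng.standard_normal((4, 17, int(5 * FS))))
        with pytest.raises(ValueError, match="empty"):
            compute_mrcp(ep, MRCPParams(), trial_subset=np.array([], dtype=int))

    def test_bad_channels_excluded_per_trial(self, rng):
        data = np.ones((4, 17, int(5 * FS)))
        data[0] *= 100.0  # contaminated trial
        ep = onset_epochs(data)
        ep.bad_channels[0, :] = True
        wf = compute_mrcp(ep, MRCPParams())
        assert np.allclose(wf, 1.0)  # trial 0 contributes nowhere

    def test_convergence_to_template(self, rng):
        # mean of template + noise approaches the template as 1/sqrt(N)
        n_samp = int(5 * FS)
        template = -5.0 * np.exp(-0.5 * ((np.arange(n_samp) / FS - 2.3) / 0.2) ** 2)
        errs = {}
        for n in (8, 128):
            data = np.tile(template, (n, 17, 1)) + 4.0 * rng.standard_normal((n, 17, n_samp))
            wf = compute_mrcp(onset_epochs(data), MRCPParams())
            errs[n] = np.sqrt(np.mean((wf[3] - template) ** 2))
        assert errs[128] < errs[8] / 2.5  # expected factor 4, slack for chance


class TestMRCPPeak:
    def _waveform(self, trace):
        n_samp = int(5 * FS)
        wf = np.zeros((17, n_samp))
        wf[3] = trace  # Cz is channel 3 of the 16-channel layout
        times = -2.5 + np.arange(n_samp) / FS
        return wf, times

    def test_constant_negative_window(self):
        from mrcperd.montage import build_montage, default_eeg_labels

        mont = build_montage(default_eeg_labels(16))
        assert mont.names[3] == "Cz"
        wf, times = self._waveform(np.full(int(5 * FS), -5.0))
        assert mrcp_peak(wf, times, mont, MRCPParams()) == pytest.approx(-5.0)

    def test_triangular_deflection_windowed_mean(self):
        # peak -10 µV at t = -0.25 s with ±100 µV/s slopes: the ±100 ms
        # window mean is -10 + 100·0.05 = -5 µV
        from mrcperd.montage import build_montage, default_eeg_labels

        mont = build_montage(default_eeg_labels(16))
        n_samp = int(5 * FS)
        times = -2.5 + np.arange(n_samp) / FS
        trace = np.where(np.abs(times + 0.25) <= 0.15,
                         -10.0 + 100.0 * np.abs(times + 0.25), 0.0)
        wf = np.zeros((17, n_samp))
        wf[3] = trace
        got = mrcp_peak(wf, times, mont, MRCPParams())
        # closed form on the discrete ±h-sample window: mean |t| is
        # h(h+1)/((2h+1)·fs), h = round(0.1·fs)
        h = round(0.1 * FS)
        expected = -10.0 + 100.0 * (h * (h + 1) / (2 * h + 1)) / FS
        assert got == pytest.approx(expected, abs=1e-9)

    def test_flat_zero(self):
        from mrcperd.montage import build_montage, default_eeg_labels

        mont = build_montage(default_eeg_labels(16))
        wf, times = self._waveform(np.zeros(int(5 * FS)))
        assert mrcp_peak(wf, times, mont, MRCPParams()) == 0.0

    def test_missing_channel_rejected(self):
        from mrcperd.montage import build_montage

        mont = build_montage(["C3", "C4"], n_eog=0, accel=False)
        with pytest.raises(ValueError, match="Cz"):
            mrcp_peak(np.zeros((2, 100)), np.linspace(-1, 1, 100), mont, MRCPParams())

    def test_scaling_linearity(self, rng):
        from mrcperd.montage import build_montage, default_eeg_labels

        mont = build_montage(default_eeg_labels(16))
        n_samp = int(5 * FS)
        times = -2.5 + np.arange(n_samp) / FS
        wf = np.zeros((17, n_samp))
        wf[3] = -np.exp(-0.5 * ((times + 0.2) / 0.15) ** 2)
        p1 = mrcp_peak(wf, times, mont, MRCPParams())
        p3 = mrcp_peak(3.0 * wf, times, mont, MRCPParams())
        assert p3 == pytest.approx(3.0 * p1)


def erd_epochs(data, movements=None):
    n_samp = data.shape[2]
    assert n_samp == int(8.0 * FS)
    return make_epochs(data, movements=movements, alignment="onset",
                       window=(-2.5, 5.5), sample_rate=FS, n_eeg=16)


def band_noise(rng, shape, band=(8.0, 13.0)):
    from scipy import signal as sps

    sos = sps.butter(4, band, btype="bandpass", fs=FS, output="sos")
    return sps.sosfiltfilt(sos, rng.standard_normal(shape), axis=-1)


class TestComputeERD:
    def test_power_halved_gives_minus_fifty(self, rng):
        prm = dataclasses.replace(default_erd_params("mu"), power_smooth=0.0)
        n_samp = int(8 * FS)
        data = band_noise(rng, (200, 17, n_samp))
        times = -2.5 + np.arange(n_samp) / FS
        gain = np.where((times >= -0.5) & (times <= 0.5), 1 / np.sqrt(2), 1.0)
        ep = erd_epochs(data * gain[None, None, :])
        erd = compute_erd(ep, prm)
        v = erd_min(erd, ep.times, ep.montage, prm)
        assert v == pytest.approx(-50.0, abs=2.0)

    def test_power_doubled_gives_plus_hundred(self, rng):
        prm = dataclasses.replace(default_erd_params("mu"), power_smooth=0.0)
        n_samp = int(8 * FS)
        data = band_noise(rng, (200, 17, n_samp))
        times = -2.5 + np.arange(n_samp) / FS
        gain = np.where(np.abs(times) <= 0.5, np.sqrt(2), 1.0)
        ep = erd_epochs(data * gain[None, None, :])
        erd = compute_erd(ep, prm)
        v = erd_min(erd, ep.times, ep.montage, prm)
        assert v == pytest.approx(100.0, abs=4.0)

    def test_stationary_noise_fluctuates_around_zero(self, rng):
        prm = default_erd_params("mu")
        data = band_noise(rng, (120, 17, int(8 * FS)))
        ep = erd_epochs(data)
        erd = compute_erd(ep, prm)
        roi = [ep.montage.index(c) for c in prm.roi]
        assert abs(np.nanmean(erd[roi])) < 3.0

    def test_reference_window_normalises_to_zero(self, rng):
        prm = default_erd_params("mu")
        data = band_noise(rng, (50, 17, int(8 * FS)))
        ep = erd_epochs(data)
        erd = compute_erd(ep, prm)
        r0, r1 = prm.reference_window
        mask = (ep.times >= r0) & (ep.times < r1)
        assert np.allclose(np.nanmean(erd[:, mask], axis=1)[ep.montage.eeg_idx],
                           0.0, atol=1e-8)

    def test_invariant_under_global_gain(self, rng):
        prm = default_erd_params("beta")
        data = band_noise(rng, (30, 17, int(8 * FS)), band=(14.0, 30.0))
        ep1 = erd_epochs(data)
        ep2 = erd_epochs(data * 40.0)
        assert np.allclose(compute_erd(ep1, prm), compute_erd(ep2, prm),
                           rtol=1e-10, atol=1e-8, equal_nan=True)

    def test_zero_signal_reference_rejected(self):
        prm = default_erd_params("mu")
        ep = erd_epochs(np.zeros((5, 17, int(8 * FS))))
        with pytest.raises(ValueError, match="reference-window power"):
            compute_erd(ep, prm)


class TestERDMin:
    def _erd(self, values_by_channel):
        n_samp = int(8 * FS)
        from mrcperd.montage import build_montage, default_eeg_labels

        mont = build_montage(default_eeg_labels(16))
        erd = np.zeros((17, n_samp))
        for ch, v in values_by_channel.items():
            erd[mont.index(ch)] = v
        times = -2.5 + np.arange(n_samp) / FS
        return erd, times, mont

    def test_constant_roi(self):
        prm = default_erd_params("mu")
        erd, times, mont = self._erd({c: -30.0 for c in prm.roi})
        assert erd_min(erd, times, mont, prm) == pytest.approx(-30.0)

    def test_roi_linearity(self):
        prm = default_erd_params("mu")
        half = len(prm.roi) // 2
        vals = {c: -40.0 for c in prm.roi[:half]} | {c: -20.0 for c in prm.roi[half:]}
        erd, times, mont = self._erd(vals)
        assert erd_min(erd, times, mont, prm) == pytest.approx(-30.0)

    def test_all_roi_missing_rejected(self):
        prm = default_erd_params("mu")
        from mrcperd.montage import build_montage

        mont = build_montage(["Fp1", "Fp2"], n_eog=0, accel=False)
        with pytest.raises(ValueError, match="ROI"):
            erd_min(np.zeros((2, 100)), np.linspace(-1, 1, 100), mont, prm)


class TestExtractFeatures:
    def _cells(self, rng, subjects=("S01", "S02")):
        movements = (["elbow_flexion", "supination", "hand_open"] * 4)
        cells = {}
        for s in subjects:
            for cond in ("ME", "MI"):
                mrcp = onset_epochs(rng.standard_normal((12, 17, int(5 * FS))),
                                    movements=movements)
                mu = erd_epochs(band_noise(rng, (12, 17, int(8 * FS))),
                                movements=movements)
                beta = erd_epochs(band_noise(rng, (12, 17, int(8 * FS)), (14.0, 30.0)),
                                  movements=movements)
                cells[(s, cond)] = {"mrcp": mrcp, "mu": mu, "beta": beta}
        return cells

    def test_row_count_and_determinism(self, rng):
        cells = self._cells(rng)
        prm = MRCPParams()
        mu, beta = default_erd_params("mu"), default_erd_params("beta")
        t1 = extract_features(cells, prm, mu, beta)
        t2 = extract_features(cells, prm, mu, beta)
        assert len(t1) == 2 * 2 * 3 * 3
        assert t1.equals(t2)
        assert set(t1["feature"]) == {"mrcp_peak", "erd_mu_min", "erd_beta_min"}

    def test_empty_cohort(self):
        prm = MRCPParams()
        mu, beta = default_erd_params("mu"), default_erd_params("beta")
        out = extract_features({}, prm, mu, beta)
        assert len(out) == 0
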