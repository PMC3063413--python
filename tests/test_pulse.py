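import numpy as np
import pytest
from scipy import signal as sig

import fastkit as fk
from fastkit.errors import DetectionError, ParameterError
from fastkit.pulse import (
    HeartbeatSeries,
    PAConfig,
    branch_filters,
    beat_locked_average,
    correct_combined,
    correct_gaussian_mean,
    correct_obs_pca,
    detect_qrs,
)
from fastkit.synth import empty_recording, gen_background, inject_pulse_artefact

FS = 500.0


def noisy_ecg_recording(seed=5, bpm=70, snr_db=10.0, duration=120.0):
    rec = gen_background(2, FS, duration, seed=seed)
    rec, truth = inject_pulse_artefact(rec, bpm=bpm, variability=0.1, seed=seed)
    i = rec.channel_names.index("ECG")
    rng = np.random.default_rng(seed + 1)
    noise_rms = rec.source._data[i].std() / 10 ** (snr_db / 20)
    rec.source._data[i] += rng.standard_normal(rec.n_samples) * noise_rms
    return rec, truth


def regular_beats(duration_s=120.0, rr_s=1.0, start_s=0.5):
    return np.arange(int(start_s * FS), int((duration_s - 1) * FS), int(rr_s * FS))


class TestDetectQrs:
    def test_noise_free_exact(self):
        rec = empty_recording(1, FS, 60.0)
        rec, truth = inject_pulse_artefact(rec, bpm=60, variability=0.0, seed=1)
        beats = detect_qrs(rec, "ECG")
        true = truth["beats"]
        assert len(beats) == len(true)
        assert np.abs(beats.r_peaks - true).max() <= 1

    def test_sensitivity_on_noisy_ecg(self):
        rec, truth = noisy_ecg_recording()
        beats = detect_qrs(rec, "ECG")
        true = truth["beats"]
        tol = int(0.020 * FS)
        matched = sum(1 for t in true if np.min(np.abs(beats.r_peaks - t)) <= tol)
        assert matched / len(true) >= 0.99
        false = len(beats) - matched
        assert false / len(beats) <= 0.01

    def test_polarity_invariant(self):
        rec = empty_recording(1, FS, 60.0)
        rec, truth = inject_pulse_artefact(rec, bpm=60, variability=0.0, seed=2)
        i = rec.channel_names.index("ECG")
        rec.source._data[i] *= -1.0
        beats = detect_qrs(rec, "ECG")
        assert np.abs(beats.r_peaks - truth["beats"]).max() <= 1

    def test_flat_channel_error(self):
        rec = empty_recording(1, FS, 60.0, channel_names=["ECG"])
        with pytest.raises(DetectionError):
            detect_qrs(rec, "ECG")

    def test_too_short_error(self):
        rec = empty_recording(1, FS, 5.0, channel_names=["ECG"])
        with pytest.raises(ParameterError):
            detect_qrs(rec, "ECG")


class TestHeartbeatSeries:
    def test_strictly_increasing(self):
        with pytest.raises(ParameterError):
            HeartbeatSeries([10, 10, 20])

    def test_median_rr(self):
        assert HeartbeatSeries([0, 100, 210, 300]).median_rr == 100


class TestGaussianMean:
    def test_identical_artefact_exact(self):
        rec = empty_recording(2, FS, 60.0)
        rec, truth = inject_pulse_artefact(rec, bpm=60, variability=0.0, seed=3)
        beats = HeartbeatSeries(truth["beats"])
        out = correct_gaussian_mean(rec, beats)
        med = beats.median_rr
        pre, post = med // 4, med - med // 4
        x = fk.read_window(out, [out.channel_names[0]], 0, out.n_samples)[0]
        # interior beats: boundary epochs differ (no preceding/following
        # artefact tail), and the 21-beat window reaches 10 beats out
        resid = max(np.abs(x[r - pre : r + post]).max() for r in beats.r_peaks[11:-11])
        assert resid < 1e-6

    def test_gaussian_beats_flat_mean_under_drift(self):
        # artefact amplitude drifts linearly; Gaussian weighting tracks it better
        rr = int(FS)
        beats = regular_beats()
        template = np.zeros(rr)
        template[rr // 4 : rr // 2] = 30.0
        n = int(120 * FS)

        def build(weight_sigma):
            x = np.zeros(n)
            for k, r in enumerate(beats):
                x[r : r + rr] += template[: n - r] * (1 + 0.01 * k)
            rec = empty_recording(1, FS, 120.0)
            rec.source._data[0] = x
            cfg = PAConfig(method="gaussian_mean", gm_sigma_beats=weight_sigma)
            out = correct_gaussian_mean(rec, HeartbeatSeries(beats), cfg)
            y = fk.read_window(out, out.channel_names, 0, out.n_samples)[0]
            return np.sqrt(np.mean(y[beats[3] : beats[-3]] ** 2))

        assert build(5.0) < build(1e6)  # huge sigma ~ unweighted mean

    def test_first_beat_truncated_window_finite(self):
        rec = empty_recording(1, FS, 60.0)
        rec, truth = inject_pulse_artefact(rec, bpm=60, variability=0.2, seed=4)
        beats = HeartbeatSeries(truth["beats"])
        out = correct_gaussian_mean(rec, beats)
        x = fk.read_window(out, out.channel_names, 0, out.n_samples)
        assert np.all(np.isfinite(x))

    def test_too_few_beats(self):
        rec = empty_recording(1, FS, 60.0)
        with pytest.raises(ParameterError):
            correct_gaussian_mean(rec, HeartbeatSeries(regular_beats()[:5]))


class TestObsPca:
    def _rank3_recording(self, seed=7, n_extra=0):
        rng = np.random.default_rng(seed)
        rec = empty_recording(1, FS, 120.0)
        beats = regular_beats()
        rr = int(FS)
        pre = rr // 4
        basis = rng.standard_normal((3, rr))
        coefs = rng.standard_normal((len(beats), 3))
        for k, r in enumerate(beats):
            rec.source._data[0, r - pre : r - pre + rr] += coefs[k] @ basis
        return rec, HeartbeatSeries(beats), basis, coefs

    def test_rank3_exact_with_k4(self):
        rec, beats, _, _ = self._rank3_recording()
        out = correct_obs_pca(rec, beats, PAConfig(method="obs_pca", n_obs_components=4))
        rr = int(FS)
        pre = rr // 4
        x = fk.read_window(out, out.channel_names, 0, out.n_samples)[0]
        resid = max(
            np.abs(x[r - pre : r - pre + rr]).max() for r in beats.r_peaks[2:-2]
        )
        assert resid < 1e-6

    def test_k2_residual_matches_projection_oracle(self):
        rec, beats, _, _ = self._rank3_recording(seed=8)
        x0 = rec.source._data[0].copy()
        rr = int(FS)
        pre = rr // 4

        # oracle: direct projection of the demeaned epoch matrix
        E = np.stack([x0[r - pre : r - pre + rr] for r in beats.r_peaks])
        D = E - E.mean(axis=1, keepdims=True)
        _, s, vt = np.linalg.svd(D, full_matrices=False)
        B = np.column_stack([vt[:2].T, np.ones(rr)])
        proj = B @ np.linalg.lstsq(B, E.T, rcond=None)[0]
        oracle_resid = E.T - proj  # rr x n_beats

        out = correct_obs_pca(rec, beats, PAConfig(method="obs_pca", n_obs_components=2))
        x = fk.read_window(out, out.channel_names, 0, out.n_samples)[0]
        got = np.stack([x[r - pre : r - pre + rr] for r in beats.r_peaks])
        inner = slice(2, -2)
        assert np.allclose(
            np.var(got[inner]), np.var(oracle_resid.T[inner]), rtol=1e-6
        )

    def test_pure_eeg_mostly_preserved(self):
        rec = gen_background(1, FS, 120.0, seed=9)
        x0 = rec.source._data[0].copy()
        beats = HeartbeatSeries(regular_beats())
        out = correct_obs_pca(rec, beats, PAConfig(method="obs_pca"))
        x1 = fk.read_window(out, out.channel_names, 0, out.n_samples)[0]

        def band_pow(x):
            f, p = sig.welch(x, fs=FS, nperseg=int(8 * FS))
            m = (f >= 8) & (f <= 12)
            return p[m].sum()

        assert abs(band_pow(x1) - band_pow(x0)) / band_pow(x0) < 0.10

    def test_determinism(self):
        rec, beats, _, _ = self._rank3_recording(seed=10)
        cfg = PAConfig(method="obs_pca")
        a = correct_obs_pca(rec, beats, cfg).source._data
        b = correct_obs_pca(rec, beats, cfg).source._data
        assert np.array_equal(a, b)


class TestCombined:
    def test_branch_complementarity(self):
        rng = np.random.default_rng(11)
        x = rng.standard_normal(int(60 * FS))
        low, high = branch_filters(x, FS, 4.0)
        err = np.sqrt(np.mean((low + high - x) ** 2)) / np.std(x)
        assert err < 0.01

    def test_branch_crossing_at_4hz(self):
        rng = np.random.default_rng(12)
        x = rng.standard_normal(int(240 * FS))
        low, high = branch_filters(x, FS, 4.0)
        nper = int(FS / 0.25)  # 0.25 Hz bins
        f, pl = sig.welch(low, fs=FS, nperseg=nper)
        _, ph = sig.welch(high, fs=FS, nperseg=nper)
        valid = slice(1, len(f))
        i = np.argmin(np.abs(np.log(pl[valid] / ph[valid])))
        assert f[valid][i] == pytest.approx(4.0, abs=0.25)

    def test_band_separated_correction(self):
        # artefact below 4 Hz, broadband EEG above 4 Hz (narrowband EEG
        # would be low-rank across beat epochs and absorbed by OBS).
        # OBS eats a fraction of EEG that scales with epoch_len / n_beats,
        # so a sleep-length recording is needed for r > 0.99.
        duration = 2400.0
        rng = np.random.default_rng(13)
        rec = empty_recording(1, FS, duration)
        eeg = fk.highpass(rng.standard_normal(rec.n_samples), FS, 5.0)[0]
        eeg *= 10.0 / eeg.std()
        beats = regular_beats(duration_s=duration)
        rr = int(FS)
        artefact = np.zeros(rec.n_samples)
        bump = 40 * np.exp(-0.5 * ((np.arange(rr) / FS - 0.5) / 0.15) ** 2)
        bump -= bump.mean()
        for r in beats:
            ln = min(rr, rec.n_samples - r)
            artefact[r : r + ln] += bump[:ln]
        rec.source._data[0] = eeg + artefact
        out = correct_combined(rec, HeartbeatSeries(beats), PAConfig())
        y = fk.read_window(out, out.channel_names, 0, out.n_samples)[0]
        sl = slice(int(5 * FS), int((duration - 5) * FS))
        y_high = fk.highpass(y[sl], FS, 4.0)[0]
        r = np.corrcoef(y_high, fk.highpass(eeg[sl], FS, 4.0)[0])[0, 1]
        assert r > 0.99
        lo_before = fk.lowpass(artefact[sl], FS, 4.0)[0]
        lo_after = fk.lowpass(y[sl] - eeg[sl], FS, 4.0)[0]
        drop_db = 10 * np.log10(np.mean(lo_before**2) / np.mean(lo_after**2))
        assert drop_db >= 20

    def test_artefact_reduction_and_spectrum_ordering(self):
        rec = gen_background(2, FS, 120.0, seed=14)
        clean = rec.source._data[:2].copy()
        rec, truth = inject_pulse_artefact(rec, bpm=65, variability=0.1, seed=14)
        beats = HeartbeatSeries(truth["beats"])
        med = beats.median_rr
        pre, post = med // 4, med - med // 4

        def locked_resid(r):
            x = fk.read_window(r, [r.channel_names[0]], 0, r.n_samples)[0]
            return np.ptp(beat_locked_average(x - clean[0], beats.r_peaks, pre, post))

        base = locked_resid(rec)
        for method, fn in [
            ("gaussian_mean", correct_gaussian_mean),
            ("obs_pca", correct_obs_pca),
            ("combined", correct_combined),
        ]:
            out = fn(rec, beats, PAConfig(method=method))
            assert locked_resid(out) <= 0.3 * base, method

    def test_ecg_channel_untouched(self):
        rec = gen_background(2, FS, 120.0, seed=15)
        rec, truth = inject_pulse_artefact(rec, bpm=60, variability=0.1, seed=15)
        beats = HeartbeatSeries(truth["beats"])
        before = fk.read_window(rec, ["ECG"], 0, rec.n_samples)
        out = correct_combined(rec, beats, PAConfig())
        after = fk.read_window(out, ["ECG"], 0, out.n_samples)
        assert np.array_equal(before, after)
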