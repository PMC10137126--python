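import numpy as np
import pytest
from scipy.special import i0, i1

from tempogate.design import CellSpec, NoiseSpec, OscComponent
from tempogate.errors import ParameterError
from tempogate.simulate import generate_subject_epochs
from tempogate.timefreq import (BANDS, BandWindow, TFDecomposition,
                                band_window_mean, default_cycles, ersp, itc,
                                morlet_decompose)

from conftest import make_design, make_epochs, sinusoid_epochs


class TestMorlet:
    def test_pure_sinusoid_has_flat_magnitude_and_linear_phase(self, rng):
        e = sinusoid_epochs(10.0, 1, 200.0, 800, rng, random_phase=False)
        tf = morlet_decompose(e, [10.0])
        sel = tf.valid[0]
        mags = np.abs(tf.coeffs[0, 0, 0, sel])
        assert mags.std() / mags.mean() < 0.02
        phase = np.unwrap(np.angle(tf.coeffs[0, 0, 0, sel]))
        slope = np.polyfit(tf.times_s[sel], phase, 1)[0]
        assert slope == pytest.approx(2 * np.pi * 10.0, rel=0.01)

    def test_zero_signal_gives_zero_coefficients(self):
        e = make_epochs(np.zeros((2, 1, 400)))
        tf = morlet_decompose(e, [5.0, 10.0])
        assert np.all(tf.coeffs == 0)

    def test_impulse_magnitude_peaks_at_the_impulse(self):
        data = np.zeros((1, 1, 400))
        data[0, 0, 200] = 1.0
        e = make_epochs(data, t0_index=200)
        tf = morlet_decompose(e, [4.0, 8.0, 16.0])
        for k in range(3):
            mags = np.where(tf.valid[k], np.abs(tf.coeffs[0, 0, k]), -1)
            assert int(np.argmax(mags)) == 200

    def test_edge_bins_are_flagged_invalid(self, rng):
        e = sinusoid_epochs(6.0, 1, 200.0, 400, rng)
        tf = morlet_decompose(e, [6.0])
        assert not tf.valid[0, 0] and not tf.valid[0, -1]
        assert tf.valid[0, 200]

    def test_epoch_too_short_for_low_frequency(self, rng):
        e = sinusoid_epochs(5.0, 1, 200.0, 100, rng)  # 0.5 s epoch
        with pytest.raises(ParameterError, match="too short"):
            morlet_decompose(e, [0.5])

    def test_cycle_schedule(self):
        freqs = np.array([1.0, 3.0, 40.0])
        assert default_cycles(freqs) == pytest.approx([3.0, 3.0, 8.0])


class TestITC:
    def test_identical_trials_give_unit_coherence(self, rng):
        trial = rng.standard_normal((1, 1, 400))
        e = make_epochs(np.repeat(trial, 5, axis=0))
        tf = morlet_decompose(e, [6.0, 10.0])
        m = itc(tf)
        assert np.allclose(m[:, :, tf.valid.all(axis=0)], 1.0, atol=1e-12)

    def test_antiphase_pair_cancels(self, rng):
        e1 = sinusoid_epochs(10.0, 1, 200.0, 400, rng, random_phase=False)
        data = np.concatenate([e1.data, -e1.data], axis=0)
        e = make_epochs(data)
        tf = morlet_decompose(e, [10.0])
        m = itc(tf)
        assert np.all(m[0, 0, tf.valid[0]] < 1e-10)

    def test_single_trial_rejected(self, rng):
        e = sinusoid_epochs(10.0, 1, 200.0, 400, rng)
        tf = morlet_decompose(e, [10.0])
        with pytest.raises(ParameterError, match="2 trials"):
            itc(tf)

    def test_von_mises_phases_recover_bessel_ratio(self):
        osc = OscComponent(center_freq_hz=6.0, amplitude_uv=2.0,
                           phase_concentration_kappa=2.0,
                           envelope=(0.03, 0.35),
                           channel_weights={"O1": 1.0})
        cell = CellSpec(oscillations=(osc,), noise=NoiseSpec(noise_sd_uv=0.0))
        spec = make_design(cell, n_trials=100)
        e = generate_subject_epochs(spec, "S01", seed=13)
        sub = e.select_trials(e.cell_mask("attended", "NTP"))
        tf = morlet_decompose(sub, [6.0])
        m = itc(tf)
        t_idx = int(np.argmin(np.abs(tf.times_s - 0.19)))
        assert m[0, 0, t_idx] == pytest.approx(i1(2) / i0(2), abs=0.06)

    def test_amplitude_rescaling_leaves_itc_unchanged(self, rng):
        e = sinusoid_epochs(8.0, 6, 200.0, 400, rng)
        tf = morlet_decompose(e, [8.0])
        m1 = itc(tf)
        scales = rng.uniform(0.5, 5.0, size=6)[:, None, None, None]
        tf2 = TFDecomposition(coeffs=tf.coeffs * scales,
                              freqs_hz=tf.freqs_hz, times_s=tf.times_s,
                              channels=tf.channels, valid=tf.valid,
                              method_meta=tf.method_meta)
        assert np.allclose(itc(tf2), m1, atol=1e-12)

    def test_itc_bounded_in_unit_interval(self, rng):
        e = make_epochs(rng.standard_normal((8, 2, 400)))
        tf = morlet_decompose(e, [4.0, 10.0, 20.0])
        m = itc(tf)
        assert np.all(m >= 0) and np.all(m <= 1 + 1e-12)

    def test_band_window_itc_increases_with_kappa(self):
        values = []
        for kappa in (0.0, 0.5, 1.0, 2.0, 4.0):
            osc = OscComponent(center_freq_hz=6.0, amplitude_uv=2.0,
                               phase_concentration_kappa=kappa,
                               envelope=(0.03, 0.35),
                               channel_weights={"O1": 1.0})
            cell = CellSpec(oscillations=(osc,),
                            noise=NoiseSpec(noise_sd_uv=1.0))
            spec = make_design(cell, n_trials=60)
            e = generate_subject_epochs(spec, "S01", seed=17)
            sub = e.select_trials(e.cell_mask("attended", "NTP"))
            tf = morlet_decompose(sub, [5.0, 6.0, 7.0])
            values.append(band_window_mean(
                itc(tf), tf, BandWindow("theta", (0.1, 0.3))))
        assert values == sorted(values)


class TestERSP:
    def test_stationary_signal_is_zero_db(self, rng):
        e = sinusoid_epochs(10.0, 20, 200.0, 400, rng)
        tf = morlet_decompose(e, [5.0, 10.0, 20.0])
        maps = ersp(tf, (-0.5, -0.4))
        for k in range(3):
            assert np.abs(maps[0, k, tf.valid[k]]).max() < 0.2

    def test_doubling_all_amplitudes_adds_six_db(self, rng):
        e = sinusoid_epochs(10.0, 10, 200.0, 400, rng)
        tf = morlet_decompose(e, [10.0])
        base = ersp(tf, (-0.5, -0.4))
        tf2 = TFDecomposition(coeffs=2 * tf.coeffs, freqs_hz=tf.freqs_hz,
                              times_s=tf.times_s, channels=tf.channels,
                              valid=tf.valid, method_meta=tf.method_meta)
        boosted = ersp(tf2, (-0.5, -0.4))
        # baseline rescales too: difference map is identically 0; instead
        # scale only post-baseline samples
        assert np.allclose(boosted, base, atol=1e-10)
        sel_post = tf.times_s > 0.0
        coeffs = tf.coeffs.copy()
        coeffs[..., sel_post] *= 2.0
        tf3 = TFDecomposition(coeffs=coeffs, freqs_hz=tf.freqs_hz,
                              times_s=tf.times_s, channels=tf.channels,
                              valid=tf.valid, method_meta=tf.method_meta)
        m3 = ersp(tf3, (-0.5, -0.4))
        interior = sel_post & tf.valid[0] & (tf.times_s > 0.2)
        assert np.abs(m3[0, 0, interior] - 20 * np.log10(2)).max() < 0.2

    def test_band_power_doubling_recovers_three_db(self, rng):
        # amplitude x sqrt(2) inside 0.15-0.45 s -> power x 2 -> +3.01 dB
        n_samp, fs = 400, 200.0
        t = (np.arange(n_samp) - n_samp // 2) / fs
        gate = 1.0 + (np.sqrt(2) - 1.0) * ((t > 0.15) & (t < 0.45))
        e = sinusoid_epochs(20.0, 12, fs, n_samp, rng, amplitude=gate)
        tf = morlet_decompose(e, np.arange(15.0, 31.0))
        maps = ersp(tf, (-0.5, -0.4))
        got = band_window_mean(maps, tf, BandWindow("beta", (0.25, 0.35)))
        assert got == pytest.approx(10 * np.log10(2), abs=0.2)

    def test_zero_baseline_power_names_the_frequency(self):
        e = make_epochs(np.zeros((3, 1, 400)))
        tf = morlet_decompose(e, [7.0])
        with pytest.raises(ParameterError, match="7"):
            ersp(tf, (-0.5, -0.4))


class TestBandWindowMean:
    def test_constant_map(self, rng):
        e = sinusoid_epochs(6.0, 3, 200.0, 400, rng)
        tf = morlet_decompose(e, [4.0, 5.0, 6.0])
        vals = np.full((1, 3, 400), 2.5)
        assert band_window_mean(vals, tf, BandWindow("theta", (0.0, 0.3))) \
            == pytest.approx(2.5)

    def test_frequency_gradient_averages_to_band_center(self, rng):
        e = sinusoid_epochs(6.0, 3, 200.0, 400, rng)
        freqs = np.array([4.0, 5.0, 6.0, 7.0, 8.0])
        tf = morlet_decompose(e, freqs)
        vals = np.broadcast_to(freqs[None, :, None], (1, 5, 400)).copy()
        got = band_window_mean(vals, tf, BandWindow("theta", (0.0, 0.2)))
        assert got == pytest.approx(6.0)

    def test_fully_contaminated_window_is_an_error(self, rng):
        e = sinusoid_epochs(6.0, 3, 200.0, 400, rng)
        tf = morlet_decompose(e, [4.0])
        with pytest.raises(ParameterError, match="edge"):
            band_window_mean(np.zeros((1, 1, 400)), tf,
                             BandWindow("theta", (-1.0, -0.95)))

    def test_band_definitions(self):
        assert BANDS["delta"] == (1.0, 3.0)
        assert BANDS["theta"] == (4.0, 8.0)
        assert BANDS["alpha"] == (8.0, 14.0)
        assert BANDS["beta"] == (15.0, 30.0)


class TestOracleEquivalence:
    def test_itc_and_ersp_match_bruteforce_loops(self, rng):
        from oracles import ersp_loop, itc_loop

        e = make_epochs(rng.standard_normal((5, 2, 300)), t0_index=250)
        tf = morlet_decompose(e, [6.0, 10.0])
        assert np.allclose(itc(tf), itc_loop(tf.coeffs), atol=1e-10)
        fs = 200.0
        mine = ersp(tf, (-0.5, -0.4))
        ref = ersp_loop(tf.coeffs, tf.times_s, tf.valid, (-0.5, -0.4), fs)
        assert np.allclose(mine, ref, atol=1e-10)
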