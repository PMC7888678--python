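"""Signal synthesis: sweeps, clicks, glint echoes, clutter, sequences."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scat import io as scat_io
from scat import synth
from scat.config import WindowParams

FS = 500e3


# ---------------------------------------------------------------------------
# FM chirps

class TestFmChirp:
    def test_log_sweep_instantaneous_frequency_matches_phase_derivative(self):
        """Oracle: numerically differentiate the waveform's analytic phase
        and compare to the closed-form log-sweep frequency at mid-sweep."""
        spec = synth.ChirpSpec(3e-3, ((55.0, 25.0),), "logarithmic",
                               edge_fraction=0.0)
        x = synth.make_fm_chirp(spec, FS)
        from scipy.signal import hilbert
        phase = np.unwrap(np.angle(hilbert(x)))
        f_inst = np.gradient(phase) * FS / (2 * np.pi)
        mid = x.size // 2
        want = synth.instantaneous_frequency(spec, np.array([1.5e-3]))[0]
        got = np.median(f_inst[mid - 25:mid + 25])
        assert got == pytest.approx(want, rel=0.01)
        # closed form itself: f(T/2) = sqrt(f0*f1) for a log sweep
        assert want == pytest.approx(np.sqrt(55e3 * 25e3), rel=1e-9)

    @pytest.mark.parametrize("shape", ["logarithmic", "hyperbolic", "linear"])
    def test_sweep_monotone_decreasing(self, shape):
        spec = synth.ChirpSpec(3e-3, ((55.0, 25.0),), shape)
        t = np.linspace(0, 3e-3, 101)
        f = synth.instantaneous_frequency(spec, t)
        assert f[0] == pytest.approx(55e3)
        assert f[-1] == pytest.approx(25e3)
        assert np.all(np.diff(f) < 0)

    def test_zero_bandwidth_sweep_is_pure_tone(self):
        spec = synth.ChirpSpec(1e-3, ((50.0, 50.0),), "logarithmic",
                               edge_fraction=0.0)
        x = synth.make_fm_chirp(spec, FS)
        spec_mag = np.abs(np.fft.rfft(x))
        f_peak = np.fft.rfftfreq(x.size, 1 / FS)[np.argmax(spec_mag)]
        assert f_peak == pytest.approx(50e3, abs=1.5e3)

    def test_two_harmonic_chirp_has_both_ridges(self):
        x = synth.make_fm_chirp(synth.bat_chirp_spec(), FS)
        mag = np.abs(np.fft.rfft(x))
        f = np.fft.rfftfreq(x.size, 1 / FS)
        band_energy = lambda lo, hi: np.sum(
            mag[(f >= lo) & (f <= hi)] ** 2)
        fm1 = band_energy(25e3, 55e3)
        fm2 = band_energy(56e3, 90e3)
        out = band_energy(100e3, 200e3)
        assert fm1 > 10 * out and fm2 > 10 * out

    def test_aliasing_rejected_with_nyquist_message(self):
        with pytest.raises(ValueError, match="Nyquist"):
            synth.make_fm_chirp(synth.bat_chirp_spec(), fs=150e3)

    def test_upsweep_rejected(self):
        with pytest.raises(ValueError, match="downsweep"):
            synth.ChirpSpec(3e-3, ((25.0, 55.0),)).validate()


# ---------------------------------------------------------------------------
# clicks

class TestClick:
    def test_spectral_centroid_near_center_frequency(self):
        """Oracle: FFT centroid within 5% of the declared centre."""
        spec = synth.dolphin_click_spec()
        x = synth.make_click(spec, FS)
        X = np.abs(np.fft.rfft(x, 4096)) ** 2
        f = np.fft.rfftfreq(4096, 1 / FS)
        centroid = np.sum(f * X) / np.sum(X)
        assert centroid == pytest.approx(95e3, rel=0.05)

    def test_minus20db_points_inside_band(self):
        x = synth.make_click(synth.dolphin_click_spec(), FS)
        X = np.abs(np.fft.rfft(x, 8192))
        f = np.fft.rfftfreq(8192, 1 / FS)
        thresh = X.max() / 10.0          # -20 dB
        inside = f[X >= thresh]
        assert inside.min() >= 38e3 and inside.max() <= 152e3

    def test_energy_confined_to_band(self):
        x = synth.make_click(synth.dolphin_click_spec(), FS)
        X = np.abs(np.fft.rfft(x, 8192)) ** 2
        f = np.fft.rfftfreq(8192, 1 / FS)
        frac = X[(f >= 40e3) & (f <= 150e3)].sum() / X.sum()
        assert frac >= 0.95

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            synth.make_click(synth.dolphin_click_spec(), fs=200e3)


# ---------------------------------------------------------------------------
# multi-glint echoes

def ratio_spectrum_minima(broadcast, echo, fs, f_lo, f_hi):
    """Brute-force oracle: frequencies of local minima of
    |FFT(echo)| / |FFT(broadcast)| inside [f_lo, f_hi]."""
    n = 1 << 16
    H = np.abs(np.fft.rfft(echo, n)) / np.maximum(
        np.abs(np.fft.rfft(broadcast, n)), 1e-12)
    f = np.fft.rfftfreq(n, 1 / fs)
    sel = (f >= f_lo) & (f <= f_hi)
    Hs, fsel = H[sel], f[sel]
    mins = [fsel[i] for i in range(1, Hs.size - 1)
            if Hs[i] < Hs[i - 1] and Hs[i] <= Hs[i + 1]
            and Hs[i] < 0.3]
    return np.asarray(mins)


class TestMultiglintEcho:
    def test_single_glint_is_exact_delayed_copy(self):
        b = synth.make_fm_chirp(synth.bat_chirp_spec(), FS)
        tg = synth.GlintTargetSpec(6e-3, (0.0,), (1.0,))
        e = synth.make_multiglint_echo(b, tg, FS)
        assert np.allclose(e[:b.size], b, atol=1e-9)

    @pytest.mark.parametrize("sep_us,expected_spacing_khz", [
        (100.0, 10.0), (50.0, 20.0),
    ])
    def test_ratio_spectrum_null_spacing(self, sep_us, expected_spacing_khz):
        """Two equal glints Dt apart put nulls at (m+1/2)/Dt; oracle =
        zeros of |1 + exp(-i 2 pi f Dt)| confirmed by brute-force FFT."""
        b = synth.make_fm_chirp(synth.bat_chirp_spec(), FS)
        tg = synth.two_glint_target(6e-3, sep_us * 1e-6)
        e = synth.make_multiglint_echo(b, tg, FS)
        mins = ratio_spectrum_minima(b, e, FS, 27e3, 88e3)
        want = np.arange(0.5, 60) / (sep_us * 1e-6)
        want = want[(want >= 27e3) & (want <= 88e3)]
        for w in want:
            assert np.min(np.abs(mins - w)) < 500.0   # within an FFT bin-ish
        spac = np.diff(sorted(mins))
        assert np.median(spac) == pytest.approx(expected_spacing_khz * 1e3,
                                                rel=0.05)

    def test_50us_minima_at_odd_multiples_of_10khz(self):
        b = synth.make_click(synth.dolphin_click_spec(), FS)
        tg = synth.two_glint_target(6e-3, 50e-6)
        e = synth.make_multiglint_echo(b, tg, FS)
        mins = ratio_spectrum_minima(b, e, FS, 45e3, 145e3)
        for w in (50e3, 70e3, 90e3, 110e3, 130e3):
            assert np.min(np.abs(mins - w)) < 500.0

    def test_null_spacing_reciprocity_across_series(self):
        """Measured FFT-ratio null spacing x Dt = 1 within the FFT bin."""
        b = synth.make_click(synth.dolphin_click_spec(), FS)
        for sep_us in (26.0, 35.0, 70.0, 100.0, 200.0):
            tg = synth.two_glint_target(6e-3, sep_us * 1e-6)
            e = synth.make_multiglint_echo(b, tg, FS)
            mins = ratio_spectrum_minima(b, e, FS, 45e3, 145e3)
            if mins.size < 2:
                continue
            spacing = np.median(np.diff(sorted(mins)))
            assert spacing * sep_us * 1e-6 == pytest.approx(1.0, abs=0.05)

    def test_rms_scales_linearly_with_gain(self):
        b = synth.make_fm_chirp(synth.bat_chirp_spec(), FS)
        rms = []
        for g in (0.25, 0.5, 1.0):
            e = synth.make_multiglint_echo(
                b, synth.GlintTargetSpec(6e-3, (0.0,), (g,)), FS)
            rms.append(np.sqrt(np.mean(e ** 2)))
        assert rms[2] / rms[0] == pytest.approx(4.0, rel=1e-6)
        assert rms[2] / rms[1] == pytest.approx(2.0, rel=1e-6)

    def test_unsorted_offsets_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            synth.GlintTargetSpec(6e-3, (0.0, 1e-4, 0.5e-4),
                                  (1.0, 1.0, 1.0)).validate()


# ---------------------------------------------------------------------------
# lowpass clutter

class TestLowpassClutter:
    def test_designed_ramp_matches_fft_gain_measurement(self):
        """Oracle: direct FFT-domain gain of filtered vs raw echo."""
        rng = np.random.default_rng(7)
        x = rng.standard_normal(4096)
        prof = (60.0, 2.0, 30.0)
        y = synth.apply_lowpass_clutter(x, prof, FS)
        gain = np.abs(np.fft.rfft(y)) / np.maximum(np.abs(np.fft.rfft(x)),
                                                   1e-12)
        f = np.fft.rfftfreq(4096, 1 / FS) / 1e3
        want_db = np.clip((f - 60.0) * 2.0, 0.0, 30.0)
        got_db = -20 * np.log10(np.maximum(gain, 1e-12))
        sel = (f > 5) & (f < 240)
        assert np.max(np.abs(got_db[sel] - want_db[sel])) < 1.0

    def test_below_cutoff_unchanged_within_half_db(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal(4096)
        y = synth.apply_lowpass_clutter(x, (80.0, 2.0, 40.0), FS)
        gain = np.abs(np.fft.rfft(y)) / np.maximum(np.abs(np.fft.rfft(x)),
                                                   1e-12)
        f = np.fft.rfftfreq(4096, 1 / FS) / 1e3
        sel = (f > 1) & (f < 79)
        assert np.max(np.abs(20 * np.log10(gain[sel]))) < 0.5

    def test_zero_max_attenuation_is_identity(self):
        x = np.sin(2 * np.pi * 40e3 * np.arange(2048) / FS)
        y = synth.apply_lowpass_clutter(x, (60.0, 2.0, 0.0), FS)
        assert np.allclose(x, y, atol=1e-10)


# ---------------------------------------------------------------------------
# sequence assembly + annotations

class TestAssembleSequence:
    def test_empty_target_list_contains_broadcast_only(self):
        b = synth.make_fm_chirp(synth.bat_chirp_spec(), FS)
        seq = synth.assemble_sequence(b, [], fs=FS)
        i0 = int(round(seq.broadcast_start_s * FS))
        assert np.allclose(seq.samples[i0:i0 + b.size], b)
        assert np.allclose(np.delete(seq.samples,
                                     np.arange(i0, i0 + b.size)), 0.0)

    def test_overlapping_echoes_rejected(self):
        b = synth.make_fm_chirp(synth.bat_chirp_spec(), FS)
        tg = [synth.two_glint_target(5e-3, 1e-4),
              synth.two_glint_target(7e-3, 1e-4)]
        with pytest.raises(ValueError, match="separation"):
            synth.assemble_sequence(b, tg, fs=FS)

    def test_echo_into_broadcast_rejected(self):
        b = synth.make_fm_chirp(synth.bat_chirp_spec(), FS)
        with pytest.raises(ValueError, match="overlaps"):
            synth.assemble_sequence(b, [synth.two_glint_target(1e-3, 1e-4)],
                                    fs=FS)

    @given(delays=st.lists(
        st.floats(min_value=5e-3, max_value=12e-3), min_size=1, max_size=3),
        seps=st.lists(st.sampled_from([26e-6, 50e-6, 1e-4, 2e-4]),
                      min_size=3, max_size=3))
    @settings(max_examples=20, deadline=None)
    def test_annotation_round_trip(self, tmp_path_factory, delays, seps):
        """Writing a sequence and reading it back returns identical
        target specifications (round-trip property)."""
        base = 5e-3
        targets = [synth.two_glint_target(base + 6e-3 * i + d * 0.0, s)
                   for i, (d, s) in enumerate(zip(delays, seps))]
        b = synth.make_click(synth.dolphin_click_spec(), FS)
        seq = synth.assemble_sequence(b, targets, fs=FS, mode="dolphin",
                                      broadcast_duration_s=50e-6)
        out = tmp_path_factory.mktemp("io") / "seq.npz"
        scat_io.write_sequence(seq, out)
        back = scat_io.read_sequence(out)
        assert back.mode == "dolphin"
        assert len(back.targets) == len(targets)
        for a, c in zip(targets, back.targets):
            assert c.range_delay_s == pytest.approx(a.range_delay_s)
            assert np.allclose(c.glint_offsets_s, a.glint_offsets_s)
            assert np.allclose(c.glint_amplitudes, a.glint_amplitudes)
        assert np.allclose(back.samples, seq.samples, atol=2e-7)

    def test_waveforms_deterministic(self):
        a = synth.make_fm_chirp(synth.bat_chirp_spec(), FS)
        b = synth.make_fm_chirp(synth.bat_chirp_spec(), FS)
        assert np.array_equal(a, b)
        ta = synth.make_multiglint_echo(a, synth.two_glint_target(6e-3, 1e-4), FS)
        tb = synth.make_multiglint_echo(b, synth.two_glint_target(6e-3, 1e-4), FS)
        assert np.array_equal(ta, tb)
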