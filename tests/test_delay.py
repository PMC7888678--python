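"""Dechirping, amplitude-latency trading, gating, range-delay estimation."""

import dataclasses

import numpy as np
import pytest

from scat import delay as D
from scat import frontend, synth
from scat.config import (ALTConfig, GateConfig, RangeDelayConfig, bat_config,
                         dolphin_config)
from scat.frontend import CrossingMap, EventWindow
from scat.model import ScatModel

FS = 500e3


def synthetic_crossing_map(bcast_times, echo_times, levels=None,
                           bcast_peaks=None, echo_peaks=None):
    """Construct a CrossingMap directly (constructed-input oracle)."""
    bcast_times = np.asarray(bcast_times, float)
    echo_times = np.asarray(echo_times, float)
    n_ch, n_lev = bcast_times.shape
    levels = (np.linspace(0.03, 0.98, n_lev) if levels is None
              else np.asarray(levels))
    events = [EventWindow("broadcast", "broadcast", 0.0, 5e-3),
              EventWindow("echo0", "echo", 5e-3, 12e-3, None)]
    times = np.stack([bcast_times, echo_times])
    peaks = np.stack([
        np.ones(n_ch) if bcast_peaks is None else np.asarray(bcast_peaks),
        np.ones(n_ch) if echo_peaks is None else np.asarray(echo_peaks)])
    return CrossingMap(events=events, times_s=times, peaks=peaks,
                       levels=levels,
                       cfs_khz=np.linspace(20, 100, n_ch))


class TestLowFrequencyGate:
    def test_full_band_echo_accepted(self, worked_example):
        assert worked_example.gate_decisions["echo0"] is True

    def test_echo_highpassed_above_35khz_rejected(self):
        """Removing the 25-30 kHz band kills delay processing outright."""
        cfg = bat_config()
        chirp = synth.make_fm_chirp(synth.bat_chirp_spec(), FS)
        tg = synth.two_glint_target(6e-3, 100e-6)
        seq = synth.assemble_sequence(chirp, [tg], cfg.windows, FS)
        # high-pass the echo portion only (zero-phase FFT mask)
        x = seq.samples.copy()
        i0 = int((seq.broadcast_start_s + 5e-3) * FS)
        seg = x[i0:]
        F = np.fft.rfft(seg)
        f = np.fft.rfftfreq(seg.size, 1 / FS)
        F[f < 35e3] = 0.0
        x[i0:] = np.fft.irfft(F, seg.size)
        seq = dataclasses.replace(seq, samples=x)
        res = ScatModel(seq, config=cfg).fit()
        assert res.gate_decisions["echo0"] is False
        img = res.image_for("echo0")
        assert not img.accepted and not img.range_estimates \
            and img.glint is None

    def test_gate_band_override_matches_exhaustive_scan(self, worked_example):
        """Brute-force oracle: the decision equals an exhaustive scan of
        level-1 crossings over the configured band."""
        cmap = worked_example.crossings
        for lo, hi in ((23.0, 30.0), (25.0, 30.0), (96.0, 100.0)):
            got = D.low_frequency_gate(cmap, GateConfig(True, lo, hi))
            e = cmap.event_index("echo0")
            want = any(np.isfinite(cmap.times_s[e, c, 1])
                       for c in range(cmap.cfs_khz.size)
                       if lo <= cmap.cfs_khz[c] <= hi)
            assert got["echo0"] == want


class TestDechirp:
    def test_constructed_perturbations_recovered_exactly(self):
        """Dechirped values equal the injected differences exactly."""
        rng = np.random.default_rng(3)
        n_ch, n_lev = 8, 10
        bcast = np.sort(rng.uniform(0, 1e-3, (n_ch, n_lev)), axis=1)
        diffs = rng.uniform(5e-3, 6e-3, (n_ch, n_lev))
        cmap = synthetic_crossing_map(bcast, bcast + diffs)
        dsp = D.dechirp(cmap)
        assert np.allclose(dsp.delays_s[0], diffs, atol=1e-15)

    def test_identical_echo_gives_zero_delay(self):
        bcast = np.tile(np.linspace(1e-4, 1e-3, 10), (5, 1))
        cmap = synthetic_crossing_map(bcast, bcast.copy())
        dsp = D.dechirp(cmap)
        assert np.allclose(dsp.delays_s[0], 0.0)

    def test_missing_broadcast_cell_propagates(self):
        bcast = np.tile(np.linspace(1e-4, 1e-3, 10), (3, 1))
        bcast[1, 5:] = np.nan
        cmap = synthetic_crossing_map(bcast, bcast + 6e-3)
        dsp = D.dechirp(cmap)
        assert np.isnan(dsp.delays_s[0, 1, 5:]).all()

    def test_delayed_copy_echo_reads_6ms_everywhere(self):
        """A full-amplitude delayed replica dechirps to ~6 ms in every
        channel and level, within an interpolation step."""
        cfg = bat_config()
        chirp = synth.make_fm_chirp(synth.bat_chirp_spec(), FS)
        tg = synth.GlintTargetSpec(6e-3, (0.0,), (1.0,))
        seq = synth.assemble_sequence(chirp, [tg], cfg.windows, FS)
        _, cmap = frontend.analyze_sequence(seq, cfg)
        dsp = D.dechirp(cmap)
        d = dsp.delays_s[0][np.isfinite(dsp.delays_s[0])]
        assert np.all(np.abs(d - 6e-3) < 2.5e-6)


class TestApplyAlt:
    def _dsp(self, atten_db):
        bcast = np.tile(np.linspace(1e-4, 1e-3, 10), (4, 1))
        cmap = synthetic_crossing_map(
            bcast, bcast + 6e-3,
            echo_peaks=10 ** (-np.asarray(atten_db) / 20.0))
        return D.dechirp(cmap)

    def test_one_db_gives_25us(self):
        dsp = self._dsp([1.0, 1.0, 1.0, 1.0])
        base = dsp.delays_s.copy()
        D.apply_alt(dsp, ALTConfig())
        assert np.allclose(dsp.delays_s - base, 25e-6)

    def test_zero_db_no_shift(self):
        dsp = self._dsp([0.0, 0.0, 0.0, 0.0])
        base = dsp.delays_s.copy()
        D.apply_alt(dsp, ALTConfig())
        assert np.array_equal(dsp.delays_s, base)

    def test_12db_uniform_shift_elementwise(self):
        """Oracle: elementwise recomputation, +300 us everywhere."""
        dsp = self._dsp([12.0, 12.0, 12.0, 12.0])
        base = dsp.delays_s.copy()
        D.apply_alt(dsp, ALTConfig())
        assert np.allclose(dsp.delays_s, base + 12 * 25e-6)

    def test_negative_attenuation_clamped(self):
        dsp = self._dsp([-6.0, 0.0, 3.0, -1.0])
        base = dsp.delays_s.copy()
        D.apply_alt(dsp, ALTConfig())
        shift = (dsp.delays_s - base)[0, :, 0]
        assert np.allclose(shift, [0.0, 0.0, 75e-6, 0.0])

    def test_alt_linearity(self):
        """Doubling the attenuation doubles the augmentation exactly."""
        d1 = self._dsp([4.0] * 4)
        d2 = self._dsp([8.0] * 4)
        b1, b2 = d1.delays_s.copy(), d2.delays_s.copy()
        D.apply_alt(d1, ALTConfig())
        D.apply_alt(d2, ALTConfig())
        assert np.allclose(d2.delays_s - b2, 2 * (d1.delays_s - b1))

    def test_missing_cells_stay_missing(self):
        dsp = self._dsp([6.0] * 4)
        dsp.delays_s[0, 2, :] = np.nan
        D.apply_alt(dsp, ALTConfig())
        assert np.isnan(dsp.delays_s[0, 2]).all()


class TestEstimateRangeDelay:
    def test_all_equal_sample_returns_value_exactly(self):
        bcast = np.tile(np.linspace(1e-4, 1e-3, 10), (8, 1))
        cmap = synthetic_crossing_map(bcast, bcast + 6.1234e-3)
        dsp = D.dechirp(cmap)
        est = D.estimate_range_delay(dsp, "echo0", RangeDelayConfig())
        assert est.t_s == pytest.approx(6.1234e-3, abs=1e-12)
        assert est.reliable

    def test_leading_edge_matches_sorted_scan_oracle(self):
        """Skewed mixture: the left cluster's boundary is found by a
        direct scan of the sorted sample (oracle), and the estimator
        agrees."""
        rng = np.random.default_rng(11)
        left = 6e-3 + rng.uniform(0, 20e-6, 40)       # tight left cluster
        tail = 6.3e-3 + rng.uniform(0, 1e-3, 60)      # ALT-style tail
        vals = np.concatenate([left, tail])
        bcast = np.tile(np.linspace(1e-4, 1e-3, 1), (100, 1))
        cmap = synthetic_crossing_map(bcast, bcast + vals[:, None],
                                      levels=[0.03])
        dsp = D.dechirp(cmap)
        rd = RangeDelayConfig()
        est = D.estimate_range_delay(dsp, "echo0", rd)
        assert est.t_s == pytest.approx(np.min(left), abs=rd.bin_width_s)

    def test_isolated_early_outlier_skipped(self):
        vals = np.concatenate([[5.2e-3], np.full(50, 6e-3)])
        bcast = np.tile([1e-4], (51, 1))
        cmap = synthetic_crossing_map(bcast, bcast + vals[:, None],
                                      levels=[0.03])
        est = D.estimate_range_delay(D.dechirp(cmap), "echo0",
                                     RangeDelayConfig())
        assert est.t_s == pytest.approx(6e-3, abs=2e-6)

    def test_too_few_channels_flagged_unreliable(self):
        bcast = np.tile([1e-4], (3, 1))
        cmap = synthetic_crossing_map(bcast, bcast + 6e-3, levels=[0.03])
        est = D.estimate_range_delay(D.dechirp(cmap), "echo0",
                                     RangeDelayConfig())
        assert not est.reliable

    def test_t_not_after_histogram_mode(self, worked_example):
        est = worked_example.images[0].range_estimates[0]
        mode_bin = np.argmax(est.hist_counts)
        assert est.t_s <= est.hist_edges_s[mode_bin + 1]

    def test_level_pooling_modes(self, worked_example):
        dsp = worked_example.dechirped
        t1 = D.estimate_range_delay(dsp, "echo0",
                                    RangeDelayConfig(level_pool="first"))
        tall = D.estimate_range_delay(dsp, "echo0",
                                      RangeDelayConfig(level_pool="all"))
        assert abs(t1.t_s - tall.t_s) < 0.2e-3
        assert tall.hist_counts.sum() >= t1.hist_counts.sum()

    def test_shift_equivariance(self):
        """Delaying the whole echo by delta shifts t by delta (one bin)."""
        cfg = bat_config()
        chirp = synth.make_fm_chirp(synth.bat_chirp_spec(), FS)
        ts = []
        for d in (6e-3, 7.5e-3):
            seq = synth.assemble_sequence(
                chirp, [synth.two_glint_target(d, 100e-6)], cfg.windows, FS)
            res = ScatModel(seq, config=cfg).fit()
            ts.append(res.images[0].range_estimates[0].t_s)
        assert (ts[1] - ts[0]) == pytest.approx(1.5e-3, abs=4e-6)

    def test_range_ordering_invariant_under_attenuation(self):
        """Two echoes at d1 < d2 with unequal attenuations (<= 20 dB)
        keep their estimated order."""
        cfg = dolphin_config()
        click = synth.make_click(synth.dolphin_click_spec(), FS)
        t1 = synth.GlintTargetSpec(6e-3, (0.0,), (1.0,), attenuation_db=18.0)
        t2 = synth.GlintTargetSpec(12e-3, (0.0,), (1.0,), attenuation_db=0.0)
        seq = synth.assemble_sequence(click, [t1, t2], cfg.windows, FS,
                                      mode="dolphin",
                                      broadcast_duration_s=50e-6)
        res = ScatModel(seq, config=cfg).fit()
        est1 = res.image_for("echo0").range_estimates[0]
        est2 = res.image_for("echo1").range_estimates[0]
        assert est1.t_s < est2.t_s


class TestSeparateGlints:
    def test_single_glint_yields_one_estimate(self, dolphin_series):
        img = dolphin_series.image_for("echo5")      # 100 us, interference
        assert len(img.range_estimates) == 1

    @pytest.mark.parametrize("eid,sep_us", [("echo8", 500.0),
                                            ("echo9", 700.0)])
    def test_widely_separated_clicks_give_two_estimates(self, dolphin_series,
                                                        eid, sep_us):
        """Ground-truth oracle: the two estimates differ by the known
        glint separation (within the second crossing's smaller natural
        retardation, ~15 us)."""
        img = dolphin_series.image_for(eid)
        assert len(img.range_estimates) == 2
        diff = (img.range_estimates[1].t_s - img.range_estimates[0].t_s)
        assert diff * 1e6 == pytest.approx(sep_us, abs=20.0)
        assert img.glint is None

    def test_300us_pair_separates_with_no_interference_estimate(
            self, dolphin_series):
        img = dolphin_series.image_for("echo7")
        assert len(img.range_estimates) == 2
        assert img.glint is None
        diff = img.range_estimates[1].t_s - img.range_estimates[0].t_s
        assert diff * 1e6 == pytest.approx(300.0, abs=20.0)
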