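"""Auditory front end: gammatone filterbank, transduction, thresholding.

The receiver converts a waveform into the model's working representation
in four stages:

1. ``run_filterbank`` -- a bank of order-4 gammatone bandpass filters
   (bat: 161 channels, 20-100 kHz at 0.5 kHz; dolphin: 121 channels,
   30-150 kHz at 1 kHz; ERB 4 kHz throughout).  Filters are realised as
   truncated FIR impulse responses, normalised to unit gain at their
   centre frequency, and aligned by the analytic envelope-peak group
   delay (identical across channels because the ERB is constant) so that
   absolute event timing is unbiased.
2. ``transduce`` -- half-wave rectification followed by a causal
   2nd-order Butterworth lowpass at 10 kHz.  The smoother is applied
   forward-only: latency is the model's computational currency and
   zero-phase filtering would erase the latency physics.  The high
   cutoff deliberately lets cycle-by-cycle structure through at low
   centre frequencies while high-frequency channels yield smooth
   envelopes.
3. ``normalize_gain`` -- the broadcast portion is scaled to full scale
   1.0 (the model's stand-in for the animal's vocalisation-synchronised
   gain control), so echoes sit lower on the threshold ladder.
4. ``detect_crossings`` -- per event window, channel and threshold
   level, the first upward crossing time, linearly interpolated between
   samples; thresholds never crossed are recorded as NaN (MISSING).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .config import (FilterbankConfig, ScatConfig, ThresholdConfig,
                     TransductionConfig)
from .synth import EchoSequence

__all__ = [
    "EventWindow", "Cochleagram", "CrossingMap",
    "gammatone_fir", "run_filterbank", "transduce",
    "normalize_gain", "detect_crossings", "event_windows",
]

#: bandwidth parameter of an order-4 gammatone expressed through its ERB
_ERB_TO_B = 1.019


@dataclass(frozen=True)
class EventWindow:
    """A [start, stop) epoch of the sequence holding one acoustic event."""

    event_id: str
    kind: str                 # "broadcast" | "echo"
    start_s: float
    stop_s: float
    nominal_delay_s: float | None = None   # ground-truth annotation (echoes)


@dataclass
class Cochleagram:
    """Per-channel smoothed half-wave envelopes (n_channels x n_samples)."""

    env: np.ndarray
    fs: float
    cfs_khz: np.ndarray
    full_scale: float | None = None       # set by normalize_gain

    @property
    def n_channels(self) -> int:
        return self.env.shape[0]

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.env.shape[1]) / self.fs


@dataclass
class CrossingMap:
    """First threshold-crossing times per (event, channel, level).

    ``times_s[e, c, l]`` is the interpolated first upward crossing of
    level ``l`` in channel ``c`` within event ``e``'s window, or NaN if
    the threshold is never crossed.  ``peaks[e, c]`` is the envelope peak
    in that window (full-scale units).
    """

    events: list[EventWindow]
    times_s: np.ndarray        # (n_events, n_channels, n_levels), NaN=missing
    peaks: np.ndarray          # (n_events, n_channels)
    levels: np.ndarray         # threshold fractions of full scale
    cfs_khz: np.ndarray

    @property
    def n_levels(self) -> int:
        return self.levels.size

    def event_index(self, event_id: str) -> int:
        for i, ev in enumerate(self.events):
            if ev.event_id == event_id:
                return i
        raise KeyError(event_id)

    @property
    def echo_events(self) -> list[EventWindow]:
        return [ev for ev in self.events if ev.kind == "echo"]

    def max_level_crossed(self, event_idx: int) -> np.ndarray:
        """Highest 1-based level crossed per channel (0 = none)."""
        return np.sum(np.isfinite(self.times_s[event_idx]), axis=1)


# ---------------------------------------------------------------------------
# filterbank

def gammatone_fir(cf_hz: float, erb_hz: float, fs: float,
                  order: int = 4, dur_s: float = 1.5e-3
                  ) -> tuple[np.ndarray, int]:
    """Truncated gammatone impulse response, unit gain at ``cf``.

    Returns ``(h, n_peak)`` where ``n_peak`` is the sample index of the
    envelope maximum t_peak = (order-1)/(2 pi b); convolution outputs are
    advanced by ``n_peak`` to compensate the filter's group delay.
    """
    b = _ERB_TO_B * erb_hz
    n = int(round(dur_s * fs))
    t = np.arange(n) / fs
    env = t ** (order - 1) * np.exp(-2 * np.pi * b * t)
    h = env * np.cos(2 * np.pi * cf_hz * t)
    gain = np.abs(np.sum(h * np.exp(-2j * np.pi * cf_hz * t)))
    h /= gain
    t_peak = (order - 1) / (2 * np.pi * b)
    return h, int(round(t_peak * fs))


def run_filterbank(waveform: np.ndarray, fb: FilterbankConfig,
                   fs: float) -> np.ndarray:
    """Filter a waveform through the gammatone bank.

    Returns an (n_channels, n_samples) array of band signals, aligned so
    that each channel's envelope peak to an impulse falls at the impulse
    time (group-delay compensated).
    """
    fb.validate()
    cfs = fb.center_frequencies_khz * 1e3
    if fs < 2 * (cfs[-1] + fb.erb_khz * 1e3):
        raise ValueError(
            f"sample rate {fs:g} Hz too low for channel at {cfs[-1]:g} Hz"
        )
    x = np.asarray(waveform, float)
    n = x.size
    hs = []
    n_peak = 0
    for cf in cfs:
        h, n_peak = gammatone_fir(cf, fb.erb_khz * 1e3, fs, fb.order)
        hs.append(h)
    H = np.asarray(hs)
    out = signal.fftconvolve(H, x[None, :], mode="full", axes=1)
    return out[:, n_peak:n_peak + n]


def filterbank_response(fb: FilterbankConfig, fs: float,
                        freqs_hz: np.ndarray) -> np.ndarray:
    """Magnitude response of every channel at the given frequencies
    (n_channels x n_freqs); channels have unit gain at their own cf."""
    cfs = fb.center_frequencies_khz * 1e3
    resp = np.empty((cfs.size, np.size(freqs_hz)))
    t = None
    for i, cf in enumerate(cfs):
        h, _ = gammatone_fir(cf, fb.erb_khz * 1e3, fs, fb.order)
        if t is None:
            t = np.arange(h.size) / fs
        resp[i] = np.abs(np.exp(-2j * np.pi * np.outer(freqs_hz, t)) @ h)
    return resp


# ---------------------------------------------------------------------------
# transduction

def transduce(bands: np.ndarray, tc: TransductionConfig,
              fs: float, cfs_khz: np.ndarray) -> Cochleagram:
    """Half-wave rectify and causally lowpass-smooth each band signal."""
    rect = np.maximum(bands, 0.0)
    sos = signal.butter(tc.lowpass_order, tc.lowpass_cutoff_hz,
                        fs=fs, output="sos")
    env = signal.sosfilt(sos, rect, axis=1)
    np.maximum(env, 0.0, out=env)   # clamp filter undershoot
    return Cochleagram(env=env, fs=fs, cfs_khz=np.asarray(cfs_khz, float))


def normalize_gain(coch: Cochleagram, broadcast_window: tuple[float, float]
                   ) -> Cochleagram:
    """Scale so the broadcast portion's global maximum is 1.0 full scale."""
    i0 = max(0, int(broadcast_window[0] * coch.fs))
    i1 = min(coch.env.shape[1], int(np.ceil(broadcast_window[1] * coch.fs)))
    peak = float(np.max(coch.env[:, i0:i1])) if i1 > i0 else 0.0
    if peak <= 0.0:
        raise ValueError("silent broadcast window: cannot set full scale")
    coch.env = coch.env / peak
    coch.full_scale = 1.0
    return coch


# ---------------------------------------------------------------------------
# event windows + threshold crossings

def event_windows(seq: EchoSequence) -> list[EventWindow]:
    """Partition a sequence into broadcast and echo epochs.

    Windows open ``pre_margin`` before the nominal event time and close
    after the signal duration plus ``post_margin`` (to catch crossings
    retarded by weak amplitudes), clipped so neighbours never overlap.
    """
    wp = seq.window_params
    dur = seq.broadcast_duration_s
    raw: list[tuple[str, str, float, float | None]] = [
        ("broadcast", "broadcast", seq.broadcast_start_s, None)
    ]
    for i, tg in enumerate(seq.targets):
        raw.append((f"echo{i}", "echo",
                    seq.broadcast_start_s + tg.range_delay_s,
                    tg.range_delay_s))
    raw.sort(key=lambda r: r[2])
    windows: list[EventWindow] = []
    for j, (eid, kind, t0, nominal) in enumerate(raw):
        start = max(0.0, t0 - wp.pre_margin_s)
        stop = t0 + dur + wp.post_margin_s
        if j + 1 < len(raw):
            nxt = raw[j + 1][2] - wp.pre_margin_s
            stop = min(stop, nxt)
        stop = min(stop, seq.duration_s)
        if stop <= start:
            raise ValueError("overlapping event windows")
        windows.append(EventWindow(eid, kind, start, stop, nominal))
    return windows


def _first_crossings(y: np.ndarray, levels: np.ndarray, fs: float,
                     t_offset: float) -> np.ndarray:
    """First upward crossing time of each level in one envelope segment.

    Uses the running maximum: its first passage above a level is exactly
    the envelope's first upward crossing, and because the running max is
    sorted the search is a binary search.  Crossing times are linearly
    interpolated between the bracketing samples.
    """
    out = np.full(levels.size, np.nan)
    if y.size < 2:
        return out
    cmax = np.maximum.accumulate(y)
    idx = np.searchsorted(cmax, levels, side="left")
    for k, i in enumerate(idx):
        if i >= y.size or i == 0:
            if i == 0 and y[0] >= levels[k]:
                out[k] = t_offset
            continue
        y0, y1 = y[i - 1], y[i]
        frac = 0.0 if y1 == y0 else (levels[k] - y0) / (y1 - y0)
        out[k] = t_offset + (i - 1 + frac) / fs
    return out


def detect_crossings(coch: Cochleagram, th: ThresholdConfig,
                     windows: list[EventWindow]) -> CrossingMap:
    """First-crossing map over (event, channel, level).

    Requires a gain-normalised cochleagram (thresholds are fractions of
    full scale).  Within one channel and event, crossing times are
    non-decreasing with level by construction.
    """
    if coch.full_scale is None:
        raise ValueError("cochleagram must be gain-normalised first")
    starts = sorted((w.start_s, w.stop_s) for w in windows)
    for (a0, a1), (b0, b1) in zip(starts, starts[1:]):
        if b0 < a1 - 1e-12:
            raise ValueError("overlapping event windows")
    levels = th.level_fractions * coch.full_scale
    n_ev, n_ch = len(windows), coch.n_channels
    times = np.full((n_ev, n_ch, levels.size), np.nan)
    peaks = np.zeros((n_ev, n_ch))
    for e, w in enumerate(windows):
        i0 = max(0, int(round(w.start_s * coch.fs)))
        i1 = min(coch.env.shape[1], int(round(w.stop_s * coch.fs)))
        seg = coch.env[:, i0:i1]
        peaks[e] = seg.max(axis=1)
        t_off = i0 / coch.fs
        for c in range(n_ch):
            times[e, c] = _first_crossings(seg[c], levels, coch.fs, t_off)
    return CrossingMap(events=list(windows), times_s=times, peaks=peaks,
                       levels=th.level_fractions.copy(),
                       cfs_khz=coch.cfs_khz.copy())


def analyze_sequence(seq: EchoSequence, cfg: ScatConfig
                     ) -> tuple[Cochleagram, CrossingMap]:
    """Convenience: full front end on an annotated sequence."""
    cfg.validate()
    bands = run_filterbank(seq.samples, cfg.filterbank, seq.fs)
    coch = transduce(bands, cfg.transduction, seq.fs,
                     cfg.filterbank.center_frequencies_khz)
    windows = event_windows(seq)
    bw = next(w for w in windows if w.kind == "broadcast")
    normalize_gain(coch, (bw.start_s, bw.stop_s))
    cmap = detect_crossings(coch, cfg.thresholds, windows)
    return coch, cmap
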