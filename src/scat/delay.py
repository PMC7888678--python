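"""Range-delay estimation: dechirping, amplitude-latency trading, gating.

The crossing map is re-referenced to the broadcast: in every channel and
at every threshold level, the echo's crossing time minus the broadcast's
crossing time in the *same* channel and level is the channel's delay
estimate.  This removes the FM sweep's time-frequency slope ("dechirps"
the representation): a flat single-glint echo maps to a vertical line at
its true delay.

Amplitude-latency trading (ALT) then augments each channel's delay by
25 us per dB of echo attenuation relative to the broadcast in that
channel, transposing the echo's spectral profile into a timing profile.
The range delay t is read from the *leading edge* of the across-channel
delay histogram, because ALT skews the histogram only towards longer
delays; echoes lacking the lowest broadcast frequencies are rejected
outright by the low-frequency gate before any estimate is formed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ALTConfig, GateConfig, RangeDelayConfig, ScatConfig
from .frontend import Cochleagram, CrossingMap, EventWindow

__all__ = [
    "DechirpedSpectrogram", "RangeDelayEstimate",
    "low_frequency_gate", "dechirp", "apply_alt",
    "estimate_range_delay", "resolve_separate_glints",
]


@dataclass
class DechirpedSpectrogram:
    """Per (echo event, channel, level) delay re broadcast, seconds.

    ``delays_s[e, c, l]`` = echo crossing - broadcast crossing (NaN where
    either is missing), plus the ALT augmentation once ``apply_alt`` has
    run (``alt_applied``).  ``attenuation_db[e, c]`` is the per-channel
    echo attenuation re the broadcast envelope peak, floored at 0 dB.
    """

    echo_events: list[EventWindow]
    delays_s: np.ndarray          # (n_echoes, n_channels, n_levels)
    attenuation_db: np.ndarray    # (n_echoes, n_channels)
    cfs_khz: np.ndarray
    levels: np.ndarray
    alt_applied: bool = False


@dataclass
class RangeDelayEstimate:
    """Leading-edge range delay plus the supporting histogram."""

    event_id: str
    t_s: float
    n_channels: int
    reliable: bool
    hist_counts: np.ndarray
    hist_edges_s: np.ndarray
    nominal_delay_s: float | None = None

    @property
    def t_ms(self) -> float:
        return self.t_s * 1e3


def low_frequency_gate(cmap: CrossingMap, gate: GateConfig) -> dict[str, bool]:
    """Accept/reject each echo on low-frequency presence.

    An echo is rejected iff no crossing of the gate level (default #2)
    exists in any channel of the gate band (default 25-30 kHz, the
    lowest frequencies of the bat broadcast).  Rejected echoes produce
    no delay or glint output.
    """
    decisions: dict[str, bool] = {}
    in_band = ((cmap.cfs_khz >= gate.band_lo_khz)
               & (cmap.cfs_khz <= gate.band_hi_khz))
    lvl = max(0, gate.level - 1)
    for e, ev in enumerate(cmap.events):
        if ev.kind != "echo":
            continue
        if not gate.enabled:
            decisions[ev.event_id] = True
            continue
        times = cmap.times_s[e, :, lvl]
        decisions[ev.event_id] = bool(np.any(np.isfinite(times[in_band])))
    return decisions


def dechirp(cmap: CrossingMap) -> DechirpedSpectrogram:
    """Re-reference echo crossings to the broadcast, channel by channel.

    Processing iterates channels from the lowest frequency upward.  Cells
    where the broadcast never crossed the level are MISSING.
    """
    b = cmap.event_index("broadcast")
    bcast = cmap.times_s[b]                       # (n_ch, n_lev)
    echoes = [ev for ev in cmap.events if ev.kind == "echo"]
    n_ch, n_lev = bcast.shape
    delays = np.full((len(echoes), n_ch, n_lev), np.nan)
    atten = np.zeros((len(echoes), n_ch))
    bpk = cmap.peaks[b]
    for i, ev in enumerate(echoes):
        e = cmap.event_index(ev.event_id)
        delays[i] = cmap.times_s[e] - bcast
        with np.errstate(divide="ignore", invalid="ignore"):
            a = 20.0 * np.log10(bpk / cmap.peaks[e])
        atten[i] = np.where(np.isfinite(a), np.maximum(a, 0.0), np.inf)
    return DechirpedSpectrogram(echo_events=echoes, delays_s=delays,
                                attenuation_db=atten,
                                cfs_khz=cmap.cfs_khz.copy(),
                                levels=cmap.levels.copy())


def apply_alt(dsp: DechirpedSpectrogram, alt: ALTConfig
              ) -> DechirpedSpectrogram:
    """Augment each cell's delay by coefficient x attenuation(channel).

    Attenuation is measured from the per-channel envelope peaks inside
    the event windows and floored at 0 dB (an echo louder than the
    broadcast in a channel is not advanced).  MISSING cells stay missing.
    """
    alt.validate()
    if dsp.alt_applied:
        return dsp
    if alt.enabled:
        shift = alt.coefficient_us_per_db * 1e-6 * dsp.attenuation_db
        shift = np.where(np.isfinite(shift), shift, 0.0)
        dsp.delays_s = dsp.delays_s + shift[:, :, None]
    dsp.alt_applied = True
    return dsp


def _leading_edge(values_s: np.ndarray, bin_width_s: float,
                  fraction: float) -> tuple[float, np.ndarray, np.ndarray]:
    """Leading edge of a delay sample: left boundary of the earliest
    contiguous histogram cluster that holds at least ``fraction`` of the
    total mass on its own (isolated early outliers are skipped; the long
    ALT tail is discounted without deleting entries).

    Returns (t, counts, edges); t is the smallest delay value inside the
    selected cluster, so a degenerate all-equal sample returns that value
    exactly.
    """
    v = np.sort(values_s)
    lo = np.floor(v[0] / bin_width_s) * bin_width_s
    hi = np.ceil(v[-1] / bin_width_s) * bin_width_s + bin_width_s
    edges = np.arange(lo, hi + bin_width_s / 2, bin_width_s)
    counts, _ = np.histogram(v, bins=edges)
    target = fraction * v.size
    occupied = counts > 0
    i = 0
    while i < counts.size:
        if not occupied[i]:
            i += 1
            continue
        j = i
        while j < counts.size and occupied[j]:
            j += 1
        if counts[i:j].sum() >= target:
            in_cluster = v[(v >= edges[i]) & (v < edges[j])]
            return float(in_cluster[0]), counts, edges
        i = j
    return float(v[0]), counts, edges


def estimate_range_delay(dsp: DechirpedSpectrogram, event_id: str,
                         rd: RangeDelayConfig) -> RangeDelayEstimate:
    """Leading-edge range delay for one echo event.

    The histogram pools all non-MISSING delays at the configured level
    set (default: level #1 only -- the earliest, least ALT-biased
    crossings; the long ALT tails are discounted by the leading-edge
    rule rather than by deleting entries).
    """
    idx = next(i for i, ev in enumerate(dsp.echo_events)
               if ev.event_id == event_id)
    ev = dsp.echo_events[idx]
    if rd.level_pool == "first":
        vals = dsp.delays_s[idx, :, 0]
    elif rd.level_pool == "all":
        vals = dsp.delays_s[idx].ravel()
    else:
        raise ValueError(f"unknown level pool {rd.level_pool!r}")
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return RangeDelayEstimate(event_id, np.nan, 0, False,
                                  np.zeros(0), np.zeros(1),
                                  ev.nominal_delay_s)
    t, counts, edges = _leading_edge(vals, rd.bin_width_s,
                                     rd.leading_edge_fraction)
    n_ch = int(np.sum(np.isfinite(dsp.delays_s[idx, :, 0])))
    return RangeDelayEstimate(event_id, t, n_ch, n_ch >= rd.min_channels,
                              counts, edges, ev.nominal_delay_s)


#: cutoff of the event-segmentation smoother (kills cycle ripple of the
#: lowest channels, preserves inter-glint valleys wider than ~150 us)
SEGMENTATION_CUTOFF_HZ = 4000.0


def _smooth_for_segmentation(env: np.ndarray, fs: float,
                             cutoff_hz: float = SEGMENTATION_CUTOFF_HZ
                             ) -> np.ndarray:
    """Heavily smoothed copy of the envelopes used only to *segment*
    events in time (cycle-by-cycle ripple of the low-frequency channels
    is removed; the valley between well-separated glint responses is
    preserved).  Timing always comes from the standard representation."""
    from scipy import signal
    sos = signal.butter(2, cutoff_hz, fs=fs, output="sos")
    sm = signal.sosfilt(sos, env, axis=-1)
    return np.maximum(sm, 0.0)


def _second_event(seg_sm: np.ndarray, seg: np.ndarray, levels: np.ndarray,
                  bcast_times: np.ndarray, fs: float, t_offset: float,
                  dead_time_s: float, rebound: float = 0.25,
                  valley_ratio: float = 0.5) -> tuple[float, float]:
    """Detect and time a second glint event in one channel's window.

    Segmentation: the smoothed envelope must show two peaks at least one
    integration time apart, the second at least ``rebound`` of the first,
    with the valley between them below ``valley_ratio`` of the smaller
    peak.  Timing: the first upward crossing, after the valley, of the
    lowest threshold level that clears the valley, dechirped against the
    broadcast's crossing at the same level.

    Returns ``(delay, lag)`` = (second-event time minus broadcast
    crossing, second-event time minus first-peak time), or NaNs.
    """
    from scipy import signal as _sig
    dist = max(1, int(round(dead_time_s * fs)))
    peaks, _ = _sig.find_peaks(seg_sm, distance=dist)
    if peaks.size < 2:
        return np.nan, np.nan
    h_glob = float(seg_sm[peaks].max())
    # the main event is the *first* significant peak; a later peak that
    # happens to edge it out is still the second event
    sig_peaks = peaks[seg_sm[peaks] >= rebound * h_glob]
    p_main = int(sig_peaks[0])
    h_main = seg_sm[p_main]
    for p2 in sig_peaks[1:]:
        h2 = seg_sm[p2]
        if h2 < rebound * h_main:
            continue
        if p2 - p_main < dist:
            continue
        v_idx = p_main + int(np.argmin(seg_sm[p_main:p2 + 1]))
        v = seg_sm[v_idx]
        if v > valley_ratio * min(h_main, h2):
            continue
        # map the valley back to the unsmoothed envelope: compensate the
        # segmentation smoother's low-frequency group delay
        gd = int(round(np.sqrt(2.0) / (2 * np.pi * SEGMENTATION_CUTOFF_HZ)
                       * fs))
        v_idx = max(p_main + 1, v_idx - gd)
        # timing: lowest level above the valley, crossed on the re-rise
        for l, level in enumerate(levels):
            if level <= 1.2 * v or not np.isfinite(bcast_times[l]):
                continue
            y = seg[v_idx:]
            up = np.nonzero((y[1:] >= level) & (y[:-1] < level))[0]
            if up.size == 0:
                break
            i = up[0]
            y0, y1 = y[i], y[i + 1]
            frac = 0.0 if y1 == y0 else (level - y0) / (y1 - y0)
            t2 = t_offset + (v_idx + i + frac) / fs
            return t2 - bcast_times[l], (v_idx + i - p_main) / fs
        break
    return np.nan, np.nan


def resolve_separate_glints(coch: Cochleagram, cmap: CrossingMap,
                            cfg: ScatConfig) -> dict[str, list[RangeDelayEstimate]]:
    """Detect widely separated glints as *separate* range-delay events.

    Glints farther apart than the integration time no longer interfere
    spectrally; instead the channel envelopes rise twice.  Each echo
    window is segmented on a smoothed envelope copy (two peaks at least
    one integration time apart with a clear valley); the second event is
    then timed by the first threshold crossing after the valley -- the
    shortened sub-window needed to capture the second glint's crossing --
    and dechirped against the broadcast at the matching level.
    Candidates whose lag matches a second peak the broadcast itself
    shows in that channel (e.g. a later harmonic sweeping through the
    same band) are discarded: they are structure of the signal, not of
    the target.  If enough channels agree, a second leading-edge
    estimate is emitted.  Returns, per echo event, one or two estimates.
    """
    b = cmap.event_index("broadcast")
    bev = cmap.events[b]
    levels = cmap.levels * (coch.full_scale or 1.0)
    rd = cfg.range_delay
    env_sm = _smooth_for_segmentation(coch.env, coch.fs)
    bi0 = max(0, int(round(bev.start_s * coch.fs)))
    bi1 = min(coch.env.shape[1], int(round(bev.stop_s * coch.fs)))
    bcast_lag = np.full(coch.n_channels, np.nan)
    for c in range(coch.n_channels):
        _, bcast_lag[c] = _second_event(
            env_sm[c, bi0:bi1], coch.env[c, bi0:bi1], levels,
            cmap.times_s[b, c], coch.fs, bi0 / coch.fs,
            cfg.integration_time_s)
    out: dict[str, list[RangeDelayEstimate]] = {}
    for e, ev in enumerate(cmap.events):
        if ev.kind != "echo":
            continue
        i0 = max(0, int(round(ev.start_s * coch.fs)))
        i1 = min(coch.env.shape[1], int(round(ev.stop_s * coch.fs)))
        # the second event's crossing is subject to amplitude-latency
        # trading like any other; same per-channel attenuation reference
        with np.errstate(divide="ignore", invalid="ignore"):
            atten = 20.0 * np.log10(cmap.peaks[b] / cmap.peaks[e])
        atten = np.where(np.isfinite(atten), np.maximum(atten, 0.0), 0.0)
        alt_shift = (cfg.alt.coefficient_us_per_db * 1e-6 * atten
                     if cfg.alt.enabled else np.zeros_like(atten))
        second = np.full(coch.n_channels, np.nan)
        for c in range(coch.n_channels):
            if not np.isfinite(cmap.times_s[e, c, 0]):
                continue
            d2, lag = _second_event(
                env_sm[c, i0:i1], coch.env[c, i0:i1], levels,
                cmap.times_s[b, c], coch.fs, i0 / coch.fs,
                cfg.integration_time_s)
            if not np.isfinite(d2):
                continue
            if np.isfinite(bcast_lag[c]) and abs(lag - bcast_lag[c]) < 1.5e-4:
                continue
            second[c] = d2 + alt_shift[c]
        vals = second[np.isfinite(second)]
        primary = estimate_range_delay(dechirp_view(cmap, ev.event_id), ev.event_id, rd)
        ests = [primary]
        if vals.size >= rd.min_channels:
            t, counts, edges = _leading_edge(vals, rd.bin_width_s,
                                             rd.leading_edge_fraction)
            ests.append(RangeDelayEstimate(ev.event_id + "/glint2", t,
                                           int(vals.size), True,
                                           counts, edges, None))
        out[ev.event_id] = ests
    return out


def dechirp_view(cmap: CrossingMap, event_id: str) -> DechirpedSpectrogram:
    """Dechirped spectrogram restricted to one echo event (pre-ALT)."""
    dsp = dechirp(cmap)
    keep = [i for i, ev in enumerate(dsp.echo_events)
            if ev.event_id == event_id]
    dsp.echo_events = [dsp.echo_events[i] for i in keep]
    dsp.delays_s = dsp.delays_s[keep]
    dsp.attenuation_db = dsp.attenuation_db[keep]
    return dsp
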