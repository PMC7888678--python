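"""Glint-delay estimation from spectral interference nulls.

Two reflections Dt apart interfere to put periodic nulls in the echo
spectrum at frequency spacing Df = 1/Dt.  After dechirping, the nulls
appear in the threshold-crossing representation as

* *voids*: channel clusters where the upper threshold levels are never
  crossed although the broadcast reached them there, and
* *latency deviations*: level-1 crossings retarded (rightward of the
  across-band leading edge) by amplitude-latency trading.

``find_nulls`` turns those cues into a sparse list of null centre
frequencies.  ``run_triangular_network`` registers the frequency spacing
of adjacent nulls as coincidence "apex" points quantised to the channel
grid and aggregates them by their mode; ``invert_spacing`` converts the
apex spacings to glint delays Dt = 1/Df and accumulates the glint-delay
histogram.  A void wider than the broadest registrable single null (the
signature of lowpass clutter) is approximated by *fill-in* nulls with
all candidate spacings from the minimum resolvable up to the registrable
maximum (``fill_lowpass_void``), producing the broad plateau of spurious
glint delays that blurs -- and thereby de-weights -- clutter once the
histogram is normalised by its total image energy
(``normalize_image_energy``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import ScatConfig, TriangularNetworkConfig
from .delay import DechirpedSpectrogram, RangeDelayEstimate
from .frontend import CrossingMap

__all__ = [
    "SpectralNull", "NullSet", "Apex", "GlintDelayEstimate",
    "find_nulls", "run_triangular_network", "invert_spacing",
    "fill_lowpass_void", "normalize_image_energy",
]


@dataclass(frozen=True)
class SpectralNull:
    """One detected interference null."""

    center_khz: float
    width_khz: float
    band: int                   # harmonic band index (0 = FM1 / single band)
    max_level_crossed: int      # at the cluster centre channel
    latency_deviation_us: float  # at the flanks/centre, re leading edge
    channel_span: tuple[int, int]  # [first, last] channel index of cluster


@dataclass
class NullSet:
    """Detected nulls for one echo event, plus wide lowpass void regions."""

    event_id: str
    nulls: list[SpectralNull] = field(default_factory=list)
    #: (f_lo_khz, f_hi_khz, band) regions wider than a registrable null
    wide_regions: list[tuple[float, float, int]] = field(default_factory=list)

    @property
    def centers_khz(self) -> np.ndarray:
        return np.array([n.center_khz for n in self.nulls])


@dataclass(frozen=True)
class Apex:
    """A coincidence apex: the spacing of one adjacent null pair
    (or one fill-in candidate), quantised to the channel grid."""

    spacing_khz: float
    f_lo_khz: float
    f_hi_khz: float
    fill_in: bool = False


@dataclass
class GlintDelayEstimate:
    """Glint delays from apex spacings, raw + energy-normalised."""

    event_id: str
    apexes: list[Apex]
    aggregate_spacing_khz: float | None    # mode of real (non-fill) apexes
    primary_delay_us: float | None         # mode of the raw histogram
    dt_grid_us: np.ndarray                 # histogram support (ascending)
    counts: np.ndarray                     # raw histogram
    density: np.ndarray | None = None      # energy-normalised histogram

    @property
    def has_estimate(self) -> bool:
        return self.aggregate_spacing_khz is not None


# ---------------------------------------------------------------------------
# null detection

def _close_gaps(mask: np.ndarray, max_gap: int) -> np.ndarray:
    """Fill False runs of length <= ``max_gap`` between True runs."""
    if max_gap <= 0:
        return mask
    out = mask.copy()
    runs = _clusters(mask)
    for (a0, a1), (b0, b1) in zip(runs, runs[1:]):
        if b0 - a1 - 1 <= max_gap:
            out[a1:b0 + 1] = True
    return out


def _clusters(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs as (first, last) index pairs."""
    runs = []
    i = 0
    n = mask.size
    while i < n:
        if mask[i]:
            j = i
            while j + 1 < n and mask[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    return runs


def find_nulls(dsp: DechirpedSpectrogram, cmap: CrossingMap, event_id: str,
               cfg: ScatConfig,
               leading_edge: RangeDelayEstimate | None = None) -> NullSet:
    """Locate spectral interference nulls for one echo event.

    A channel joins a void cluster if (a) the echo's envelope peak falls
    below ``void_peak_ratio`` (default one half) of the broadcast's peak
    in that channel -- the notch keeps the echo from crossing the upper
    thresholds the broadcast reached -- or (b) its level-1 latency
    deviates rightward of the across-band leading edge by more than
    ``deviation_mad_multiple`` x the median absolute deviation (with a
    small absolute floor so a flat echo yields an empty set).  Void
    evidence is only judged where the broadcast crossed at least
    ``void_level`` thresholds (the channel must be able to express the
    upper levels at all).  Analysis
    is restricted to channels the broadcast itself excited (level-1
    support), and in bat mode FM1 and FM2 are clustered separately so no
    null straddles the harmonic seam.  Null centres are
    latency-weighted centroids of their clusters; clusters wider than
    the maximum registrable null width are recorded as wide (lowpass)
    regions instead.
    """
    nc = cfg.nulls
    net = cfg.network
    idx = next(i for i, ev in enumerate(dsp.echo_events)
               if ev.event_id == event_id)
    e = cmap.event_index(event_id)
    b = cmap.event_index("broadcast")
    cfs = dsp.cfs_khz
    n_ch = cfs.size

    echo_maxlev = np.sum(np.isfinite(cmap.times_s[e]), axis=1)
    bcast_maxlev = np.sum(np.isfinite(cmap.times_s[b]), axis=1)
    supported = bcast_maxlev >= 1

    # leading edge of the event (level-1 pool)
    if leading_edge is None:
        from .delay import estimate_range_delay
        leading_edge = estimate_range_delay(dsp, event_id, cfg.range_delay)
    t0 = leading_edge.t_s

    lvl1 = dsp.delays_s[idx, :, 0]
    dev = lvl1 - t0                                # rightward deviation
    finite = np.isfinite(dev) & supported
    if not np.any(finite):
        return NullSet(event_id=event_id)
    med = np.median(dev[finite])
    mad = np.median(np.abs(dev[finite] - med))
    thr_dev = max(nc.deviation_mad_multiple * mad, nc.deviation_floor_s)

    atten_db = dsp.attenuation_db[idx]
    depth_db = -20.0 * np.log10(nc.void_peak_ratio)
    void_a = supported & (bcast_maxlev >= nc.void_level) \
        & (atten_db > depth_db)
    void_b = supported & np.isfinite(dev) & (dev > thr_dev)
    void_missing = supported & (echo_maxlev == 0)
    void = void_a | void_b | void_missing

    # band id per channel (bat: FM1 vs FM2, split at the harmonic seam)
    if cfg.harmonic_seam_khz is not None:
        band_id = (cfs > cfg.harmonic_seam_khz).astype(int)
    else:
        band_id = np.zeros(n_ch, int)

    spacing = cfg.filterbank.spacing_khz
    nulls: list[SpectralNull] = []
    wide: list[tuple[float, float, int]] = []
    core_db = -20.0 * np.log10(nc.core_peak_ratio)
    core = (np.where(np.isfinite(atten_db), atten_db, np.inf) > core_db) \
        | (echo_maxlev == 0)
    gap_ch = int(round(nc.gap_close_khz / spacing))
    for bnd in np.unique(band_id):
        mask = void & (band_id == bnd) & supported
        mask = _close_gaps(mask, gap_ch)
        for i, j in _clusters(mask):
            if j - i + 1 < nc.min_cluster_channels:
                continue
            width = (j - i + 1) * spacing
            # centre = depth-weighted centroid (deeper attenuation sits
            # nearer the null core); missing channels count as deepest
            w = atten_db[i:j + 1].copy()
            wmax = np.max(w[np.isfinite(w)]) if np.any(np.isfinite(w)) else 1.0
            w = np.where(np.isfinite(w), w, wmax)
            w = np.clip(w - depth_db, spacing * 1e-3, None)
            center = float(np.sum(w * cfs[i:j + 1]) / np.sum(w))
            core_width = float(np.sum(core[i:j + 1])) * spacing
            if core_width > net.max_null_width_khz:
                wide.append((float(cfs[i]), float(cfs[j]), int(bnd)))
                continue
            mid = (i + j) // 2
            dev_us = (float(np.nanmax(dev[i:j + 1]) * 1e6)
                      if np.any(np.isfinite(dev[i:j + 1])) else np.inf)
            nulls.append(SpectralNull(
                center_khz=center, width_khz=width, band=int(bnd),
                max_level_crossed=int(echo_maxlev[mid]),
                latency_deviation_us=dev_us, channel_span=(i, j)))
    nulls.sort(key=lambda nl: nl.center_khz)
    return NullSet(event_id=event_id, nulls=nulls, wide_regions=wide)


# ---------------------------------------------------------------------------
# triangular coincidence network

def _quantize(spacing_khz: float, grid_khz: float) -> float:
    return max(round(spacing_khz / grid_khz), 1) * grid_khz


def run_triangular_network(nullset: NullSet, net: TriangularNetworkConfig
                           ) -> tuple[list[Apex], float | None]:
    """Register adjacent-null spacings as apex points.

    One apex per consecutive null pair *within the same harmonic band*
    (spacings straddling the seam are never formed).  Spacings are
    quantised to the channel grid and kept when inside the resolvable
    range [min spacing, base].  The aggregate Df is the mode of the apex
    spacings (the dominant apex column); ties resolve to the spacing
    closest to the raw mean.  Fewer than two nulls -> no estimate.
    """
    apexes: list[Apex] = []
    raws: list[float] = []
    for band in sorted({n.band for n in nullset.nulls}):
        ns = [n for n in nullset.nulls if n.band == band]
        for a, b in zip(ns, ns[1:]):
            raw = b.center_khz - a.center_khz
            q = _quantize(raw, net.grid_khz)
            if net.min_spacing_khz <= q <= net.base_khz:
                apexes.append(Apex(q, a.center_khz, b.center_khz))
                raws.append(raw)
    if not apexes:
        return [], None
    spacings = np.array([a.spacing_khz for a in apexes])
    uniq, cnt = np.unique(spacings, return_counts=True)
    best = uniq[cnt == cnt.max()]
    aggregate = float(best[np.argmin(np.abs(best - np.mean(raws)))])
    return apexes, aggregate


def fill_lowpass_void(nullset: NullSet, net: TriangularNetworkConfig
                      ) -> list[Apex]:
    """Approximate each wide (lowpass) void by fill-in nulls.

    The region is tiled with every candidate spacing on the channel grid
    from the minimum resolvable up to the largest registrable spacing
    that fits in the region; each candidate contributes one (uniformly
    weighted) apex, producing the broad glint-delay plateau after
    inversion.
    """
    apexes: list[Apex] = []
    for f_lo, f_hi, _band in nullset.wide_regions:
        width = f_hi - f_lo
        top = min(width, net.max_null_width_khz)
        s = _quantize(net.min_spacing_khz, net.grid_khz)
        while s <= top + 1e-9:
            if s >= net.min_spacing_khz:
                apexes.append(Apex(round(s, 6), f_lo, f_lo + s, fill_in=True))
            s += net.grid_khz
    return apexes


def invert_spacing(apexes: list[Apex], aggregate_khz: float | None,
                   net: TriangularNetworkConfig,
                   event_id: str = "") -> GlintDelayEstimate:
    """Convert apex spacings Df to glint delays Dt = 1/Df.

    The histogram accumulates *all* apexes (fill-in included) on the
    reciprocal grid between 1/base and 1/min-spacing; spacings outside
    the resolvable range are dropped.  The primary Dt is the mode of the
    raw histogram (ties resolve to the aggregate's reciprocal when
    available, else the shortest delay).
    """
    f_grid = np.arange(_quantize(net.min_spacing_khz, net.grid_khz),
                       net.base_khz + net.grid_khz / 2, net.grid_khz)
    dt_grid = 1e3 / f_grid[::-1]          # ascending us
    counts = np.zeros(dt_grid.size)
    for a in apexes:
        if not (net.min_spacing_khz <= a.spacing_khz <= net.base_khz):
            continue
        k = np.argmin(np.abs(f_grid[::-1] - a.spacing_khz))
        counts[k] += 1.0
    primary = None
    if counts.sum() > 0:
        best = np.nonzero(counts == counts.max())[0]
        if aggregate_khz is not None:
            want = 1e3 / aggregate_khz
            primary = float(dt_grid[best[np.argmin(np.abs(dt_grid[best] - want))]])
        else:
            primary = float(dt_grid[best[0]])
    return GlintDelayEstimate(event_id=event_id, apexes=list(apexes),
                              aggregate_spacing_khz=aggregate_khz,
                              primary_delay_us=primary,
                              dt_grid_us=dt_grid, counts=counts)


def normalize_image_energy(est: GlintDelayEstimate) -> GlintDelayEstimate:
    """Divide the glint-delay histogram by its total image energy (area).

    A focused echo concentrates its mass at the true Dt; a lowpass
    (clutter) echo spreads mass across fill-in delays, so after
    normalisation the clutter's value at any one delay is scaled down --
    the model's anticorrelation-style clutter rejection.  An empty
    histogram is left unchanged.
    """
    if est.counts.sum() == 0:
        est.density = est.counts.copy()
        return est
    widths = np.gradient(est.dt_grid_us)
    area = float(np.sum(est.counts * widths))
    est.density = est.counts / area
    return est
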