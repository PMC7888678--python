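"""Configuration objects for the SCAT biosonar receiver.

Every tunable of the model lives here: the gammatone filterbank grid, the
transduction (rectify + smooth) stage, the ten-level threshold ladder,
amplitude-latency trading, event windowing, null detection and the
triangular coincidence network.  Two species presets are provided:

``bat``
    big brown bat (*Eptesicus fuscus*): 161 channels, 20-100 kHz at
    0.5 kHz spacing, ERB 4 kHz, order-4 gammatone; two-harmonic FM chirps
    are analysed as separate FM1 (<=50 kHz) and FM2 (>50 kHz) bands.
``dolphin``
    bottlenose dolphin (*Tursiops truncatus*): 121 channels, 30-150 kHz at
    1 kHz spacing, ERB 4 kHz; clicks are analysed as a single band.

Times are stored in seconds internally; interfaces report ms / us.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict

import numpy as np
import yaml

#: two-way travel time per metre of target range
DELAY_PER_METRE_AIR_MS = 5.8
DELAY_PER_METRE_WATER_MS = 1.4

DEFAULT_FS = 500_000.0  # Hz


def delay_to_range_m(delay_s: float, medium: str = "air") -> float:
    """Target range (m) from two-way echo delay (5.8 ms/m in air,
    1.4 ms/m in water); also converts a glint delay into the depth of
    the target's glint profile (100 us <-> ~1.7 cm in air)."""
    per_m = {"air": DELAY_PER_METRE_AIR_MS,
             "water": DELAY_PER_METRE_WATER_MS}[medium]
    return delay_s * 1e3 / per_m


@dataclass(frozen=True)
class FilterbankConfig:
    """Gammatone filterbank layout."""

    f_lo_khz: float = 20.0
    f_hi_khz: float = 100.0
    spacing_khz: float = 0.5
    erb_khz: float = 4.0
    order: int = 4

    @property
    def center_frequencies_khz(self) -> np.ndarray:
        n = int(round((self.f_hi_khz - self.f_lo_khz) / self.spacing_khz)) + 1
        return self.f_lo_khz + self.spacing_khz * np.arange(n)

    @property
    def n_channels(self) -> int:
        return self.center_frequencies_khz.size

    def validate(self) -> None:
        cfs = self.center_frequencies_khz
        if not np.all(np.diff(cfs) > 0):
            raise ValueError("center-frequency grid must be strictly increasing")
        if self.order < 1:
            raise ValueError("gammatone order must be >= 1")


@dataclass(frozen=True)
class TransductionConfig:
    """Half-wave rectification followed by causal lowpass smoothing."""

    lowpass_cutoff_hz: float = 10_000.0
    lowpass_order: int = 2


@dataclass(frozen=True)
class ThresholdConfig:
    """Ten equally spaced threshold levels, 3% to 98% of full scale."""

    n_levels: int = 10
    start_fraction: float = 0.03
    stop_fraction: float = 0.98

    @property
    def level_fractions(self) -> np.ndarray:
        return np.linspace(self.start_fraction, self.stop_fraction, self.n_levels)

    def validate(self) -> None:
        lv = self.level_fractions
        if not np.all(np.diff(lv) > 0):
            raise ValueError("threshold levels must be strictly increasing")


@dataclass(frozen=True)
class WindowParams:
    """Event-window timing (Table-2 style signal description).

    ``broadcast_start_s`` is when the broadcast begins in the assembled
    sequence; ``echo_separation_s`` is the minimum spacing between
    successive echo events; the ``call_len_*`` values describe how long a
    single event occupies a frequency channel and size the crossing-search
    windows.
    """

    broadcast_start_s: float = 0.5e-3
    echo_separation_s: float = 5e-3
    call_len_most_s: float = 1.5e-3
    call_len_high_s: float = 1.5e-3
    call_len_special_s: float = 1.8e-3
    #: search window opens this long before the nominal event time
    pre_margin_s: float = 0.25e-3
    #: extra tail beyond signal duration to catch retarded crossings
    post_margin_s: float = 1.5e-3


@dataclass(frozen=True)
class ALTConfig:
    """Amplitude-latency trading: added latency per dB of echo attenuation."""

    coefficient_us_per_db: float = 25.0
    enabled: bool = True

    def validate(self) -> None:
        if self.coefficient_us_per_db < 0:
            raise ValueError("ALT coefficient magnitude must be >= 0 us/dB")


@dataclass(frozen=True)
class GateConfig:
    """Low-frequency gate: echoes lacking the lowest broadcast
    frequencies are rejected outright (bat mode only)."""

    enabled: bool = True
    band_lo_khz: float = 25.0
    band_hi_khz: float = 30.0
    #: the gate-band channels must cross this threshold level (1-based)
    #: for the echo to count as carrying the low frequencies; with the
    #: heavily overlapping filters, skirt leakage from higher bands can
    #: graze the lowest (3%) threshold even when the band is empty
    level: int = 2


@dataclass(frozen=True)
class RangeDelayConfig:
    """Range-delay histogram / leading-edge extraction."""

    bin_width_s: float = 2e-6          # one sample at 500 kHz
    leading_edge_fraction: float = 0.10
    min_channels: int = 5
    #: which threshold levels feed the histogram; "first" = level #1 only
    level_pool: str = "first"          # "first" | "all"


@dataclass(frozen=True)
class NullDetectionConfig:
    """Evidence thresholds for spectral-null (void) detection."""

    #: a channel is judged for void evidence only where the broadcast
    #: itself crossed at least this threshold level (1-based)
    void_level: int = 4
    #: a channel is a void if the echo's envelope peak falls below this
    #: fraction of the broadcast's peak in the same channel (null depths
    #: keep the echo from crossing thresholds above ~half broadcast scale)
    void_peak_ratio: float = 0.5
    #: ... OR its level-1 latency deviation exceeds this multiple of the
    #: across-band median absolute deviation
    deviation_mad_multiple: float = 3.0
    #: numerical floor on the deviation criterion (guards the flat-echo
    #: degenerate case where the MAD is ~0)
    deviation_floor_s: float = 10e-6
    #: gaps up to this wide (kHz) inside a void cluster are closed (a
    #: null is one connected region even if odd channels sneak above the
    #: evidence thresholds)
    gap_close_khz: float = 1.0
    #: clusters narrower than this many channels are discarded as specks
    min_cluster_channels: int = 2
    #: a cluster counts as a *wide* (lowpass-like) region only when its
    #: deep core -- channels attenuated below this fraction of the
    #: broadcast peak -- exceeds the maximum registrable null width;
    #: interference nulls have broad shallow flanks but narrow deep cores
    core_peak_ratio: float = 0.25


@dataclass(frozen=True)
class TriangularNetworkConfig:
    """Triangular coincidence network that registers adjacent-null
    frequency spacings (the apex points)."""

    base_khz: float = 80.0             # analysed bandwidth (bat)
    min_spacing_khz: float = 3.0       # minimum resolvable null spacing
    grid_khz: float = 0.5              # apex quantisation = channel spacing
    #: widest single null the tuning curves can register; wider voids are
    #: approximated by fill-in nulls with spacings up to this value
    max_null_width_khz: float = 15.0

    @property
    def delay_axis_top_us(self) -> float:
        """Shortest registrable glint delay = 1/base."""
        return 1e3 / self.base_khz

    @property
    def delay_axis_bottom_us(self) -> float:
        """Longest registrable glint delay = 1/min spacing."""
        return 1e3 / self.min_spacing_khz


@dataclass(frozen=True)
class ScatConfig:
    """Full receiver configuration (one species mode)."""

    mode: str = "bat"
    fs: float = DEFAULT_FS
    filterbank: FilterbankConfig = field(default_factory=FilterbankConfig)
    transduction: TransductionConfig = field(default_factory=TransductionConfig)
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    windows: WindowParams = field(default_factory=WindowParams)
    alt: ALTConfig = field(default_factory=ALTConfig)
    gate: GateConfig = field(default_factory=GateConfig)
    range_delay: RangeDelayConfig = field(default_factory=RangeDelayConfig)
    nulls: NullDetectionConfig = field(default_factory=NullDetectionConfig)
    network: TriangularNetworkConfig = field(default_factory=TriangularNetworkConfig)
    #: inner-ear integration time; glints closer than this merge into one
    #: spectrally rippled event, farther ones separate in time
    integration_time_s: float = 350e-6
    #: split the analysed band at this frequency (bat FM1/FM2 seam);
    #: None = single continuous band
    harmonic_seam_khz: float | None = 50.0
    #: fraction of level-1 channels that must show a second crossing for
    #: separate-glint resolution to pre-empt the interference pathway
    separation_consensus: float = 0.5
    #: minimum dwell below a threshold level before a re-crossing counts
    #: as a second event; longer than any half-cycle ripple dip of the
    #: lowest channels, far shorter than a true inter-glint silence
    separation_quiet_s: float = 50e-6

    def validate(self) -> None:
        self.filterbank.validate()
        self.thresholds.validate()
        self.alt.validate()
        nyq = self.fs / 2.0
        if self.filterbank.f_hi_khz * 1e3 + self.filterbank.erb_khz * 1e3 > nyq:
            raise ValueError(
                f"sample rate {self.fs:g} Hz too low for filterbank top "
                f"{self.filterbank.f_hi_khz:g} kHz (Nyquist {nyq:g} Hz)"
            )


def bat_config(**overrides) -> ScatConfig:
    """Big brown bat preset: 161 channels 20-100 kHz, FM1/FM2 seam at
    50 kHz, 25-30 kHz low-frequency gate, 80 kHz triangle base,
    300-350 us integration time."""
    cfg = ScatConfig(
        mode="bat",
        filterbank=FilterbankConfig(20.0, 100.0, 0.5, 4.0, 4),
        gate=GateConfig(enabled=True, band_lo_khz=25.0, band_hi_khz=30.0),
        network=TriangularNetworkConfig(base_khz=80.0, grid_khz=0.5),
        integration_time_s=350e-6,
        harmonic_seam_khz=50.0,
    )
    return replace(cfg, **overrides) if overrides else cfg


def dolphin_config(**overrides) -> ScatConfig:
    """Bottlenose dolphin preset: 121 channels 30-150 kHz at 1 kHz
    spacing, no gate or harmonic seam, 120 kHz triangle base, 250 us
    integration time."""
    cfg = ScatConfig(
        mode="dolphin",
        filterbank=FilterbankConfig(30.0, 150.0, 1.0, 4.0, 4),
        gate=GateConfig(enabled=False),
        network=TriangularNetworkConfig(base_khz=120.0, grid_khz=1.0),
        integration_time_s=250e-6,
        harmonic_seam_khz=None,
    )
    return replace(cfg, **overrides) if overrides else cfg


def config_for_mode(mode: str, **overrides) -> ScatConfig:
    if mode == "bat":
        return bat_config(**overrides)
    if mode == "dolphin":
        return dolphin_config(**overrides)
    raise ValueError(f"unknown mode {mode!r}; expected 'bat' or 'dolphin'")


# ---------------------------------------------------------------------------
# YAML serialisation (external key names mirror the model's published
# parameter table: Fs, callLenForMostFreq, ... ALT)

_YAML_KEYS = {
    "Fs": ("fs", 1.0),
    "callLenForMostFreq": ("windows.call_len_most_s", 1.0),
    "callLenForHighFreq": ("windows.call_len_high_s", 1.0),
    "callLenSpecial": ("windows.call_len_special_s", 1.0),
    "whenBrStart": ("windows.broadcast_start_s", 1.0),
    "SepbwBRand1stEchoinSmpls": ("windows.echo_separation_s", 1.0),
    "startingThPercent": ("thresholds.start_fraction", 1.0),
    "NT": ("thresholds.n_levels", 1.0),
    "ALT": ("alt.coefficient_us_per_db", -1.0),  # stored with - sign outside
}


def config_to_yaml(cfg: ScatConfig, path) -> None:
    doc = {
        "mode": cfg.mode,
        "Fs": cfg.fs,
        "callLenForMostFreq": cfg.windows.call_len_most_s,
        "callLenForHighFreq": cfg.windows.call_len_high_s,
        "callLenSpecial": cfg.windows.call_len_special_s,
        "whenBrStart": cfg.windows.broadcast_start_s,
        "SepbwBRand1stEchoinSmpls": cfg.windows.echo_separation_s,
        "startingThPercent": cfg.thresholds.start_fraction,
        "NT": cfg.thresholds.n_levels,
        "ALT": -cfg.alt.coefficient_us_per_db,
        "gate_band_khz": [cfg.gate.band_lo_khz, cfg.gate.band_hi_khz],
        "filterbank": asdict(cfg.filterbank),
        "network": asdict(cfg.network),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def config_from_yaml(path) -> ScatConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError(f"config file {path} does not contain a mapping")
    cfg = config_for_mode(doc.get("mode", "bat"))
    if "Fs" in doc:
        cfg = replace(cfg, fs=float(doc["Fs"]))
    win = cfg.windows
    win_map = {
        "callLenForMostFreq": "call_len_most_s",
        "callLenForHighFreq": "call_len_high_s",
        "callLenSpecial": "call_len_special_s",
        "whenBrStart": "broadcast_start_s",
        "SepbwBRand1stEchoinSmpls": "echo_separation_s",
    }
    win_over = {attr: float(doc[k]) for k, attr in win_map.items() if k in doc}
    if win_over:
        cfg = replace(cfg, windows=replace(win, **win_over))
    th_over = {}
    if "startingThPercent" in doc:
        th_over["start_fraction"] = float(doc["startingThPercent"])
    if "NT" in doc:
        th_over["n_levels"] = int(doc["NT"])
    if th_over:
        cfg = replace(cfg, thresholds=replace(cfg.thresholds, **th_over))
    if "ALT" in doc:
        cfg = replace(cfg, alt=replace(cfg.alt,
                                       coefficient_us_per_db=abs(float(doc["ALT"]))))
    if "gate_band_khz" in doc:
        lo, hi = doc["gate_band_khz"]
        cfg = replace(cfg, gate=replace(cfg.gate, band_lo_khz=float(lo),
                                        band_hi_khz=float(hi)))
    if "filterbank" in doc:
        cfg = replace(cfg, filterbank=FilterbankConfig(**doc["filterbank"]))
    if "network" in doc:
        cfg = replace(cfg, network=TriangularNetworkConfig(**doc["network"]))
    cfg.validate()
    return cfg
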