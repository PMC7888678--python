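"""Canonical study fixtures: the scenarios the model is demonstrated on.

Each preset builds an annotated sequence (and matching receiver
configuration) for one of the four demonstration scenarios:

``bat2HFM``
    two-harmonic bat chirp with three 2-glint echoes (glint separations
    50/100/200 us at range delays 5/12/18 ms) -- the batch display
    fixture -- plus the single worked example (100 us glints at 6 ms).
``dolClick``
    dolphin click followed by the standard two-glint echo series with
    separations 9-700 us.
``clutterRejection``
    single-harmonic FM sweep (100->20 kHz) with seven 100-us two-glint
    echoes under progressively stronger lowpass clutter filtering.
``clutterRejection-dolClick``
    focused vs. lowpass-cluttered 100-us two-glint click echoes.
"""

from __future__ import annotations

from .config import ScatConfig, bat_config, dolphin_config
from .synth import (CLICK_SERIES_US, ChirpSpec, EchoSequence,
                    assemble_sequence, bat_chirp_spec, dolphin_click_spec,
                    make_click, make_fm_chirp, two_glint_target)

__all__ = [
    "worked_example_bat", "bat_batch", "dolphin_click_series",
    "bat_chirp_series", "clutter_series_fm", "clutter_pair_dolphin",
    "PRESETS", "build_preset",
]

#: lowpass clutter ramps for the seven-echo FM series: the cutoff starts
#: near the top of the band and walks down to 50-60 kHz; ramp 2 dB/kHz,
#: capped at 40 dB
_CLUTTER_CUTOFFS_KHZ = (95.0, 87.5, 80.0, 72.5, 65.0, 57.5, 50.0)
_CLUTTER_RAMP_DB_PER_KHZ = 2.0
_CLUTTER_MAX_DB = 40.0


def worked_example_bat(fs: float = 500e3) -> tuple[EchoSequence, ScatConfig]:
    """Two-harmonic chirp + one 100-us two-glint echo at 6 ms."""
    cfg = bat_config(fs=fs)
    chirp = make_fm_chirp(bat_chirp_spec(), fs)
    seq = assemble_sequence(chirp, [two_glint_target(6e-3, 100e-6)],
                            cfg.windows, fs, mode="bat")
    return seq, cfg


def bat_batch(fs: float = 500e3) -> tuple[EchoSequence, ScatConfig]:
    """Three 2-glint chirp echoes: 50/100/200 us at 5/12/18 ms."""
    cfg = bat_config(fs=fs)
    chirp = make_fm_chirp(bat_chirp_spec(), fs)
    targets = [two_glint_target(5e-3, 50e-6),
               two_glint_target(12e-3, 100e-6),
               two_glint_target(18e-3, 200e-6)]
    seq = assemble_sequence(chirp, targets, cfg.windows, fs, mode="bat")
    return seq, cfg


def _series_targets(seps_us) -> list:
    return [two_glint_target((5 + 5 * i) * 1e-3, s * 1e-6)
            for i, s in enumerate(seps_us)]


def dolphin_click_series(fs: float = 500e3, seps_us=CLICK_SERIES_US
                         ) -> tuple[EchoSequence, ScatConfig]:
    """Click + two-glint echoes at the standard separations (9-700 us)."""
    cfg = dolphin_config(fs=fs)
    click = make_click(dolphin_click_spec(), fs)
    seq = assemble_sequence(click, _series_targets(seps_us), cfg.windows,
                            fs, mode="dolphin",
                            broadcast_duration_s=dolphin_click_spec().duration_s)
    return seq, cfg


def bat_chirp_series(fs: float = 500e3, seps_us=CLICK_SERIES_US
                     ) -> tuple[EchoSequence, ScatConfig]:
    """Chirp + two-glint echoes at the standard separations."""
    cfg = bat_config(fs=fs)
    chirp = make_fm_chirp(bat_chirp_spec(), fs)
    seq = assemble_sequence(chirp, _series_targets(seps_us), cfg.windows,
                            fs, mode="bat")
    return seq, cfg


def clutter_series_fm(fs: float = 500e3) -> tuple[EchoSequence, ScatConfig]:
    """Seven 100-us two-glint FM echoes under increasing lowpass clutter.

    Uses a single-harmonic 100->20 kHz sweep (no FM1/FM2 seam) so the
    spreading lowpass region is continuous in the analysed band.
    """
    cfg = bat_config(fs=fs, harmonic_seam_khz=None)
    spec = ChirpSpec(3e-3, ((100.0, 20.0),), "logarithmic")
    chirp = make_fm_chirp(spec, fs)
    targets = []
    for i, cutoff in enumerate(_CLUTTER_CUTOFFS_KHZ):
        targets.append(two_glint_target(
            (5 + 5 * i) * 1e-3, 100e-6,
            lowpass_profile=(cutoff, _CLUTTER_RAMP_DB_PER_KHZ,
                             _CLUTTER_MAX_DB)))
    seq = assemble_sequence(chirp, targets, cfg.windows, fs, mode="bat")
    return seq, cfg


def clutter_pair_dolphin(fs: float = 500e3) -> tuple[EchoSequence, ScatConfig]:
    """Focused vs. lowpass 100-us two-glint click echoes.

    The lowpass twin mimics an off-axis target: above ~100 kHz its
    spectrum rolls off, leaving a ~40 kHz wide lowpass region."""
    cfg = dolphin_config(fs=fs)
    click = make_click(dolphin_click_spec(), fs)
    targets = [
        two_glint_target(5e-3, 100e-6),
        two_glint_target(10e-3, 100e-6,
                         lowpass_profile=(100.0, 1.5, 40.0)),
    ]
    seq = assemble_sequence(click, targets, cfg.windows, fs, mode="dolphin",
                            broadcast_duration_s=dolphin_click_spec().duration_s)
    return seq, cfg


PRESETS = {
    "bat2HFM": bat_batch,
    "bat-worked-example": worked_example_bat,
    "bat-2glint-series": bat_chirp_series,
    "dolClick": dolphin_click_series,
    "dolphin-2glint-series": dolphin_click_series,
    "clutterRejection": clutter_series_fm,
    "lowpass-series": clutter_series_fm,
    "clutterRejection-dolClick": clutter_pair_dolphin,
}


def build_preset(name: str, fs: float = 500e3):
    try:
        factory = PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; choose from {sorted(PRESETS)}"
        ) from None
    return factory(fs=fs)
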