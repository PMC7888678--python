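"""Top-level modelling interface: ``ScatModel`` and ``ScatResults``.

``ScatModel`` wraps an annotated echo sequence plus a receiver
configuration; ``fit()`` runs the full deterministic cascade --
filterbank, transduction, gain normalisation, threshold crossings,
low-frequency gating, dechirping, amplitude-latency trading, range-delay
and glint-delay estimation -- and returns a ``ScatResults`` carrying the
composite images, diagnostics, tabular summaries and plotting helpers.

>>> from scat import synth, ScatModel
>>> chirp = synth.make_fm_chirp(synth.bat_chirp_spec())
>>> seq = synth.assemble_sequence(
...     chirp, [synth.two_glint_target(6e-3, 100e-6)])
>>> res = ScatModel(seq).fit()
>>> print(res.summary())            # doctest: +SKIP
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import delay as _delay
from . import frontend as _frontend
from . import glint as _glint
from . import imaging as _imaging
from .config import ScatConfig, config_for_mode
from .synth import EchoSequence

__all__ = ["ScatModel", "ScatResults"]

log = logging.getLogger("scat")


@dataclass
class ScatResults:
    """Fitted SCAT receiver output for one broadcast-echo sequence."""

    config: ScatConfig
    sequence: EchoSequence
    cochleagram: _frontend.Cochleagram
    crossings: _frontend.CrossingMap
    dechirped: _delay.DechirpedSpectrogram
    gate_decisions: dict[str, bool]
    images: list[_imaging.ScatImage]
    counters: dict[str, int] = field(default_factory=dict)

    # -- tabular views ------------------------------------------------
    @property
    def range_table(self) -> pd.DataFrame:
        rows = []
        for img in self.images:
            if not img.accepted:
                rows.append({"event": img.event_id, "t_ms": np.nan,
                             "n_channels": 0, "reliable": False,
                             "rejected_by_gate": True})
                continue
            for est in img.range_estimates:
                rows.append({"event": est.event_id, "t_ms": est.t_ms,
                             "n_channels": est.n_channels,
                             "reliable": est.reliable,
                             "rejected_by_gate": False})
        return pd.DataFrame(rows)

    @property
    def glint_table(self) -> pd.DataFrame:
        rows = []
        for img in self.images:
            gl = img.glint
            rows.append({
                "event": img.event_id,
                "delta_t_us": (gl.primary_delay_us
                               if gl is not None else np.nan),
                "delta_f_khz": (gl.aggregate_spacing_khz
                                if gl is not None else np.nan),
                "n_nulls": len(img.nulls.nulls) if img.nulls else 0,
                "n_apexes": len(gl.apexes) if gl is not None else 0,
                "separate_glints": len(img.range_estimates) > 1,
            })
        return pd.DataFrame(rows)

    def image_for(self, event_id: str) -> _imaging.ScatImage:
        for img in self.images:
            if img.event_id == event_id:
                return img
        raise KeyError(event_id)

    def summary(self) -> str:
        """Plain-text summary of the fitted images."""
        lines = [
            "SCAT receiver results",
            "=" * 70,
            f"mode: {self.config.mode}   fs: {self.config.fs / 1e3:.0f} kHz   "
            f"channels: {self.config.filterbank.n_channels}   "
            f"thresholds: {self.config.thresholds.n_levels}",
            f"ALT: {'-' if self.config.alt.enabled else 'off '}"
            f"{self.config.alt.coefficient_us_per_db:g} us/dB   "
            f"triangle base: {self.config.network.base_khz:g} kHz "
            f"(axis top {self.config.network.delay_axis_top_us:g} us)",
            "-" * 70,
            f"{'event':<12}{'t (ms)':>10}{'Dt (us)':>10}{'Df (kHz)':>10}"
            f"{'nulls':>7}{'chan':>6}  flags",
        ]
        for img in self.images:
            if not img.accepted:
                lines.append(f"{img.event_id:<12}{'--':>10}{'--':>10}"
                             f"{'--':>10}{'--':>7}{'--':>6}  gate-rejected")
                continue
            for k, est in enumerate(img.range_estimates):
                gl = img.glint if k == 0 else None
                dt = (f"{gl.primary_delay_us:.1f}"
                      if gl is not None and gl.primary_delay_us else "--")
                df = (f"{gl.aggregate_spacing_khz:.1f}"
                      if gl is not None and gl.aggregate_spacing_khz else "--")
                nn = len(img.nulls.nulls) if (img.nulls and k == 0) else 0
                flags = []
                if not est.reliable:
                    flags.append("unreliable")
                if len(img.range_estimates) > 1:
                    flags.append("separate-glints")
                lines.append(
                    f"{est.event_id:<12}{est.t_ms:>10.3f}{dt:>10}{df:>10}"
                    f"{nn:>7}{est.n_channels:>6}  {','.join(flags)}")
        lines.append("-" * 70)
        lines.append("t = leading-edge range delay; Dt = glint delay from "
                     "null spacing Df (Dt = 1/Df)")
        return "\n".join(lines)

    def plot(self, out_dir, threshold_level: int = 1,
             formats: tuple[str, ...] = ("png",)):
        return _imaging.render_3d(self.images, self.dechirped, out_dir,
                                  threshold_level, formats)

    def save_tables(self, out_dir) -> None:
        from pathlib import Path
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.range_table.to_csv(out / "range_delays.tsv", sep="\t",
                                index=False, float_format="%.6f")
        self.glint_table.to_csv(out / "glint_delays.tsv", sep="\t",
                                index=False, float_format="%.6f")


class ScatModel:
    """SCAT biosonar receiver bound to one annotated echo sequence.

    Parameters
    ----------
    sequence : EchoSequence
        Annotated waveform (one broadcast + echo train), typically from
        :mod:`scat.synth` or loaded via :mod:`scat.io`.
    mode : str, optional
        Species preset, ``"bat"`` or ``"dolphin"``; ignored when an
        explicit ``config`` is given.
    config : ScatConfig, optional
        Full receiver configuration.
    """

    def __init__(self, sequence: EchoSequence, mode: str | None = None,
                 config: ScatConfig | None = None):
        self.sequence = sequence
        self.config = config or config_for_mode(mode or sequence.mode)
        self.config.validate()

    @classmethod
    def from_waveform(cls, samples, fs, broadcast_start_s,
                      broadcast_duration_s, echo_delays_s,
                      mode: str = "bat", config: ScatConfig | None = None):
        """Build a model from a bare waveform plus event annotations
        (e.g. an externally supplied recording)."""
        from .synth import GlintTargetSpec
        targets = [GlintTargetSpec(range_delay_s=d) for d in echo_delays_s]
        seq = EchoSequence(samples=np.asarray(samples, float), fs=fs,
                           broadcast_start_s=broadcast_start_s,
                           broadcast_duration_s=broadcast_duration_s,
                           targets=targets, mode=mode)
        return cls(seq, config=config)

    def fit(self) -> ScatResults:
        """Run the receiver cascade and return the fitted results."""
        cfg = self.config
        seq = self.sequence
        coch, cmap = _frontend.analyze_sequence(seq, cfg)
        gate = _delay.low_frequency_gate(cmap, cfg.gate)
        dsp = _delay.apply_alt(_delay.dechirp(cmap), cfg.alt)
        separate = _delay.resolve_separate_glints(coch, cmap, cfg)

        range_map: dict[str, list[_delay.RangeDelayEstimate]] = {}
        glint_map: dict[str, _glint.GlintDelayEstimate | None] = {}
        nullsets: dict[str, _glint.NullSet] = {}
        counters = {"events": 0, "gated_out": 0, "nulls": 0, "apexes": 0,
                    "fill_in": 0, "separate": 0}
        for ev in dsp.echo_events:
            eid = ev.event_id
            counters["events"] += 1
            if not gate.get(eid, True):
                counters["gated_out"] += 1
                range_map[eid] = []
                glint_map[eid] = None
                continue
            primary = _delay.estimate_range_delay(dsp, eid, cfg.range_delay)
            ests = [primary]
            extra = [e for e in separate.get(eid, [])
                     if e.event_id.endswith("/glint2")]
            consensus = (extra[0].n_channels / max(primary.n_channels, 1)
                         if extra else 0.0)
            separated = consensus >= cfg.separation_consensus
            nullset = apexes = fill = None
            aggregate = None
            if not separated:
                nullset = _glint.find_nulls(dsp, cmap, eid, cfg,
                                            leading_edge=primary)
                apexes, aggregate = _glint.run_triangular_network(
                    nullset, cfg.network)
                fill = _glint.fill_lowpass_void(nullset, cfg.network)
            if separated and extra:
                counters["separate"] += 1
                ests += extra
                range_map[eid] = ests
                glint_map[eid] = None
                log.info("event %s: separate glints at %.3f / %.3f ms",
                         eid, ests[0].t_ms, ests[1].t_ms)
                continue
            est = _glint.invert_spacing(apexes + fill, aggregate,
                                        cfg.network, eid)
            _glint.normalize_image_energy(est)
            counters["nulls"] += len(nullset.nulls)
            counters["apexes"] += len(apexes)
            counters["fill_in"] += len(fill)
            range_map[eid] = ests
            glint_map[eid] = est
            nullsets[eid] = nullset
            log.info("event %s: t=%.3f ms, %d nulls, Df=%s kHz",
                     eid, primary.t_ms, len(nullset.nulls), aggregate)
        images = _imaging.assemble_image(range_map, glint_map, gate, nullsets)
        return ScatResults(config=cfg, sequence=seq, cochleagram=coch,
                           crossings=cmap, dechirped=dsp,
                           gate_decisions=gate, images=images,
                           counters=counters)
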