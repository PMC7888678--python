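"""Composite SCAT images and their display.

The model's output per echo event is a composite "image": the range
delay t (leading edge of the cross-channel delay histogram) with the
glint delay Dt (from the triangular null-spacing network) attached to
it.  When the separate-glint pathway fired, the event instead carries
two t values and no Dt -- both glints then live entirely on the range
axis.  The 3D display (X = range delay, Y = frequency, Z = glint delay)
is decomposed into its planes as separate panels in addition to the
combined view, because quantitative statements are made on the planes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .delay import DechirpedSpectrogram, RangeDelayEstimate
from .glint import GlintDelayEstimate, NullSet

__all__ = ["ScatImage", "assemble_image", "render_3d"]


@dataclass
class ScatImage:
    """Joint range-delay + glint-delay record for one echo event."""

    event_id: str
    accepted: bool
    range_estimates: list[RangeDelayEstimate] = field(default_factory=list)
    glint: GlintDelayEstimate | None = None
    nulls: NullSet | None = None

    @property
    def t_ms(self) -> float | None:
        return self.range_estimates[0].t_ms if self.range_estimates else None

    @property
    def delta_t_us(self) -> float | None:
        if self.glint is not None and self.glint.primary_delay_us is not None:
            return self.glint.primary_delay_us
        return None


def assemble_image(range_estimates: dict[str, list[RangeDelayEstimate]],
                   glint_estimates: dict[str, GlintDelayEstimate | None],
                   accepted: dict[str, bool],
                   nullsets: dict[str, NullSet] | None = None
                   ) -> list[ScatImage]:
    """Merge per-event range and glint estimates into composite images.

    Keys must agree across the inputs; an event rejected by the
    low-frequency gate carries no estimates at all.
    """
    if set(range_estimates) != set(glint_estimates):
        raise ValueError("range and glint estimates keyed to different events")
    images = []
    for eid in range_estimates:
        ok = accepted.get(eid, True)
        if not ok:
            images.append(ScatImage(eid, accepted=False))
            continue
        rng = range_estimates[eid]
        gl = glint_estimates[eid]
        if len(rng) > 1:
            gl = None          # separate-glint regime: both on the range axis
        images.append(ScatImage(eid, True, rng, gl,
                                (nullsets or {}).get(eid)))
    return images


def render_3d(images: list[ScatImage], dsp: DechirpedSpectrogram,
              out_dir, threshold_level: int = 1,
              formats: tuple[str, ...] = ("png",)) -> list[Path]:
    """Write static figures: dechirped X-Y spectrogram plane, range
    histograms, triangular network zig-zag, X-Z glint histograms, and a
    combined 3D view.  Deterministic given images + options."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    lvl = threshold_level - 1

    fig, axes = plt.subplots(2, 2, figsize=(11, 8))
    ax = axes[0, 0]
    for i, ev in enumerate(dsp.echo_events):
        d = dsp.delays_s[i, :, lvl] * 1e3
        ax.plot(d, dsp.cfs_khz, ".", ms=2, label=ev.event_id)
    ax.axvline(0.0, color="k", lw=0.8, ls="--")
    ax.set_xlabel("range delay (ms)")
    ax.set_ylabel("frequency (kHz)")
    ax.set_title(f"dechirped spectrogram (threshold #{threshold_level})")

    ax = axes[0, 1]
    for img in images:
        for est in img.range_estimates:
            if est.hist_counts.size:
                ax.stairs(est.hist_counts, est.hist_edges_s * 1e3,
                          label=est.event_id)
    ax.set_xlabel("range delay (ms)")
    ax.set_ylabel("count")
    ax.set_title("range-delay histograms (X axis)")

    ax = axes[1, 0]
    y0 = 0.0
    for img in images:
        if img.nulls is None or not img.nulls.nulls:
            continue
        cents = img.nulls.centers_khz
        zig_x, zig_y = [], []
        for a, b in zip(cents, cents[1:]):
            zig_x += [0.0, (b - a) / 2, 0.0]
            zig_y += [a + y0, (a + b) / 2 + y0, b + y0]
        ax.plot(zig_x, zig_y, "r-", lw=1)
        ax.plot(np.zeros_like(cents), cents + y0, "ro", ms=3)
    ax.set_xlabel("null spacing / 2 (kHz)")
    ax.set_ylabel("null frequency (kHz)")
    ax.set_title("triangular network zig-zag")

    ax = axes[1, 1]
    for img in images:
        if img.glint is not None and img.glint.counts.sum() > 0:
            ax.plot(img.glint.dt_grid_us, img.glint.counts, lw=1,
                    label=img.event_id)
    ax.set_xlabel("glint delay (us)")
    ax.set_ylabel("count")
    ax.set_title("glint-delay histograms (X-Z plane)")
    for a in axes.flat:
        if a.get_legend_handles_labels()[1]:
            a.legend(fontsize=6, loc="best")
    fig.tight_layout()
    for ext in formats:
        p = out_dir / f"scat_planes.{ext}"
        fig.savefig(p, dpi=120)
        written.append(p)
    plt.close(fig)

    fig = plt.figure(figsize=(8, 6))
    ax3 = fig.add_subplot(projection="3d")
    for i, ev in enumerate(dsp.echo_events):
        d = dsp.delays_s[i, :, lvl] * 1e3
        ax3.scatter(d, dsp.cfs_khz, np.zeros_like(d), s=2)
    for img in images:
        if img.glint is not None and img.glint.counts.sum() > 0 and img.t_ms:
            z = img.glint.dt_grid_us
            ax3.plot(np.full_like(z, img.t_ms), np.zeros_like(z) +
                     dsp.cfs_khz[-1], z, "r-", lw=1)
    ax3.set_xlabel("range delay (ms)")
    ax3.set_ylabel("frequency (kHz)")
    ax3.set_zlabel("glint delay (us)")
    for ext in formats:
        p = out_dir / f"scat_3d.{ext}"
        fig.savefig(p, dpi=120)
        written.append(p)
    plt.close(fig)
    return written
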