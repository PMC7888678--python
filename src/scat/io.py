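"""Readers/writers: WAV, array container (.npz) with YAML sidecar.

An :class:`~scat.synth.EchoSequence` round-trips through either a float
WAV (sample rate embedded) or a compressed ``.npz`` array container; in
both cases the annotations (broadcast timing, glint targets, window
parameters, mode) travel in a YAML sidecar next to the waveform file.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import numpy as np
import yaml
from scipy.io import wavfile

from .config import WindowParams
from .synth import EchoSequence, GlintTargetSpec

__all__ = ["write_sequence", "read_sequence"]


def _annotations(seq: EchoSequence) -> dict:
    return {
        "fs": float(seq.fs),
        "mode": seq.mode,
        "broadcast_start_ms": seq.broadcast_start_s * 1e3,
        "broadcast_duration_ms": seq.broadcast_duration_s * 1e3,
        "window_params": asdict(seq.window_params),
        "targets": [
            {
                "range_delay_ms": t.range_delay_s * 1e3,
                "glint_offsets_us": [o * 1e6 for o in t.glint_offsets_s],
                "glint_amplitudes": list(t.glint_amplitudes),
                "glint_signs": (list(t.glint_signs)
                                if t.glint_signs is not None else None),
                "lowpass_profile": (list(t.lowpass_profile)
                                    if t.lowpass_profile is not None else None),
                "attenuation_db": t.attenuation_db,
            }
            for t in seq.targets
        ],
    }


def _targets_from(doc: list[dict]) -> list[GlintTargetSpec]:
    out = []
    for d in doc:
        out.append(GlintTargetSpec(
            range_delay_s=d["range_delay_ms"] * 1e-3,
            glint_offsets_s=tuple(o * 1e-6 for o in d["glint_offsets_us"]),
            glint_amplitudes=tuple(d["glint_amplitudes"]),
            glint_signs=(tuple(d["glint_signs"])
                         if d.get("glint_signs") else None),
            lowpass_profile=(tuple(d["lowpass_profile"])
                             if d.get("lowpass_profile") else None),
            attenuation_db=d.get("attenuation_db", 0.0),
        ))
    return out


def write_sequence(seq: EchoSequence, path) -> Path:
    """Write a sequence as ``.wav`` or ``.npz`` plus a ``.yaml`` sidecar."""
    path = Path(path)
    if path.suffix == ".wav":
        wavfile.write(path, int(seq.fs), seq.samples.astype(np.float32))
    elif path.suffix == ".npz":
        np.savez_compressed(path, samples=seq.samples, fs=seq.fs)
    else:
        raise ValueError(f"unsupported container {path.suffix!r}")
    sidecar = path.with_suffix(path.suffix + ".yaml")
    with open(sidecar, "w") as fh:
        yaml.safe_dump(_annotations(seq), fh, sort_keys=False)
    return path


def read_sequence(path) -> EchoSequence:
    """Read a sequence written by :func:`write_sequence`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".wav":
        fs, samples = wavfile.read(path)
        samples = np.asarray(samples, float)
        fs = float(fs)
    elif path.suffix == ".npz":
        with np.load(path) as z:
            samples = np.asarray(z["samples"], float)
            fs = float(z["fs"])
    else:
        raise ValueError(f"unsupported container {path.suffix!r}")
    if samples.size == 0:
        raise ValueError(f"{path} contains no samples")
    sidecar = path.with_suffix(path.suffix + ".yaml")
    if not sidecar.exists():
        raise FileNotFoundError(
            f"annotation sidecar {sidecar} missing (event windows unknown)")
    with open(sidecar) as fh:
        doc = yaml.safe_load(fh)
    wp = WindowParams(**doc.get("window_params", {}))
    return EchoSequence(
        samples=samples, fs=doc.get("fs", fs),
        broadcast_start_s=doc["broadcast_start_ms"] * 1e-3,
        broadcast_duration_s=doc["broadcast_duration_ms"] * 1e-3,
        targets=_targets_from(doc.get("targets", [])),
        window_params=wp, mode=doc.get("mode", "bat"),
    )
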