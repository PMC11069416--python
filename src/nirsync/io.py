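"""Plain-text interchange formats for simulated and recorded sessions.

One directory per dyad:

* ``<participant>_intensity.tsv`` — one column per channel x wavelength
  (header ``ch<id>_<nm>``), one row per sample.
* ``<participant>_geometry.tsv`` — optode id, kind, real-space x/y/z (cm),
  MNI x/y/z (mm).
* ``<participant>_channels.tsv`` — channel id with forming source/detector.
* ``events.tsv`` — onset_s, duration_s, phase_label.
* ``meta.json`` — dyad metadata; ``truth.json`` — simulation ground truth.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .inference import DyadMeta
from .montage import OptodeSet
from .preprocess import WAVELENGTHS_NM, RawIntensity
from .synthetic import GroundTruth, SessionRecording


def _intensity_frame(raw: RawIntensity) -> pd.DataFrame:
    cols = {}
    for i, ch in enumerate(raw.channel_ids):
        for w, wl in enumerate(raw.wavelengths):
            cols[f"ch{int(ch)}_{int(wl)}"] = raw.values[i, :, w]
    return pd.DataFrame(cols)


def _intensity_from_frame(df: pd.DataFrame, fs: float) -> RawIntensity:
    chans = sorted({int(c.split("_")[0][2:]) for c in df.columns})
    values = np.empty((len(chans), len(df), 3))
    for i, ch in enumerate(chans):
        for w, wl in enumerate(WAVELENGTHS_NM):
            values[i, :, w] = df[f"ch{ch}_{int(wl)}"].to_numpy()
    return RawIntensity(values=values, fs=fs, channel_ids=np.array(chans))


def write_session(session: SessionRecording, out_dir: str | Path, truth: GroundTruth | None = None) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fs = next(iter(session.raw.values())).fs
    for role, raw in session.raw.items():
        pid = getattr(session.meta, f"participant_{role.lower()}")
        _intensity_frame(raw).to_csv(out / f"{pid}_intensity.tsv", sep="\t", index=False)
        geom = session.geometry[role]
        geom.optodes.to_csv(out / f"{pid}_geometry.tsv", sep="\t", index=False)
        geom.channels.to_csv(out / f"{pid}_channels.tsv", sep="\t", index=False)
    session.events.to_csv(out / "events.tsv", sep="\t", index=False)
    meta = {
        "dyad_id": session.meta.dyad_id,
        "video_order": session.meta.video_order,
        "participant_a": session.meta.participant_a,
        "participant_b": session.meta.participant_b,
        "is_real": session.meta.is_real,
        "fs": fs,
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=2))
    if truth is not None:
        (out / "truth.json").write_text(json.dumps(_truth_dict(truth), indent=2))
    return out


def _truth_dict(truth: GroundTruth) -> dict:
    return {
        "dyad_id": truth.dyad_id,
        "coupling": {"|".join(k): v for k, v in truth.coupling.items()},
        "stimulus_coupling": dict(truth.stimulus_coupling),
        "artifacts": {
            role: {str(ch): ev for ch, ev in chans.items()}
            for role, chans in truth.artifacts.items()
        },
        "seed": truth.seed,
        "dyad_index": truth.dyad_index,
    }


def read_session(session_dir: str | Path) -> SessionRecording:
    d = Path(session_dir)
    meta = json.loads((d / "meta.json").read_text())
    fs = float(meta["fs"])
    events = pd.read_csv(d / "events.tsv", sep="\t")
    raw, geometry = {}, {}
    for role, pid_key in (("A", "participant_a"), ("B", "participant_b")):
        pid = meta[pid_key]
        df = pd.read_csv(d / f"{pid}_intensity.tsv", sep="\t")
        raw[role] = _intensity_from_frame(df, fs)
        optodes = pd.read_csv(d / f"{pid}_geometry.tsv", sep="\t")
        channels = pd.read_csv(d / f"{pid}_channels.tsv", sep="\t")
        pairs = list(zip(channels["source"], channels["detector"]))
        geometry[role] = OptodeSet(
            optodes=optodes, channels=channels, participant=pid, neighbor_pairs=pairs
        )
    return SessionRecording(
        raw=raw,
        geometry=geometry,
        events=events,
        meta=DyadMeta(
            dyad_id=meta["dyad_id"],
            video_order=meta["video_order"],
            participant_a=meta["participant_a"],
            participant_b=meta["participant_b"],
            is_real=bool(meta["is_real"]),
        ),
    )
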