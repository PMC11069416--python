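"""Synthetic dyadic fNIRS sessions with known inter-brain coupling.

Each session emulates two participants recorded simultaneously while they
watch a 2-minute video (phase ``video1``), converse (phase ``conversation``)
and watch a second video (phase ``video2``), at 8.33 Hz with 19 channels per
hemisphere and three wavelengths (780/805/830 nm).

The latent hemodynamic model mixes, per region of interest, frequency band
and phase, three unit-variance band-limited Gaussian processes:

    x = a * stimulus + c * dyad_shared + sqrt(1 - a^2 - c^2) * private

``stimulus`` is shared by every participant watching the same video
(stimulus-driven baseline coherence, what pseudo-dyads capture), while
``dyad_shared`` is shared only within a real dyad, with coupling ``c``
configurable per (phase, band, ROI).  ``c`` maps monotonically onto expected
wavelet coherence.  HbR is generated anti-correlated with HbO (ratio -0.3)
plus independent noise so CBSI has realistic structure.  Channel intensities
are produced through the Beer-Lambert forward model (the exact inverse of
the preprocessing MBLL step) with baseline, heartbeat oscillation, slow
drift, multiplicative white noise and injectable motion artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from . import montage as mont
from .geometry import roi_specs
from .inference import DyadMeta
from .preprocess import RawIntensity, mbll_matrix

PHASES = ("video1", "conversation", "video2")
BAND_EDGES = {"high": (0.1, 0.2), "medium": (0.03, 0.1), "low": (0.02, 0.03)}
BAND_NAMES = tuple(BAND_EDGES)
BROADBAND = (0.01, 0.4)

CouplingMap = Mapping[str, Mapping[str, float | Mapping[str, float]]]


@dataclass
class SimulationConfig:
    """Study conditions for a simulated cohort.

    ``coupling`` maps phase -> band -> coefficient in [0, 1]; the
    coefficient may be a scalar (applied to every ROI) or a mapping of ROI
    labels (e.g. ``"TPJ_R"``).  ``stimulus_coupling`` (band -> coefficient)
    is the video-locked component shared by *all* participants watching the
    same episode, real and pseudo partners alike.
    """

    n_dyads: int = 27
    fs: float = 8.33
    phase_durations: tuple[float, float, float] = (120.0, 1200.0, 120.0)
    n_channels_per_hemisphere: int = 19
    coupling: CouplingMap = field(default_factory=dict)
    stimulus_coupling: Mapping[str, float] = field(
        default_factory=lambda: {"low": 0.3, "medium": 0.3, "high": 0.2}
    )
    artifact_rate_per_min: float = 0.5
    heartbeat_freq: float = 1.1
    heartbeat_amp_od: float = 0.015
    drift_sd_od: float = 0.02
    noise_sd: float = 0.003  # relative intensity noise (shot-noise level)
    spatial_sigma_mm: float = 20.0  # spatial extent of ROI activity
    hbo_amp_um: float = 0.8
    hbr_ratio: float = -0.3
    hbr_noise: float = 0.2
    mni_jitter_sd_mm: float = 8.0
    mni_jitter_max_mm: float = 15.0
    real_jitter_sd_cm: float = 0.05
    mislocation_rate: float = 0.0
    counterbalance: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if any(d <= 0 for d in self.phase_durations):
            raise ValueError("phase durations must be positive")
        if self.artifact_rate_per_min < 0:
            raise ValueError("artifact rate must be non-negative")
        roi_labels = {r.label for r in roi_specs()}
        for phase, bands in self.coupling.items():
            if phase not in PHASES:
                raise ValueError(f"unknown phase {phase!r}; expected one of {PHASES}")
            for band, c in bands.items():
                if band not in BAND_EDGES:
                    raise ValueError(
                        f"unknown band {band!r} in coupling map; expected one of "
                        f"{sorted(BAND_EDGES)}"
                    )
                vals = c.values() if isinstance(c, Mapping) else [c]
                if isinstance(c, Mapping):
                    for roi in c:
                        if roi not in roi_labels:
                            raise ValueError(f"unknown ROI label {roi!r} in coupling map")
                for v in vals:
                    if not 0.0 <= float(v) <= 1.0:
                        raise ValueError(f"coupling coefficient {v} outside [0, 1]")
        for band, v in self.stimulus_coupling.items():
            if band not in BAND_EDGES:
                raise ValueError(f"unknown band {band!r} in stimulus_coupling")
            if not 0.0 <= float(v) <= 1.0:
                raise ValueError(f"stimulus coupling {v} outside [0, 1]")

    def coupling_at(self, phase: str, band: str, roi: str) -> float:
        c = self.coupling.get(phase, {}).get(band, 0.0)
        if isinstance(c, Mapping):
            c = c.get(roi, 0.0)
        return float(c)

    def phase_samples(self) -> list[int]:
        return [int(round(d * self.fs)) for d in self.phase_durations]

    def events(self) -> pd.DataFrame:
        onsets = np.concatenate([[0.0], np.cumsum(self.phase_durations)[:-1]])
        return pd.DataFrame(
            {
                "onset_s": onsets,
                "duration_s": list(self.phase_durations),
                "phase_label": list(PHASES),
            }
        )


@dataclass
class GroundTruth:
    """What was actually injected into one simulated session."""

    dyad_id: str
    coupling: dict  # (phase, band, roi) -> coefficient
    stimulus_coupling: dict  # band -> coefficient
    artifacts: dict  # participant -> channel id -> list of event dicts
    seed: int
    dyad_index: int


@dataclass
class SessionRecording:
    """One dyad's raw recording: two intensity streams, events, geometry."""

    raw: dict[str, RawIntensity]  # roles "A" and "B"
    geometry: dict[str, mont.OptodeSet]
    events: pd.DataFrame
    meta: DyadMeta


@dataclass
class SimulatedCohort:
    sessions: list[SessionRecording]
    truths: list[GroundTruth]
    meta: pd.DataFrame


# ---------------------------------------------------------------------------
# latent signal helpers


def _filtered_noise(rng: np.random.Generator, n: int, fs: float, lo: float, hi: float) -> np.ndarray:
    """Unit-variance zero-phase band-limited Gaussian noise of length n."""
    pad = int(min(2.0 / lo * fs, 4 * n))
    raw = rng.standard_normal(n + 2 * pad)
    sos = sps.butter(4, [lo, hi], btype="bandpass", output="sos", fs=fs)
    x = sps.sosfiltfilt(sos, raw)[pad : pad + n]
    sd = x.std()
    return x / sd if sd > 0 else x


def _slow_drift(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Unit-variance drift below the analysis band (< 0.01 Hz)."""
    pad = min(4 * n, int(200 * fs))
    raw = rng.standard_normal(n + 2 * pad)
    sos = sps.butter(2, 0.008, btype="lowpass", output="sos", fs=fs)
    x = sps.sosfiltfilt(sos, raw)[pad : pad + n]
    sd = x.std()
    return x / sd if sd > 0 else x


def _stimulus_latent(config: SimulationConfig, video: int, band: str, roi_idx: int, n: int) -> np.ndarray:
    """Video-locked latent, identical for everyone watching this episode."""
    rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed) & 0x7FFFFFFF, 1, video, BAND_NAMES.index(band), roi_idx])
    )
    lo, hi = BAND_EDGES[band]
    return _filtered_noise(rng, n, config.fs, lo, hi)


def _videos_for_order(order: str) -> dict[str, int]:
    """Phase -> episode index under a given counterbalancing order."""
    return {"video1": 0, "video2": 1} if order == "order0" else {"video1": 1, "video2": 0}


# ---------------------------------------------------------------------------
# motion artifacts


def _draw_artifacts(rng: np.random.Generator, n: int, fs: float, rate_per_min: float) -> list[dict]:
    n_events = rng.poisson(rate_per_min * n / fs / 60.0)
    events = []
    for _ in range(n_events):
        sample = int(rng.integers(0, n))
        kind = "spike" if rng.random() < 0.7 else "step"
        sign = 1.0 if rng.random() < 0.5 else -1.0
        if kind == "spike":
            amp = 5.0 + rng.exponential(3.0)
            width_s = float(rng.uniform(0.05, 0.3))  # Gaussian SD; support < 2 s
        else:
            amp = 1.0 + rng.exponential(2.0)
            width_s = 0.0
        events.append(
            {"sample": sample, "kind": kind, "amplitude_sd": sign * amp, "width_s": width_s}
        )
    return sorted(events, key=lambda e: e["sample"])


def _apply_artifacts(x: np.ndarray, events: Sequence[dict], fs: float) -> np.ndarray:
    out = x.astype(float).copy()
    sd = x.std()
    if sd == 0:
        sd = 1.0
    t = np.arange(len(x))
    for ev in events:
        amp = ev["amplitude_sd"] * sd
        if ev["kind"] == "spike":
            w = max(ev["width_s"] * fs, 0.5)
            out += amp * np.exp(-0.5 * ((t - ev["sample"]) / w) ** 2)
        else:
            out[ev["sample"] :] += amp
    return out


def inject_motion_artifacts(
    signal: np.ndarray, rate_per_min: float, seed: int, fs: float = 8.33
) -> tuple[np.ndarray, list[dict]]:
    """Add Poisson-timed spikes (>= 5 x SD, < 2 s wide) and step shifts.

    Returns the corrupted series and the ground-truth event list; with
    ``rate_per_min = 0`` the input is returned unchanged.
    """
    if rate_per_min < 0:
        raise ValueError("rate must be non-negative")
    x = np.asarray(signal, float)
    if rate_per_min == 0:
        return x.copy(), []
    rng = np.random.default_rng(seed)
    events = _draw_artifacts(rng, len(x), fs, rate_per_min)
    return _apply_artifacts(x, events, fs), events


# ---------------------------------------------------------------------------
# session assembly


def _jittered_geometry(
    config: SimulationConfig, rng: np.random.Generator, participant: str
) -> mont.OptodeSet:
    optset = mont.reference_optodes(participant, config.n_channels_per_hemisphere)
    opt = optset.optodes.copy()
    n = len(opt)
    real_jit = rng.normal(0.0, config.real_jitter_sd_cm, (n, 3))
    mni_jit = rng.normal(0.0, config.mni_jitter_sd_mm, (n, 3))
    norms = np.linalg.norm(mni_jit, axis=1, keepdims=True)
    over = norms[:, 0] > config.mni_jitter_max_mm
    if over.any():  # truncate isotropic jitter at the configured radius
        mni_jit[over] *= config.mni_jitter_max_mm / norms[over]
    mislocated = rng.random(n) < config.mislocation_rate
    for i in np.flatnonzero(mislocated):
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        real_jit[i] = direction * rng.uniform(1.5, 2.5)
        mni_jit[i] = direction * rng.uniform(25.0, 40.0)
    opt[["x_cm", "y_cm", "z_cm"]] += real_jit
    opt[["mni_x", "mni_y", "mni_z"]] += mni_jit
    return replace(optset, optodes=opt)


def _nominal_channel_rois(config: SimulationConfig) -> dict[int, tuple[str, float] | None]:
    """Ground-truth channel -> (nearest ROI, activity weight) on the
    jitter-free montage.

    ROI activity has spatial extent: a channel at nominal distance d from
    its nearest ROI centre carries a fraction w = exp(-d^2 / (2 sigma^2)) of
    the ROI latent's variance, so neighbouring channels sample attenuated
    copies of the same activity (weights below 0.1 are treated as zero).
    """
    optset = mont.reference_optodes("", config.n_channels_per_hemisphere)
    opt = optset.optodes.set_index("optode")
    rois = roi_specs()
    centers = np.array([r.center for r in rois])
    out: dict[int, tuple[str, float] | None] = {}
    for ch in optset.channels.itertuples():
        mid = 0.5 * (
            opt.loc[ch.source, ["mni_x", "mni_y", "mni_z"]].to_numpy(float)
            + opt.loc[ch.detector, ["mni_x", "mni_y", "mni_z"]].to_numpy(float)
        )
        d = np.linalg.norm(centers - mid, axis=1)
        j = int(np.argmin(d))
        w = float(np.exp(-0.5 * (d[j] / config.spatial_sigma_mm) ** 2))
        out[int(ch.channel)] = (rois[j].label, w) if w >= 0.1 else None
    return out


def simulate_session(
    config: SimulationConfig, dyad_index: int
) -> tuple[SessionRecording, GroundTruth]:
    """Generate one dyad's raw two-participant recording plus ground truth."""
    fs = config.fs
    n_phase = config.phase_samples()
    n_total = sum(n_phase)
    offsets = np.concatenate([[0], np.cumsum(n_phase)]).astype(int)
    order = "order0" if (not config.counterbalance or dyad_index % 2 == 0) else "order1"
    videos = _videos_for_order(order)
    dyad_id = f"d{dyad_index:02d}"
    rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed) & 0x7FFFFFFF, 2, int(dyad_index)])
    )

    rois = roi_specs()
    roi_labels = [r.label for r in rois]
    channel_roi = _nominal_channel_rois(config)

    # dyad-shared latents per (phase, band, roi)
    shared = {
        (ph, b, roi): _filtered_noise(rng, n_phase[pi], fs, *BAND_EDGES[b])
        for pi, ph in enumerate(PHASES)
        for b in BAND_NAMES
        for roi in roi_labels
    }
    video_n = max(n_phase[0], n_phase[2])
    stimulus = {
        (v, b, roi): _stimulus_latent(config, v, b, ri, video_n)
        for v in (0, 1)
        for b in BAND_NAMES
        for ri, roi in enumerate(roi_labels)
    }

    truth_coupling = {
        (ph, b, roi): config.coupling_at(ph, b, roi)
        for ph in PHASES
        for b in BAND_NAMES
        for roi in roi_labels
    }

    raw: dict[str, RawIntensity] = {}
    geometry: dict[str, mont.OptodeSet] = {}
    artifacts: dict[str, dict[int, list[dict]]] = {}
    A = mbll_matrix()

    for role in ("A", "B"):
        participant = f"{dyad_id}{role}"
        # per-ROI HbO latents over the full session
        roi_hbo = {}
        for roi in roi_labels:
            parts = np.zeros(n_total)
            for b in BAND_NAMES:
                series = np.zeros(n_total)
                for pi, ph in enumerate(PHASES):
                    sl = slice(offsets[pi], offsets[pi + 1])
                    npi = n_phase[pi]
                    a = float(config.stimulus_coupling.get(b, 0.0)) if ph != "conversation" else 0.0
                    c = truth_coupling[(ph, b, roi)]
                    # dyad coupling takes priority in the unit variance budget;
                    # the stimulus weight is capped at what remains
                    a = min(a, np.sqrt(max(0.0, 1.0 - c * c)))
                    priv_w = np.sqrt(max(0.0, 1.0 - a * a - c * c))
                    seg = c * shared[(ph, b, roi)]
                    if a > 0:
                        seg = seg + a * stimulus[(videos[ph], b, roi)][:npi]
                    if priv_w > 0:
                        seg = seg + priv_w * _filtered_noise(rng, npi, fs, *BAND_EDGES[b])
                    series[sl] = seg
                parts += series
            roi_hbo[roi] = config.hbo_amp_um / np.sqrt(len(BAND_NAMES)) * parts

        optset = _jittered_geometry(config, rng, participant)
        channels = optset.channels["channel"].astype(int).tolist()
        n_ch = len(channels)
        hbo = np.empty((n_ch, n_total))
        hbr = np.empty((n_ch, n_total))
        for i, ch in enumerate(channels):
            hit = channel_roi.get(ch)
            if hit is not None:
                roi, w = hit
                hbo[i] = np.sqrt(w) * roi_hbo[roi] + np.sqrt(
                    1.0 - w
                ) * config.hbo_amp_um * _filtered_noise(rng, n_total, fs, *BROADBAND)
            else:
                hbo[i] = config.hbo_amp_um * _filtered_noise(rng, n_total, fs, *BROADBAND)
            hbr[i] = config.hbr_ratio * hbo[i] + config.hbr_noise * config.hbo_amp_um * _filtered_noise(
                rng, n_total, fs, *BROADBAND
            )

        # Beer-Lambert forward model: (C, T, 3) optical densities
        od = hbo[:, :, None] * A[:, 0][None, None, :] + hbr[:, :, None] * A[:, 1][None, None, :]

        if config.drift_sd_od > 0:
            wl_scale = np.array([1.0, 0.95, 1.05])
            for i in range(n_ch):
                od[i] += config.drift_sd_od * _slow_drift(rng, n_total, fs)[:, None] * wl_scale
        if config.heartbeat_amp_od > 0:
            f_hb = config.heartbeat_freq + rng.normal(0.0, 0.05)
            t = np.arange(n_total) / fs
            for i in range(n_ch):
                amp = config.heartbeat_amp_od * rng.uniform(0.8, 1.2)
                phase0 = rng.uniform(0, 2 * np.pi)
                od[i] += (amp * np.sin(2 * np.pi * f_hb * t + phase0))[:, None]

        baseline = rng.uniform(500.0, 2000.0, (n_ch, 1, 3))
        intensity = baseline * np.exp(-od)
        if config.noise_sd > 0:
            noise = 1.0 + config.noise_sd * rng.standard_normal(intensity.shape)
            intensity = intensity * np.clip(noise, 0.05, None)

        part_artifacts: dict[int, list[dict]] = {}
        if config.artifact_rate_per_min > 0:
            for i, ch in enumerate(channels):
                events = _draw_artifacts(rng, n_total, fs, config.artifact_rate_per_min)
                if events:
                    for w in range(3):
                        intensity[i, :, w] = np.clip(
                            _apply_artifacts(intensity[i, :, w], events, fs),
                            1e-3 * baseline[i, 0, w],
                            None,
                        )
                part_artifacts[ch] = events
        artifacts[role] = part_artifacts

        raw[role] = RawIntensity(values=intensity, fs=fs, channel_ids=np.array(channels))
        geometry[role] = optset

    meta = DyadMeta(
        dyad_id=dyad_id,
        video_order=order,
        participant_a=f"{dyad_id}A",
        participant_b=f"{dyad_id}B",
        is_real=True,
    )
    session = SessionRecording(raw=raw, geometry=geometry, events=config.events(), meta=meta)
    truth = GroundTruth(
        dyad_id=dyad_id,
        coupling=truth_coupling,
        stimulus_coupling=dict(config.stimulus_coupling),
        artifacts=artifacts,
        seed=config.seed,
        dyad_index=dyad_index,
    )
    return session, truth


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Simulate ``n_dyads`` sessions with counterbalanced episode order."""
    if config.n_dyads < 2:
        raise ValueError("a cohort needs at least 2 dyads")
    sessions, truths, rows = [], [], []
    for i in range(config.n_dyads):
        session, truth = simulate_session(config, i)
        sessions.append(session)
        truths.append(truth)
        m = session.meta
        rows.append(
            {
                "dyad_id": m.dyad_id,
                "video_order": m.video_order,
                "participant_a": m.participant_a,
                "participant_b": m.participant_b,
                "is_real": m.is_real,
            }
        )
    return SimulatedCohort(sessions=sessions, truths=truths, meta=pd.DataFrame(rows))
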