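"""Wavelet transform coherence between two activation signals.

Continuous analytic Morlet transform (omega0 = 6) over dyadic scales,
cross-spectrum smoothed in time (scale-proportional Gaussian) and in scale
(0.6-octave boxcar), squared coherence

    r2 = |S(Wxy / s)|^2 / (S(|Wx|^2 / s) * S(|Wy|^2 / s))

with the cone of influence taken at the wavelet's e-folding time.  Smoothing
uses identical positive weights for the cross- and auto-spectra, so r2 is in
[0, 1] by the Cauchy-Schwarz inequality; without smoothing it would be
identically 1.

Band summaries average r2 over the cells of one frequency band, by default
excluding cells below the cone of influence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

OMEGA0 = 6.0
#: Fourier factor: period = FOURIER_FACTOR * scale for the Morlet wavelet
FOURIER_FACTOR = 4.0 * np.pi / (OMEGA0 + np.sqrt(2.0 + OMEGA0**2))
DEFAULT_DJ = 1.0 / 12.0  # 12 voices per octave
SCALE_SMOOTH_OCTAVES = 0.6
#: Time-smoothing Gaussian SD in units of scale.  Two scales per SD keeps the
#: no-coupling coherence floor near the 0.2-0.3 level typical of published
#: dyadic fNIRS baselines while leaving self-coherence at 1.
TIME_SMOOTH_SCALE_FACTOR = 2.0
MIN_SAMPLES = 64


@dataclass(frozen=True)
class FrequencyBand:
    """Half-open frequency interval [lo, hi) in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self):
        if not self.lo < self.hi:
            raise ValueError("band requires lo < hi")


#: The three analysis bands; together they tile [0.02, 0.2) Hz.
DEFAULT_BANDS: tuple[FrequencyBand, ...] = (
    FrequencyBand("high", 0.1, 0.2),
    FrequencyBand("medium", 0.03, 0.1),
    FrequencyBand("low", 0.02, 0.03),
)


def band_by_name(name: str) -> FrequencyBand:
    for b in DEFAULT_BANDS:
        if b.name == name:
            return b
    raise KeyError(f"unknown band {name!r}; expected one of "
                   f"{[b.name for b in DEFAULT_BANDS]}")


def extract_trial(
    x: np.ndarray, events: pd.DataFrame, phase: str, fs: float
) -> np.ndarray:
    """Cut the samples of one phase out of a full-session series.

    ``events`` has columns onset_s, duration_s, phase_label.  The segment is
    the half-open sample range [round(onset*fs), round((onset+duration)*fs))
    with round-half-to-even.
    """
    hit = events[events["phase_label"] == phase]
    if hit.empty:
        raise KeyError(
            f"phase {phase!r} not found; available: "
            f"{sorted(events['phase_label'].unique())}"
        )
    onset = float(hit["onset_s"].iloc[0])
    duration = float(hit["duration_s"].iloc[0])
    start = int(np.round(onset * fs))
    end = int(np.round((onset + duration) * fs))
    x = np.asarray(x)
    if not 0 <= start <= end <= x.shape[-1]:
        raise ValueError(
            f"trial window [{start}, {end}) outside series of length {x.shape[-1]}"
        )
    return x[..., start:end]


@dataclass
class CoherenceSpectrogram:
    """Time-frequency squared coherence with cone of influence.

    ``frequencies`` are in descending order (smallest scale first).  ``coi``
    holds, per time point, the lowest frequency unaffected by edge effects;
    cells with frequency below ``coi[t]`` lie outside the cone and are
    unreliable.
    """

    frequencies: np.ndarray
    times: np.ndarray
    r2: np.ndarray  # (frequencies, times)
    coi: np.ndarray  # per-time frequency boundary

    def in_coi_mask(self) -> np.ndarray:
        """Boolean (freq, time) mask of cells inside the reliable region."""
        return self.frequencies[:, None] >= self.coi[None, :]


class WaveletTransform:
    """Morlet CWT of one series, cached for pairwise coherence.

    Precomputes the transform, the smoothed autospectrum and the COI so a
    participant's transform can be reused across every dyad pairing.
    """

    def __init__(self, x: np.ndarray, fs: float, dj: float = DEFAULT_DJ):
        x = np.asarray(x, float)
        if x.ndim != 1:
            raise ValueError("expected a 1-D series")
        if len(x) < MIN_SAMPLES:
            raise ValueError(f"need at least {MIN_SAMPLES} samples, got {len(x)}")
        if not np.isfinite(x).all():
            raise ValueError("series contains non-finite values")
        self.n = len(x)
        self.fs = float(fs)
        self.dt = 1.0 / fs
        self.dj = dj

        s0 = 2.0 * self.dt
        jmax = int(np.floor(np.log2(self.n * self.dt / s0) / dj))
        self.scales = s0 * 2.0 ** (dj * np.arange(jmax + 1))
        self.frequencies = 1.0 / (FOURIER_FACTOR * self.scales)
        self.times = np.arange(self.n) * self.dt

        nfft = int(2 ** np.ceil(np.log2(self.n)))
        self._nfft = nfft
        xhat = np.fft.fft(x - x.mean(), nfft)
        omega = 2.0 * np.pi * np.fft.fftfreq(nfft, self.dt)
        # analytic Morlet daughter in the frequency domain
        arg = self.scales[:, None] * omega[None, :]
        psi = (np.pi**-0.25) * np.exp(-0.5 * (arg - OMEGA0) ** 2) * (omega[None, :] > 0)
        norm = np.sqrt(2.0 * np.pi * self.scales / self.dt)
        self.W = np.fft.ifft(xhat[None, :] * psi * norm[:, None], axis=1)[:, : self.n]

        # e-folding time sqrt(2)*s -> per-time lowest reliable frequency
        edge = np.minimum(np.arange(self.n), np.arange(self.n)[::-1]) * self.dt
        coi_period = FOURIER_FACTOR / np.sqrt(2.0) * edge
        with np.errstate(divide="ignore"):
            self.coi = np.where(coi_period > 0, 1.0 / np.maximum(coi_period, 1e-300), np.inf)

        self._auto: np.ndarray | None = None

    # -- smoothing -------------------------------------------------------
    def _smooth(self, field: np.ndarray) -> np.ndarray:
        """Grinsted-style smoothing: Gaussian in time (SD = scale), boxcar
        over 0.6 octave in scale.  Weights are positive and identical for
        every field smoothed against this transform."""
        nfft = self._nfft
        fhat = np.fft.fft(field, nfft, axis=1)
        omega = 2.0 * np.pi * np.fft.fftfreq(nfft, self.dt)
        gauss = np.exp(
            -0.5 * (TIME_SMOOTH_SCALE_FACTOR * self.scales[:, None] * omega[None, :]) ** 2
        )
        out = np.fft.ifft(fhat * gauss, axis=1)[:, : self.n]
        if not np.iscomplexobj(field):
            out = out.real

        width = SCALE_SMOOTH_OCTAVES / self.dj  # e.g. 7.2 voices
        nfull = int(np.floor(width))
        frac = (width - nfull) / 2.0
        kernel = np.concatenate([[frac], np.ones(nfull), [frac]]) / width
        if len(kernel) % 2 == 0:  # keep 'same' convolution centred
            kernel = np.concatenate([kernel, [0.0]])
        # normalised 'same' convolution along the scale axis (shift-and-add,
        # which stays cheap and supports complex fields)
        k = len(kernel)
        pad = k // 2
        nsc = out.shape[0]
        padded = np.zeros((nsc + k - 1, out.shape[1]), dtype=out.dtype)
        padded[pad : pad + nsc] = out
        sm = sum(kernel[i] * padded[i : i + nsc] for i in range(k))
        ones = np.zeros(nsc + k - 1)
        ones[pad : pad + nsc] = 1.0
        denom = sum(kernel[i] * ones[i : i + nsc] for i in range(k))
        return sm / denom[:, None]

    @property
    def smoothed_auto(self) -> np.ndarray:
        if self._auto is None:
            self._auto = self._smooth(np.abs(self.W) ** 2 / self.scales[:, None])
        return self._auto


def wtc_from_transforms(tx: WaveletTransform, ty: WaveletTransform) -> CoherenceSpectrogram:
    """Squared wavelet coherence from two precomputed transforms."""
    if tx.n != ty.n or tx.fs != ty.fs:
        raise ValueError("transforms must share length and sampling rate")
    cross = tx._smooth(tx.W * np.conj(ty.W) / tx.scales[:, None])
    denom = tx.smoothed_auto * ty.smoothed_auto
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.abs(cross) ** 2 / denom
    r2 = np.clip(np.nan_to_num(r2, nan=0.0), 0.0, 1.0)
    return CoherenceSpectrogram(
        frequencies=tx.frequencies.copy(),
        times=tx.times.copy(),
        r2=r2,
        coi=np.minimum(tx.coi, ty.coi),
    )


def wtc(x: np.ndarray, y: np.ndarray, fs: float, dj: float = DEFAULT_DJ) -> CoherenceSpectrogram:
    """Wavelet transform coherence between two equal-length series."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    return wtc_from_transforms(WaveletTransform(x, fs, dj), WaveletTransform(y, fs, dj))


@dataclass
class BandCoherenceValue:
    """Mean squared coherence of one trial in one frequency band."""

    value: float
    band: str
    coi_excluded_fraction: float
    n_cells: int


def band_average(
    spec: CoherenceSpectrogram,
    band: FrequencyBand,
    exclude_coi: bool = True,
) -> BandCoherenceValue:
    """Arithmetic mean of r2 over in-band (and, optionally, in-COI) cells."""
    inband = (spec.frequencies >= band.lo) & (spec.frequencies < band.hi)
    if not inband.any():
        raise ValueError(
            f"band {band.name} [{band.lo}, {band.hi}) Hz outside the resolvable "
            f"frequency range [{spec.frequencies.min():.4g}, "
            f"{spec.frequencies.max():.4g}] Hz"
        )
    cells = spec.r2[inband]
    total = cells.size
    if exclude_coi:
        mask = spec.in_coi_mask()[inband]
        eligible = cells[mask]
        excluded_fraction = 1.0 - eligible.size / total
        if eligible.size == 0:
            raise ValueError(
                f"band {band.name}: every in-band cell lies outside the cone of "
                "influence for this trial length"
            )
    else:
        eligible = cells.ravel()
        excluded_fraction = 0.0
    return BandCoherenceValue(
        value=float(eligible.mean()),
        band=band.name,
        coi_excluded_fraction=float(excluded_fraction),
        n_cells=int(eligible.size),
    )


def dyad_measures(v1: BandCoherenceValue, v2: BandCoherenceValue) -> Mapping[str, float]:
    """Per-dyad summary measures from the two co-watching trials.

    ``cowatch1`` is the first-video coherence, ``change`` the second minus the
    first (the conversation effect), ``mean`` their average (kept only for
    supplementary-style summaries).
    """
    if v1.band != v2.band:
        raise ValueError(f"band mismatch: {v1.band} vs {v2.band}")
    return {
        "cowatch1": v1.value,
        "change": v2.value - v1.value,
        "mean": 0.5 * (v1.value + v2.value),
    }
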