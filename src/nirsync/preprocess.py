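"""Raw intensity -> CBSI activation signal.

The fixed stage order is: optical density, wavelet motion correction,
band-pass filtering, modified Beer-Lambert inversion, CBSI combination.
Every stage preserves the (channels, samples) layout.

Concentrations carry an arbitrary absolute scale (the extinction table and
DPF fix the units, but wavelet coherence downstream is scale-invariant).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt
from scipy import signal as sps

WAVELENGTHS_NM = (780.0, 805.0, 830.0)

# Molar extinction coefficients, cm^-1 / (mol/L), compiled from the
# Prahl/OMLC tabulation of Hb spectra at the three instrument wavelengths.
# Rows follow WAVELENGTHS_NM; columns are (HbO2, HbR).
EXTINCTION = np.array(
    [
        [735.4, 1104.0],  # 780 nm
        [880.0, 851.6],  # 805 nm (near-isosbestic)
        [974.0, 693.2],  # 830 nm
    ]
)


@dataclass
class RawIntensity:
    """Raw light intensities, shape (channels, samples, 3 wavelengths)."""

    values: np.ndarray
    fs: float
    channel_ids: np.ndarray
    wavelengths: tuple[float, float, float] = WAVELENGTHS_NM

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        self.channel_ids = np.asarray(self.channel_ids)
        if self.values.ndim != 3 or self.values.shape[2] != 3:
            raise ValueError("intensity array must be (channels, samples, 3)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class OpticalDensity:
    values: np.ndarray  # (channels, samples, 3), dimensionless
    fs: float
    channel_ids: np.ndarray


@dataclass
class ConcentrationSignals:
    """Hemoglobin concentration changes in uM, shape (channels, samples)."""

    hbo: np.ndarray
    hbr: np.ndarray
    fs: float
    channel_ids: np.ndarray
    dpf: tuple[float, float, float] = (6.0, 6.0, 6.0)


@dataclass
class ActivationSignal:
    """Per-channel CBSI activation x = (HbO - alpha*HbR)/2, alpha = sd ratio."""

    values: np.ndarray  # (channels, samples)
    alpha: np.ndarray  # per channel
    fs: float
    channel_ids: np.ndarray
    degenerate: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.degenerate is None:
            self.degenerate = np.zeros(self.values.shape[0], bool)

    def channel(self, channel_id: int) -> np.ndarray:
        idx = int(np.flatnonzero(self.channel_ids == channel_id)[0])
        return self.values[idx]


def intensity_to_od(raw: RawIntensity) -> OpticalDensity:
    """OD(t) = -ln(I(t) / temporal mean of I), per channel and wavelength."""
    vals = raw.values
    bad = ~(vals > 0)
    if bad.any():
        ch, t, wl = (int(v) for v in np.argwhere(bad)[0])
        raise ValueError(
            f"non-positive intensity at channel {raw.channel_ids[ch]}, "
            f"sample {t}, wavelength {raw.wavelengths[wl]:g} nm"
        )
    od = -np.log(vals / vals.mean(axis=1, keepdims=True))
    return OpticalDensity(values=od, fs=raw.fs, channel_ids=raw.channel_ids)


def _wavelet_despike(x: np.ndarray, wavelet: str, iqr_factor: float) -> np.ndarray:
    level = pywt.dwt_max_level(len(x), pywt.Wavelet(wavelet).dec_len)
    if level < 1:
        warnings.warn("series too short for wavelet motion correction; passing through")
        return x.copy()
    coeffs = pywt.wavedec(x, wavelet, level=level)
    out = [coeffs[0]]
    for d in coeffs[1:]:
        q1, q3 = np.percentile(d, [25, 75])
        iqr = q3 - q1
        lo, hi = q1 - iqr_factor * iqr, q3 + iqr_factor * iqr
        dd = d.copy()
        dd[(dd < lo) | (dd > hi)] = 0.0
        out.append(dd)
    rec = pywt.waverec(out, wavelet)
    return rec[: len(x)]


def motion_correct_wavelet(
    od: OpticalDensity, iqr_factor: float = 1.5, wavelet: str = "db5"
) -> OpticalDensity:
    """Suppress motion artifacts by zeroing outlying detail coefficients.

    Each channel/wavelength series is decomposed with a discrete wavelet
    transform (Daubechies-5, maximum dyadic depth); detail coefficients
    outside [Q1 - f*IQR, Q3 + f*IQR] of their level are set to zero before
    reconstruction.
    """
    if iqr_factor <= 0:
        raise ValueError("iqr_factor must be positive")
    if not np.isfinite(od.values).all():
        raise ValueError("optical density contains non-finite values")
    out = np.empty_like(od.values)
    for c in range(od.values.shape[0]):
        for w in range(od.values.shape[2]):
            out[c, :, w] = _wavelet_despike(od.values[c, :, w], wavelet, iqr_factor)
    return OpticalDensity(values=out, fs=od.fs, channel_ids=od.channel_ids)


def bandpass(
    od: OpticalDensity, lo: float = 0.01, hi: float = 0.4, order: int = 5
) -> OpticalDensity:
    """Zero-phase Butterworth band-pass, applied per channel/wavelength."""
    nyq = od.fs / 2.0
    if not 0 < lo < hi:
        raise ValueError("need 0 < lo < hi")
    if hi >= nyq:
        raise ValueError(f"upper edge {hi} Hz must be below Nyquist {nyq:g} Hz")
    sos = sps.butter(order, [lo, hi], btype="bandpass", output="sos", fs=od.fs)
    # generous reflect-padding keeps low-frequency edge transients out of band
    padlen = int(min(od.values.shape[1] - 1, round(3 * od.fs / lo)))
    out = sps.sosfiltfilt(sos, od.values, axis=1, padlen=padlen)
    return OpticalDensity(values=out, fs=od.fs, channel_ids=od.channel_ids)


def mbll_matrix(
    source_detector_distance_cm: float = 3.0,
    dpf: tuple[float, float, float] = (6.0, 6.0, 6.0),
) -> np.ndarray:
    """3x2 forward matrix mapping (dHbO, dHbR) in uM to OD at each wavelength."""
    dpf = np.asarray(dpf, float)
    if np.any(dpf <= 0):
        raise ValueError("DPF entries must be positive")
    # 1e-6: concentrations expressed in micromolar
    A = EXTINCTION * source_detector_distance_cm * dpf[:, None] * 1e-6
    if np.linalg.matrix_rank(A) < 2:
        raise ValueError("extinction matrix is singular; check wavelength table")
    return A


def od_to_concentration(
    od: OpticalDensity,
    source_detector_distance_cm: float = 3.0,
    dpf: tuple[float, float, float] = (6.0, 6.0, 6.0),
) -> ConcentrationSignals:
    """Invert the modified Beer-Lambert law by least squares over wavelengths.

    Solves OD(lambda, t) = [eps_HbO(lambda) dHbO + eps_HbR(lambda) dHbR]
    * d * DPF(lambda) for each channel, yielding uM concentration changes.
    """
    A = mbll_matrix(source_detector_distance_cm, dpf)
    pinv = np.linalg.pinv(A)  # (2, 3)
    # values: (C, T, 3) -> concentrations (C, T, 2)
    conc = np.einsum("kw,ctw->ctk", pinv, od.values)
    return ConcentrationSignals(
        hbo=conc[:, :, 0],
        hbr=conc[:, :, 1],
        fs=od.fs,
        channel_ids=od.channel_ids,
        dpf=tuple(float(v) for v in dpf),
    )


def cbsi(conc: ConcentrationSignals) -> ActivationSignal:
    """Correlation-based signal improvement.

    Per channel: alpha = sd(HbO)/sd(HbR); x = (HbO - alpha*HbR)/2.  A channel
    with sd(HbR) = 0 is flagged degenerate (alpha undefined) and should be
    excluded downstream.
    """
    sd_o = conc.hbo.std(axis=1)
    sd_r = conc.hbr.std(axis=1)
    degenerate = sd_r == 0
    alpha = np.where(degenerate, np.nan, sd_o / np.where(degenerate, 1.0, sd_r))
    x = 0.5 * (conc.hbo - alpha[:, None] * conc.hbr)
    x[degenerate] = np.nan
    return ActivationSignal(
        values=x,
        alpha=alpha,
        fs=conc.fs,
        channel_ids=conc.channel_ids,
        degenerate=degenerate,
    )


@dataclass
class QualityThresholds:
    snr_threshold_db: float = 4.0
    jump_iqr_factor: float = 5.0
    max_jumps: int = 30
    saturation_value: float = np.inf
    flatline_seconds: float = 1.0


def channel_quality(
    raw: RawIntensity,
    heartbeat_band: tuple[float, float] = (0.5, 2.0),
    thresholds: QualityThresholds | None = None,
) -> pd.DataFrame:
    """Automated stand-in for visual channel screening.

    A channel is included when a cardiac spectral peak is visible
    (peak power in the heartbeat band over median power in the flanking
    bands, in dB, at or above the SNR threshold), it is not light-saturated
    (no sample at the rail, no flat-line run), and its large first-difference
    jumps stay under the limit.
    """
    if thresholds is None:
        thresholds = QualityThresholds()
    if raw.n_samples / raw.fs < 60:
        raise ValueError("need at least 60 s of data for channel quality checks")
    nyq = raw.fs / 2.0
    lo, hi = heartbeat_band
    hi = min(hi, 0.95 * nyq)
    rows = []
    flat_run = max(2, int(round(thresholds.flatline_seconds * raw.fs)))
    for c in range(raw.n_channels):
        # normalise each wavelength by its mean so PSDs are comparable
        x = raw.values[c] / raw.values[c].mean(axis=0, keepdims=True)
        # short segments: heavy averaging keeps the no-peak null flat, so a
        # cardiac peak stands out against the flanking-band median
        f, psd = sps.welch(x, fs=raw.fs, nperseg=min(raw.n_samples, 256), axis=0)
        psd = psd.mean(axis=1)
        inband = (f >= lo) & (f <= hi)
        flank = ((f >= lo / 2) & (f < lo)) | ((f > hi) & (f <= min(hi * 1.5, nyq)))
        peak = psd[inband].max() if inband.any() else 0.0
        ref = np.median(psd[flank]) if flank.any() else np.nan
        snr_db = 10.0 * np.log10(peak / ref) if ref and np.isfinite(ref) and ref > 0 else -np.inf

        sat = bool((raw.values[c] >= thresholds.saturation_value).any())
        if not sat:
            # flat-line: a run of identical consecutive samples
            for w in range(raw.values.shape[2]):
                d = np.diff(raw.values[c, :, w]) == 0
                if d.any():
                    padded = np.concatenate(([False], d, [False]))
                    edges = np.diff(padded.astype(np.int8))
                    runs = np.flatnonzero(edges == -1) - np.flatnonzero(edges == 1)
                    if runs.size and runs.max() + 1 >= flat_run:
                        sat = True
                        break

        diffs = np.diff(raw.values[c], axis=0)
        q1, q3 = np.percentile(diffs, [25, 75])
        iqr = q3 - q1
        if iqr == 0:
            jumps = int((np.abs(diffs) > 0).sum())
        else:
            thr = thresholds.jump_iqr_factor * iqr
            jumps = int((np.abs(diffs) > thr).any(axis=1).sum())

        included = (
            (snr_db >= thresholds.snr_threshold_db)
            and not sat
            and jumps <= thresholds.max_jumps
        )
        rows.append(
            {
                "channel": raw.channel_ids[c],
                "heartbeat_snr_db": float(snr_db),
                "saturation_flag": sat,
                "motion_jump_count": jumps,
                "included": bool(included),
            }
        )
    return pd.DataFrame(rows)


def preprocess_to_activation(
    raw: RawIntensity,
    iqr_factor: float = 1.5,
    band: tuple[float, float] = (0.01, 0.4),
    filter_order: int = 5,
    source_detector_distance_cm: float = 3.0,
    dpf: tuple[float, float, float] = (6.0, 6.0, 6.0),
) -> ActivationSignal:
    """Run the full fixed-order pipeline on one participant's recording."""
    od = intensity_to_od(raw)
    od = motion_correct_wavelet(od, iqr_factor=iqr_factor)
    od = bandpass(od, lo=band[0], hi=band[1], order=filter_order)
    conc = od_to_concentration(od, source_detector_distance_cm, dpf)
    return cbsi(conc)
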