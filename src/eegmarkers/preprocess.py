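"""Filtering, average referencing, validity accounting and resampling.

The filter chain reproduces a conventional clinical-EEG design: a 45 Hz
linear-phase FIR lowpass whose order equals twice the sampling rate, and a
0.4 Hz 5th-order Butterworth highpass whose analog magnitude response
attenuates 0.5 Hz activity by only ~0.44 dB while strongly suppressing
slower drift.  Filters are applied zero-phase by default (forward-backward
for the Butterworth; the symmetric FIR is inherently linear-phase and is
applied centered).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .records import EEGRecord


@dataclass(frozen=True)
class FilterSpec:
    lowpass_hz: float = 45.0
    highpass_hz: float = 0.4
    highpass_order: int = 5
    #: FIR length rule: order = 2 x sampling rate (Hamming-windowed design)
    fir_order_factor: float = 2.0
    zero_phase: bool = True


@dataclass(frozen=True)
class ValidityPolicy:
    """Data-sufficiency rules tied to the lowest analysis frequency.

    A recording is usable when at least ``min_valid_windows`` windows of
    ``lowest_frequency_window_s`` seconds (hopping by
    ``1 - overlap_fraction`` of the window) each contain at least
    ``window_usable_fraction`` usable samples.
    """

    min_valid_windows: int = 15
    window_usable_fraction: float = 0.80
    lowest_frequency_window_s: float = 10.9
    overlap_fraction: float = 0.75

    @property
    def hop_s(self) -> float:
        return (1.0 - self.overlap_fraction) * self.lowest_frequency_window_s

    @property
    def min_required_s(self) -> float:
        """Analytic minimum usable duration: the span of the minimum number
        of overlapping windows, scaled by the usable fraction."""
        span = (self.lowest_frequency_window_s
                + (self.min_valid_windows - 1) * self.hop_s)
        return self.window_usable_fraction * span


def highpass_attenuation_db(freq_hz: float, spec: FilterSpec = FilterSpec()) -> float:
    """Single-pass magnitude attenuation (dB) of the analog Butterworth
    highpass prototype at ``freq_hz``.

    For an order-n Butterworth highpass with cutoff fc the magnitude is
    ``|H| = 1/sqrt(1 + (fc/f)^(2n))``.
    """
    ratio = spec.highpass_hz / freq_hz
    return 10.0 * math.log10(1.0 + ratio ** (2 * spec.highpass_order))


def bandpass_array(
    x: np.ndarray, fs: float, spec: FilterSpec = FilterSpec()
) -> np.ndarray:
    """Apply the lowpass-FIR + highpass-Butterworth chain to an array.

    Works on 1-D signals or (channels, samples) arrays.
    """
    if fs <= 2 * spec.lowpass_hz:
        raise ValueError(
            f"sampling rate {fs} Hz too low for a {spec.lowpass_hz} Hz "
            f"lowpass of order {spec.fir_order_factor} x fs"
        )
    numtaps = int(round(spec.fir_order_factor * fs)) + 1
    if numtaps % 2 == 0:
        numtaps += 1  # keep the kernel symmetric about an integer delay
    fir = sps.firwin(numtaps, spec.lowpass_hz, fs=fs, window="hamming")
    x = np.asarray(x, dtype=np.float64)
    was_1d = x.ndim == 1
    x = np.atleast_2d(x)
    # symmetric FIR applied centered == zero phase
    pad = numtaps // 2
    ext = np.pad(x, [(0, 0), (pad, pad)], mode="reflect")
    y = sps.fftconvolve(ext, fir[None, :], mode="same", axes=-1)[:, pad:-pad]
    sos = sps.butter(
        spec.highpass_order, spec.highpass_hz / (fs / 2.0), "highpass",
        output="sos",
    )
    if spec.zero_phase:
        y = sps.sosfiltfilt(sos, y, axis=-1)
    else:
        y = sps.sosfilt(sos, y, axis=-1)
    return y[0] if was_1d else y


def bandpass(record: EEGRecord, spec: FilterSpec = FilterSpec()) -> EEGRecord:
    """Return a filtered copy of the record; the artifact mask is unchanged."""
    filtered = bandpass_array(record.data, record.fs, spec)
    return record.copy_with(data=np.atleast_2d(filtered))


def average_reference(record: EEGRecord) -> EEGRecord:
    """Re-reference to the instantaneous channel mean."""
    if record.n_channels < 2:
        raise ValueError("average reference requires at least 2 channels")
    data = record.data - record.data.mean(axis=0, keepdims=True)
    return record.copy_with(data=data)


def check_sufficiency(
    record: EEGRecord, policy: ValidityPolicy = ValidityPolicy()
) -> dict:
    """Count valid lowest-frequency windows and report usability.

    A window is valid when at least ``window_usable_fraction`` of its
    samples are usable per the artifact mask.  Windows hop by
    ``(1 - overlap) * window length`` starting at sample 0; a trailing
    partial window is not counted.
    """
    win = int(round(policy.lowest_frequency_window_s * record.fs))
    hop = max(int(round(policy.hop_s * record.fs)), 1)
    mask = record.artifact_mask.astype(np.float64)
    n_valid = 0
    n_windows = 0
    start = 0
    csum = np.concatenate(([0.0], np.cumsum(mask)))
    while start + win <= record.n_samples:
        frac = (csum[start + win] - csum[start]) / win
        n_windows += 1
        if frac >= policy.window_usable_fraction - 1e-12:
            n_valid += 1
        start += hop
    return {
        "usable": n_valid >= policy.min_valid_windows,
        "n_valid_windows": n_valid,
        "n_windows": n_windows,
        "min_required_s": round(policy.min_required_s, 1),
    }


def resample_array(x: np.ndarray, fs: float, target_fs: float) -> np.ndarray:
    """Polyphase anti-aliased resampling of a 1-D or (channels, samples) array."""
    if target_fs > fs:
        raise ValueError("target rate must not exceed the original rate")
    if target_fs == fs:
        return np.asarray(x, dtype=np.float64).copy()
    frac = Fraction(target_fs / fs).limit_denominator(1000)
    return sps.resample_poly(np.asarray(x, dtype=np.float64), frac.numerator,
                             frac.denominator, axis=-1)


def resample_mask(mask: np.ndarray, fs: float, target_fs: float,
                  n_out: int) -> np.ndarray:
    """Downsample a usability mask: an output sample is usable only if every
    original sample in its footprint is usable (logical AND)."""
    if target_fs == fs:
        return mask.copy()
    ratio = fs / target_fs
    n_in = len(mask)
    out = np.empty(n_out, dtype=bool)
    for i in range(n_out):
        lo = int(math.floor(i * ratio))
        hi = max(int(math.ceil((i + 1) * ratio)), lo + 1)
        out[i] = mask[lo:min(hi, n_in)].all() if lo < n_in else False
    return out


def downsample(record: EEGRecord, target_fs: float) -> EEGRecord:
    """Anti-aliased downsampling of data and conservative mask resampling."""
    data = resample_array(record.data, record.fs, target_fs)
    data = np.atleast_2d(data)
    mask = resample_mask(record.artifact_mask, record.fs, target_fs,
                         data.shape[1])
    return record.copy_with(data=data, artifact_mask=mask, fs=float(target_fs))
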