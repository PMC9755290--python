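"""Morlet-wavelet band power, dwPLI connectivity, and spectral peak picking.

Power spectral densities are estimated with 7-cycle complex Morlet wavelets
at 49 logarithmically spaced frequencies (8 per octave, 0.5-32 Hz,
endpoints inclusive).  Band powers integrate the PSD with the trapezoid
rule on that grid in six octave bands with inclusive lower and exclusive
upper bounds; relative powers are normalized by the integrated broadband
power.  Connectivity uses the debiased weighted phase-lag index (dwPLI)
estimated from per-window cross-spectral densities (2-s Hamming segments,
50% overlap, inside 5-s windows), with windows as observations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .montage import PairClassification
from .records import EEGRecord

__all__ = [
    "WaveletGrid", "BandSet", "PairClassification",
    "morlet_psd", "band_power", "dwpli", "spectral_peak",
]


@dataclass(frozen=True)
class WaveletGrid:
    """Log-spaced wavelet frequency grid with per-frequency window lengths."""

    f_min: float = 0.5
    f_max: float = 32.0
    per_octave: int = 8
    n_cycles: float = 7.0
    truncate_sd: float = 2.5     # kernel support: +/- this many Gaussian SDs
    overlap: float = 0.75

    @property
    def frequencies(self) -> np.ndarray:
        n_oct = np.log2(self.f_max / self.f_min)
        n = int(round(n_oct * self.per_octave)) + 1
        return self.f_min * 2.0 ** (np.arange(n) / self.per_octave)

    def sigma_t(self, f: float) -> float:
        return self.n_cycles / (2.0 * np.pi * f)

    def window_s(self, f: float) -> float:
        """Kernel support in seconds (also the validity-window length)."""
        return 2.0 * self.truncate_sd * self.sigma_t(f)


@dataclass(frozen=True)
class BandSet:
    """Octave bands; lower bounds inclusive, upper bounds exclusive."""

    bands: tuple[tuple[str, float, float], ...] = (
        ("s", 0.5, 1.0),
        ("delta1", 1.0, 2.0),
        ("delta2", 2.0, 4.0),
        ("theta", 4.0, 8.0),
        ("alpha_sigma", 8.0, 16.0),
        ("beta", 16.0, 32.0),
    )

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _, _ in self.bands)


def _morlet_kernel(f: float, fs: float, grid: WaveletGrid) -> np.ndarray:
    """Unit-energy complex Morlet kernel at frequency ``f``."""
    sigma = grid.sigma_t(f)
    half = int(round(grid.truncate_sd * sigma * fs))
    t = np.arange(-half, half + 1) / fs
    kern = np.exp(-0.5 * (t / sigma) ** 2) * np.exp(2j * np.pi * f * t)
    kern -= kern.mean()  # zero-mean correction for low-f kernels
    return kern / np.sqrt((np.abs(kern) ** 2).sum())


def morlet_psd(
    record: EEGRecord,
    grid: WaveletGrid = WaveletGrid(),
    min_usable: float = 0.8,
) -> np.ndarray:
    """Per-channel PSD (uV^2/Hz) on the wavelet grid, shape (n_ch, n_freq).

    At each frequency, wavelet power is averaged over samples belonging to
    valid analysis windows (window length = kernel support, 75% overlap, at
    least 80% usable samples, fully inside the unpadded signal).  Entries
    are NaN for frequencies with no valid window.
    """
    data = record.data
    fs = record.fs
    n = record.n_samples
    freqs = grid.frequencies
    psd = np.full((record.n_channels, len(freqs)), np.nan)
    mask = record.artifact_mask
    # one padded FFT of the data, reused for every wavelet frequency
    from scipy import fft as sfft
    max_kern = int(2 * round(grid.truncate_sd * grid.sigma_t(freqs[0]) * fs)) + 1
    nfft = sfft.next_fast_len(n + max_kern)
    data_spec = sfft.fft(data, nfft, axis=-1)
    for fi, f in enumerate(freqs):
        kern = _morlet_kernel(f, fs, grid)
        half = len(kern) // 2
        if len(kern) > n:
            continue
        kspec = sfft.fft(kern, nfft)
        W = sfft.ifft(data_spec * kspec[None, :], axis=-1)[:, half:half + n]
        power = (W.real ** 2 + W.imag ** 2)
        # valid-sample mask: usable and away from the convolution edges
        ok = mask.copy()
        ok[:half] = False
        ok[n - half:] = False
        win = len(kern)
        hop = max(int(round(win * (1.0 - grid.overlap))), 1)
        starts = np.arange(0, n - win + 1, hop)
        if len(starts) == 0:
            continue
        csum = np.concatenate(([0.0], np.cumsum(ok)))
        frac = (csum[starts + win] - csum[starts]) / win
        good = frac >= min_usable - 1e-12
        if not good.any():
            continue
        sample_sel = np.zeros(n, dtype=bool)
        for s0 in starts[good]:
            sample_sel[s0:s0 + win] = True
        sample_sel &= ok
        # scale mean |W|^2 to a one-sided density in uV^2/Hz
        psd[:, fi] = 2.0 * power[:, sample_sel].mean(axis=1) / fs
    return psd


def band_power(
    psd: np.ndarray,
    grid: WaveletGrid = WaveletGrid(),
    bands: BandSet = BandSet(),
    relative: bool = False,
) -> np.ndarray:
    """Integrate the PSD in each band (trapezoid on the log-spaced grid).

    ``psd`` is (..., n_freq); returns (..., n_bands).  With
    ``relative=True`` each band is normalized by the total integrated
    broadband power; relative values sum to 1.
    """
    freqs = grid.frequencies
    psd = np.asarray(psd, dtype=np.float64)
    out = np.empty(psd.shape[:-1] + (len(bands.bands),))
    for bi, (_, lo, hi) in enumerate(bands.bands):
        sel = (freqs >= lo - 1e-9) & (freqs <= hi + 1e-9)
        out[..., bi] = np.trapezoid(psd[..., sel], freqs[sel], axis=-1)
    if relative:
        total = out.sum(axis=-1, keepdims=True)
        if np.any(total == 0):
            raise ValueError("relative band power undefined for zero total power")
        out = out / total
    return out


# ---------------------------------------------------------------------------
# dwPLI
# ---------------------------------------------------------------------------

def _csd_per_window(
    data: np.ndarray,
    fs: float,
    freqs: np.ndarray,
    mask: np.ndarray,
    window_s: float = 5.0,
    window_overlap: float = 0.5,
    seg_s: float = 2.0,
    seg_overlap: float = 0.5,
    min_usable: float = 0.8,
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Per-channel spectra averaged into cross-spectral observations.

    Returns the complex spectra X with shape (n_windows, n_channels,
    n_freqs), one observation per valid 5-s window; each window's spectrum
    averages Hamming-tapered direct DFTs (at the exact log-spaced
    frequencies) over its 2-s, 50%-overlapping segments.
    """
    n_ch, n = data.shape
    win = int(round(window_s * fs))
    hop = max(int(round(win * (1.0 - window_overlap))), 1)
    seg = int(round(seg_s * fs))
    seg_hop = max(int(round(seg * (1.0 - seg_overlap))), 1)
    taper = np.hamming(seg)
    t = np.arange(seg) / fs
    # (seg, n_freq) complex exponential basis
    basis = np.exp(-2j * np.pi * t[:, None] * freqs[None, :]) * taper[:, None]
    windows = []
    spectra = []
    start = 0
    while start + win <= n:
        if mask[start:start + win].mean() >= min_usable - 1e-12:
            segs = []
            s0 = start
            while s0 + seg <= start + win:
                segs.append(data[:, s0:s0 + seg])
                s0 += seg_hop
            if segs:
                block = np.stack(segs)                       # (S, ch, seg)
                X = block @ basis                            # (S, ch, F)
                spectra.append(X)
                windows.append((start, start + win))
        start += hop
    if not spectra:
        return np.empty((0, n_ch, len(freqs)), dtype=complex), []
    # cross-spectra are formed per window from segment-averaged products;
    # keep segment spectra so products average correctly
    return spectra, windows


def _dwpli_from_imag(imag_csd: np.ndarray) -> np.ndarray:
    """Debiased WPLI-square across observations (axis 0).

    ``sum_{j != k} Im(X_j) Im(X_k) / sum_{j != k} |Im(X_j) Im(X_k)|``
    computed as ((sum Im)^2 - sum Im^2) / ((sum |Im|)^2 - sum Im^2).
    """
    s = imag_csd.sum(axis=0)
    s_abs = np.abs(imag_csd).sum(axis=0)
    s_sq = (imag_csd ** 2).sum(axis=0)
    num = s ** 2 - s_sq
    den = s_abs ** 2 - s_sq
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return out


def dwpli(
    record: EEGRecord,
    pairs: PairClassification,
    grid: WaveletGrid = WaveletGrid(),
    bands: BandSet = BandSet(),
) -> dict[str, np.ndarray]:
    """Band-averaged dwPLI for short- and long-range channel pairs.

    Returns ``{"short": (n_bands,), "long": (n_bands,), "per_pair": ...}``
    where the per-pair array is (n_pairs_used, n_bands) over short pairs
    followed by long pairs.  NaN when fewer than 2 valid windows exist.
    """
    freqs = grid.frequencies
    spectra, windows = _csd_per_window(
        record.data, record.fs, freqs, record.artifact_mask
    )
    used_pairs = list(pairs.short_pairs) + list(pairs.long_pairs)
    n_bands = len(bands.bands)
    if len(windows) < 2:
        nanarr = np.full(n_bands, np.nan)
        return {"short": nanarr, "long": nanarr.copy(),
                "per_pair": np.full((len(used_pairs), n_bands), np.nan)}
    # band membership: lower-inclusive, upper-exclusive
    band_sel = [
        (freqs >= lo - 1e-9) & (freqs < hi - 1e-9) for (_, lo, hi) in bands.bands
    ]
    per_pair = np.empty((len(used_pairs), n_bands))
    # imaginary cross-spectra per window: (n_windows, n_pairs, n_freq)
    ia = np.array([p[0] for p in used_pairs])
    ib = np.array([p[1] for p in used_pairs])
    imag = np.empty((len(spectra), len(used_pairs), len(freqs)))
    mag = np.empty_like(imag)
    for wi, X in enumerate(spectra):
        # X: (S, ch, F); average the cross product over segments
        cross = (X[:, ia, :] * np.conj(X[:, ib, :])).mean(axis=0)
        imag[wi] = cross.imag
        mag[wi] = np.abs(cross)
    dw = _dwpli_from_imag(imag)                 # (n_pairs, n_freq)
    # a numerically-zero imaginary part (e.g. perfectly zero-lag channels)
    # means no measurable phase lag: report 0 rather than roundoff noise
    negligible = np.abs(imag).sum(axis=0) < 1e-9 * mag.sum(axis=0)
    dw = np.where(negligible, 0.0, dw)
    for bi, sel in enumerate(band_sel):
        per_pair[:, bi] = dw[:, sel].mean(axis=1)
    n_short = len(pairs.short_pairs)
    return {
        "short": per_pair[:n_short].mean(axis=0) if n_short else
        np.full(n_bands, np.nan),
        "long": per_pair[n_short:].mean(axis=0) if len(pairs.long_pairs) else
        np.full(n_bands, np.nan),
        "per_pair": per_pair,
    }


# ---------------------------------------------------------------------------
# spectral peak
# ---------------------------------------------------------------------------

def spectral_peak(
    psd: np.ndarray,
    grid: WaveletGrid = WaveletGrid(),
    prominence: float = 0.35,
) -> float | None:
    """Frequency (Hz) of the strongest spectral peak above the 1/f trend.

    The channel-averaged PSD is log-scaled, a log-log linear background is
    fit by least squares and subtracted, and local maxima of the residual
    are located; the peak with the greatest residual power is returned, or
    None when no local maximum reaches the prominence threshold (in log10
    power units).  A simplified stand-in for full spectral
    parameterization.
    """
    psd = np.asarray(psd, dtype=np.float64)
    if psd.ndim == 2:
        psd = np.nanmean(psd, axis=0)
    freqs = grid.frequencies
    ok = np.isfinite(psd) & (psd > 0)
    if ok.sum() < 5:
        return None
    logf = np.log10(freqs[ok])
    logp = np.log10(psd[ok])
    slope, intercept = np.polyfit(logf, logp, 1)
    resid = logp - (slope * logf + intercept)
    peaks, props = sps.find_peaks(resid, prominence=prominence)
    if len(peaks) == 0:
        return None
    best = peaks[np.argmax(resid[peaks])]
    return float(freqs[ok][best])
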