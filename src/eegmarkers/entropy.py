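"""Entropy and complexity estimators for EEG signals.

Five estimators are provided, all invariant to positive affine amplitude
transforms of the input by construction (ordinal- or median-based, or
computed on standardized series):

* permutation entropy (PermEn) of ordinal patterns with embedding
  dimension ``m`` and sample delay ``tau``, normalized to [0, 1];
* weighted symbolic mutual information (wSMI) between two channels'
  ordinal-pattern streams, with identical and sign-opposite pattern pairs
  zero-weighted to suppress volume-conduction artifacts, and normalized by
  the channels' local (unnormalized) permutation entropies;
* modified multiscale sample entropy (mMSE): sample entropy with a
  sigmoidal neighbor membership on coarse-grained, per-scale standardized
  series, averaged over the first block of timescales;
* Lempel-Ziv-76 phrase-count complexity of the median-binarized signal,
  normalized by N / log2(N);
* context-tree-weighting (CTW) entropy rate in bits per symbol of the
  median-binarized signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import permutations

import numpy as np

from ._fast import ctw_log2_prob, lz76_phrase_count

# ---------------------------------------------------------------------------
# ordinal patterns
# ---------------------------------------------------------------------------

PERMEN_TAUS_MS = (8.0, 16.0, 32.0, 64.0, 128.0)
PERMEN_FS = 125.0  # Hz; symbolic measures are computed at this rate


@lru_cache(maxsize=None)
def _pattern_tables(m: int) -> tuple[np.ndarray, np.ndarray]:
    """(code->symbol lookup over base-m rank codes, symbol->opposite symbol).

    A window's rank vector (r_0 .. r_{m-1}), with ties broken by temporal
    order, is encoded as a base-m integer; the lookup maps the m! valid
    codes onto compact symbols 0..m!-1 (lexicographic order of rank
    vectors).  The opposite of a pattern is the pattern of the negated
    window, i.e. ranks (m-1) - r.
    """
    perms = sorted(permutations(range(m)))
    powers = m ** np.arange(m - 1, -1, -1)
    code_to_symbol = np.full(m ** m, -1, dtype=np.int64)
    for sym, ranks in enumerate(perms):
        code_to_symbol[int(np.dot(ranks, powers))] = sym
    opposite = np.empty(len(perms), dtype=np.int64)
    index = {ranks: sym for sym, ranks in enumerate(perms)}
    for sym, ranks in enumerate(perms):
        opposite[sym] = index[tuple(m - 1 - r for r in ranks)]
    return code_to_symbol, opposite


@dataclass
class SymbolicSeries:
    """Ordinal-pattern symbol stream with its embedding provenance.

    ``symbols[t]`` encodes the rank pattern of samples
    ``(x_t, x_{t+tau}, ..., x_{t+(m-1)tau})``.
    """

    symbols: np.ndarray
    m: int
    tau_samples: int
    fs: float | None = None

    @property
    def tau_ms(self) -> float | None:
        return None if self.fs is None else 1000.0 * self.tau_samples / self.fs

    @property
    def alphabet_size(self) -> int:
        return math.factorial(self.m)

    @property
    def opposite_map(self) -> np.ndarray:
        return _pattern_tables(self.m)[1]


def symbolize_batch(X: np.ndarray, m: int, tau_samples: int) -> np.ndarray:
    """Ordinal symbols for a batch of signals, shape (B, n) -> (B, L).

    Ranks are assigned with the stable tie-break: of two equal samples the
    earlier one receives the lower rank.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    B, n = X.shape
    span = (m - 1) * tau_samples
    L = n - span
    if L < 1:
        raise ValueError(
            f"signal of {n} samples too short for m={m}, tau={tau_samples}"
        )
    V = np.stack([X[:, k * tau_samples: k * tau_samples + L] for k in range(m)])
    ranks = np.zeros((m, B, L), dtype=np.int64)
    for i in range(m):
        for j in range(m):
            if i == j:
                continue
            if j < i:
                ranks[i] += (V[j] <= V[i])
            else:
                ranks[i] += (V[j] < V[i])
    powers = m ** np.arange(m - 1, -1, -1)
    code = np.tensordot(powers, ranks, axes=(0, 0))
    code_to_symbol, _ = _pattern_tables(m)
    return code_to_symbol[code]


def ordinal_symbolize(
    signal: np.ndarray, m: int = 3, tau_samples: int = 1,
    fs: float | None = None,
) -> SymbolicSeries:
    """Map a 1-D signal onto its ordinal-pattern symbol stream."""
    signal = np.asarray(signal, dtype=np.float64)
    if signal.ndim != 1:
        raise ValueError("ordinal_symbolize expects a 1-D signal")
    symbols = symbolize_batch(signal[None, :], m, tau_samples)[0]
    return SymbolicSeries(symbols=symbols, m=m, tau_samples=tau_samples, fs=fs)


# ---------------------------------------------------------------------------
# permutation entropy
# ---------------------------------------------------------------------------

def perm_entropy_symbols(symbols: np.ndarray, m: int = 3) -> float:
    """Normalized Shannon entropy of a symbol stream: in [0, 1]."""
    counts = np.bincount(symbols, minlength=math.factorial(m)).astype(float)
    total = counts.sum()
    if total == 0:
        return float("nan")
    p = counts[counts > 0] / total
    return float(-(p * np.log(p)).sum() / math.log(math.factorial(m)))


def perm_entropy_batch(codes: np.ndarray, m: int = 3) -> np.ndarray:
    """Row-wise normalized permutation entropy for a (B, L) symbol array."""
    B, L = codes.shape
    nsym = math.factorial(m)
    offsets = np.arange(B)[:, None] * nsym
    flat = np.bincount((codes + offsets).ravel(), minlength=B * nsym)
    counts = flat.reshape(B, nsym).astype(float)
    p = counts / L
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    return -terms.sum(axis=1) / math.log(nsym)


def _window_slices(
    n_samples: int,
    fs: float,
    window_s: float,
    overlap: float,
    mask: np.ndarray | None,
    min_usable: float = 0.8,
) -> list[tuple[int, int]]:
    win = int(round(window_s * fs))
    hop = max(int(round(win * (1.0 - overlap))), 1)
    out = []
    start = 0
    while start + win <= n_samples:
        if mask is None:
            out.append((start, start + win))
        else:
            if mask[start:start + win].mean() >= min_usable - 1e-12:
                out.append((start, start + win))
        start += hop
    return out


def perm_entropy(
    series: SymbolicSeries,
    mask: np.ndarray | None = None,
    window_s: float = 5.0,
    overlap: float = 0.5,
) -> float:
    """Windowed permutation entropy: normalized entropy per 5-s window
    (50% overlap by default), averaged across valid windows.

    ``mask`` is a per-sample usability mask aligned with the original
    signal; windows with less than 80% usable samples are dropped.  NaN is
    returned when no window is valid.
    """
    if series.fs is None:
        return perm_entropy_symbols(series.symbols, series.m)
    span = (series.m - 1) * series.tau_samples
    n_samples = len(series.symbols) + span
    values = []
    for a, b in _window_slices(n_samples, series.fs, window_s, overlap, mask):
        seg = series.symbols[a: b - span]
        if len(seg) > 0:
            values.append(perm_entropy_symbols(seg, series.m))
    return float(np.mean(values)) if values else float("nan")


# ---------------------------------------------------------------------------
# weighted symbolic mutual information
# ---------------------------------------------------------------------------

def _wsmi_window(sx: np.ndarray, sy: np.ndarray, m: int) -> float:
    nsym = math.factorial(m)
    joint = np.bincount(sx * nsym + sy, minlength=nsym * nsym).astype(float)
    joint = joint.reshape(nsym, nsym) / len(sx)
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    _, opposite = _pattern_tables(m)
    w = np.ones((nsym, nsym))
    idx = np.arange(nsym)
    w[idx, idx] = 0.0
    w[idx, opposite] = 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = joint / (px[:, None] * py[None, :])
        terms = np.where(joint > 0, joint * np.log(ratio), 0.0)
    wsmi_val = float((w * terms).sum())
    # local (unnormalized, natural-log) permutation entropies
    pex = float(-(px[px > 0] * np.log(px[px > 0])).sum())
    pey = float(-(py[py > 0] * np.log(py[py > 0])).sum())
    denom = pex + pey
    if denom == 0:
        return float("nan")
    return 2.0 * wsmi_val / denom


def wsmi(
    series_x: SymbolicSeries,
    series_y: SymbolicSeries,
    mask: np.ndarray | None = None,
    window_s: float = 5.0,
    overlap: float = 0.5,
) -> float:
    """Normalized weighted symbolic mutual information between two channels.

    Identical and sign-opposite symbol pairs carry zero weight, so
    ``wsmi(x, x) == 0`` and ``wsmi(x, -x) == 0`` exactly.  The value is
    normalized by the sum of the two windows' local permutation entropies
    and averaged across valid 5-s windows.
    """
    if series_x.m != series_y.m or series_x.tau_samples != series_y.tau_samples:
        raise ValueError("both series must share (m, tau)")
    if len(series_x.symbols) != len(series_y.symbols):
        raise ValueError("aligned series required")
    m = series_x.m
    if series_x.fs is None:
        return _wsmi_window(series_x.symbols, series_y.symbols, m)
    span = (m - 1) * series_x.tau_samples
    n_samples = len(series_x.symbols) + span
    values = []
    for a, b in _window_slices(n_samples, series_x.fs, window_s, overlap, mask):
        sx = series_x.symbols[a: b - span]
        sy = series_y.symbols[a: b - span]
        if len(sx) > 0:
            v = _wsmi_window(sx, sy, m)
            if not math.isnan(v):
                values.append(v)
    return float(np.mean(values)) if values else float("nan")


def perm_entropy_windows(
    codes: np.ndarray,
    tau_samples: int,
    fs: float,
    mask: np.ndarray | None = None,
    m: int = 3,
    window_s: float = 5.0,
    overlap: float = 0.5,
) -> np.ndarray:
    """Window-averaged PermEn per channel for a (n_ch, L) symbol array."""
    span = (m - 1) * tau_samples
    n_samples = codes.shape[1] + span
    slices = _window_slices(n_samples, fs, window_s, overlap, mask)
    vals = []
    for a, b in slices:
        seg = codes[:, a: b - span]
        if seg.shape[1] > 0:
            vals.append(perm_entropy_batch(seg, m))
    if not vals:
        return np.full(codes.shape[0], np.nan)
    return np.mean(vals, axis=0)


def wsmi_pairs_windows(
    codes: np.ndarray,
    pairs: list[tuple[int, int]],
    tau_samples: int,
    fs: float,
    mask: np.ndarray | None = None,
    m: int = 3,
    window_s: float = 5.0,
    overlap: float = 0.5,
) -> np.ndarray:
    """Window-averaged normalized wSMI for many channel pairs at once.

    ``codes`` is the (n_ch, L) symbol array of one recording at one tau.
    Returns one value per pair (NaN if no valid window).
    """
    if not pairs:
        return np.empty(0)
    nsym = math.factorial(m)
    span = (m - 1) * tau_samples
    n_samples = codes.shape[1] + span
    slices = _window_slices(n_samples, fs, window_s, overlap, mask)
    ia = np.array([p[0] for p in pairs])
    ib = np.array([p[1] for p in pairs])
    _, opposite = _pattern_tables(m)
    w = np.ones((nsym, nsym))
    idx = np.arange(nsym)
    w[idx, idx] = 0.0
    w[idx, opposite] = 0.0
    P = len(pairs)
    offsets = (np.arange(P) * nsym * nsym)[:, None]
    acc = np.zeros(P)
    cnt = np.zeros(P)
    for a, b in slices:
        sx = codes[ia, a: b - span]
        sy = codes[ib, a: b - span]
        L = sx.shape[1]
        if L == 0:
            continue
        flat = np.bincount(
            (sx * nsym + sy + offsets).ravel(), minlength=P * nsym * nsym
        )
        joint = flat.reshape(P, nsym, nsym).astype(float) / L
        px = joint.sum(axis=2)
        py = joint.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = joint / (px[:, :, None] * py[:, None, :])
            terms = np.where(joint > 0, joint * np.log(ratio), 0.0)
        wsmi_val = (w[None, :, :] * terms).sum(axis=(1, 2))
        with np.errstate(divide="ignore", invalid="ignore"):
            pex = -np.where(px > 0, px * np.log(px), 0.0).sum(axis=1)
            pey = -np.where(py > 0, py * np.log(py), 0.0).sum(axis=1)
        denom = pex + pey
        good = denom > 0
        acc[good] += 2.0 * wsmi_val[good] / denom[good]
        cnt[good] += 1
    with np.errstate(invalid="ignore"):
        return np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)


# ---------------------------------------------------------------------------
# modified multiscale sample entropy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MMSEConfig:
    """Parameters of the modified (fuzzy) multiscale sample entropy."""

    scales: tuple[int, ...] = tuple(range(1, 21))
    average_scales: tuple[int, ...] = tuple(range(1, 11))
    r_factor: float = 0.15       # radius as a fraction of the per-scale SD
    segment_s: float = 30.0      # nonoverlapping segments
    fs: float = 200.0            # analysis rate
    min_valid_samples_per_scale: int = 100
    m: int = 2                   # embedding dimension on the coarse series
    chunk: int = 512


def fuzzy_sampen(x: np.ndarray, m: int = 2, r: float = 0.15,
                 chunk: int = 512) -> float:
    """Sample entropy with sigmoidal neighbor membership
    ``mu(d) = 1 / (1 + exp((d - 0.5) / r))`` on Chebyshev distances.

    ``x`` must already be standardized; ``r`` is then the radius in SD
    units.  Returns ``-ln(A/B)`` where A and B are membership sums at
    embedding dimensions m+1 and m over all template pairs i < j.
    """
    x = np.asarray(x, dtype=np.float64)
    n = len(x)
    N = n - m
    if N < 2:
        return float("nan")
    lanes = [x[k: k + N] for k in range(m + 1)]
    # accumulate over all ordered pairs, then remove the N diagonal terms
    # (mu(0) each); the A/B ratio over ordered pairs equals that over i<j
    A = 0.0
    B = 0.0
    d = np.empty((min(chunk, N), N))
    t = np.empty_like(d)
    for i0 in range(0, N, chunk):
        i1 = min(i0 + chunk, N)
        c = i1 - i0
        dd, tt = d[:c], t[:c]
        np.subtract(lanes[0][i0:i1, None], lanes[0][None, :], out=dd)
        np.abs(dd, out=dd)
        for k in range(1, m):
            np.subtract(lanes[k][i0:i1, None], lanes[k][None, :], out=tt)
            np.abs(tt, out=tt)
            np.maximum(dd, tt, out=dd)
        np.subtract(dd, 0.5, out=tt)
        tt /= r
        np.exp(tt, out=tt)
        tt += 1.0
        B += float(np.reciprocal(tt, out=tt).sum())
        np.subtract(lanes[m][i0:i1, None], lanes[m][None, :], out=tt)
        np.abs(tt, out=tt)
        np.maximum(dd, tt, out=dd)
        np.subtract(dd, 0.5, out=dd)
        dd /= r
        np.exp(dd, out=dd)
        dd += 1.0
        A += float(np.reciprocal(dd, out=dd).sum())
    mu0 = 1.0 / (1.0 + math.exp(-0.5 / r))
    A -= N * mu0
    B -= N * mu0
    if A <= 0 or B <= 0:
        return float("nan")
    return float(-math.log(A / B))


def coarse_grain(x: np.ndarray, scale: int) -> np.ndarray:
    """Average nonoverlapping blocks of ``scale`` samples."""
    n = (len(x) // scale) * scale
    if n == 0:
        return np.empty(0)
    return x[:n].reshape(-1, scale).mean(axis=1)


def mmse_per_scale(
    signal: np.ndarray,
    fs: float,
    config: MMSEConfig = MMSEConfig(),
    mask: np.ndarray | None = None,
) -> dict[int, float]:
    """Segment-averaged modified sample entropy at each timescale.

    The signal is cut into nonoverlapping segments; at each scale the
    segment is coarse-grained (only samples whose source blocks are fully
    usable are kept), standardized, and fuzzy sample entropy computed with
    radius ``r_factor`` in units of that scale's SD.  Segments providing
    fewer than ``min_valid_samples_per_scale`` coarse samples are dropped
    for that scale.
    """
    signal = np.asarray(signal, dtype=np.float64)
    seg_len = int(round(config.segment_s * fs))
    if seg_len < config.m + 2:
        raise ValueError("segment too short")
    per_scale: dict[int, list[float]] = {s: [] for s in config.scales}
    for start in range(0, len(signal) - seg_len + 1, seg_len):
        seg = signal[start:start + seg_len]
        seg_mask = None if mask is None else mask[start:start + seg_len]
        for s in config.scales:
            cg = coarse_grain(seg, s)
            if seg_mask is not None:
                ok = coarse_grain(seg_mask.astype(float), s) >= 1.0 - 1e-12
                cg = cg[ok]
            if len(cg) < max(config.min_valid_samples_per_scale, config.m + 2):
                continue
            sd = cg.std()
            if sd == 0:
                continue
            z = (cg - cg.mean()) / sd
            v = fuzzy_sampen(z, config.m, config.r_factor, config.chunk)
            if not math.isnan(v):
                per_scale[s].append(v)
    return {
        s: (float(np.mean(vals)) if vals else float("nan"))
        for s, vals in per_scale.items()
    }


def mmse(
    signal: np.ndarray,
    fs: float,
    config: MMSEConfig = MMSEConfig(),
    mask: np.ndarray | None = None,
) -> float:
    """Modified multiscale entropy: mean over ``config.average_scales``."""
    scales = tuple(s for s in config.average_scales if s in config.scales)
    per = mmse_per_scale(signal, fs, config, mask)
    vals = [per[s] for s in scales if not math.isnan(per.get(s, float("nan")))]
    return float(np.mean(vals)) if vals else float("nan")


# ---------------------------------------------------------------------------
# Lempel-Ziv 76 and CTW entropy rate
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LZCTWConfig:
    segment_s: float = 60.0
    fs: float = 200.0
    min_samples: int = 2000
    ctw_depth: int = 20


def median_binarize(x: np.ndarray) -> np.ndarray:
    """Binarize a signal at its median (strictly-above -> 1)."""
    x = np.asarray(x, dtype=np.float64)
    return (x > np.median(x)).astype(np.uint8)


def lz76_segment(x: np.ndarray) -> float:
    """Normalized LZ76 complexity of one segment: c / (N / log2 N)."""
    b = median_binarize(x)
    N = len(b)
    if N < 2:
        return float("nan")
    c = lz76_phrase_count(b)
    return float(c * math.log2(N) / N)


def ctw_segment(x: np.ndarray, depth: int = 20) -> float:
    """CTW entropy rate (bits/symbol) of one median-binarized segment."""
    b = median_binarize(x)
    N = len(b)
    if N < 1:
        return float("nan")
    return float(-ctw_log2_prob(b, depth) / N)


def _segments(
    signal: np.ndarray,
    fs: float,
    config: LZCTWConfig,
    mask: np.ndarray | None,
) -> list[np.ndarray]:
    seg_len = int(round(config.segment_s * fs))
    out = []
    for start in range(0, len(signal) - seg_len + 1, seg_len):
        seg = signal[start:start + seg_len]
        if mask is not None:
            good = mask[start:start + seg_len]
            seg = seg[good]
        if len(seg) >= config.min_samples:
            out.append(seg)
    return out


def lz76(
    signal: np.ndarray,
    fs: float,
    config: LZCTWConfig = LZCTWConfig(),
    mask: np.ndarray | None = None,
) -> float:
    """Segment-averaged normalized Lempel-Ziv-76 complexity."""
    vals = [lz76_segment(seg) for seg in _segments(signal, fs, config, mask)]
    vals = [v for v in vals if not math.isnan(v)]
    return float(np.mean(vals)) if vals else float("nan")


def ctw_entropy_rate(
    signal: np.ndarray,
    fs: float,
    config: LZCTWConfig = LZCTWConfig(),
    mask: np.ndarray | None = None,
) -> float:
    """Segment-averaged CTW entropy rate in bits per symbol."""
    vals = [ctw_segment(seg, config.ctw_depth)
            for seg in _segments(signal, fs, config, mask)]
    vals = [v for v in vals if not math.isnan(v)]
    return float(np.mean(vals)) if vals else float("nan")
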