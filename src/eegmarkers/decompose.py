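"""Surrogate decomposition of wake - sleep permutation-entropy changes.

The observed change ``delta_total = PermEn(wake) - PermEn(sleep)`` is
partitioned into three additive components:

* ``amplitude`` -- the gap that persists when the Fourier phases of both
  conditions are fully randomized, i.e. the part explained by each
  condition's amplitude spectrum alone;
* ``phase`` -- the additional gap attributable to the conditions'
  specific phase distributions, estimated by cross-condition phase
  swapping (amplitudes of one condition combined with phases donated by
  segments of the other);
* ``interaction`` -- the residual, so the three terms sum to the observed
  total exactly.

With ``G(X, Y)`` denoting the surrogate-mean PermEn of signals built from
the amplitude spectra of condition X and phases drawn from condition Y
(``Y = "rand"`` meaning i.i.d. uniform phases):

``amplitude = G(w, rand) - G(s, rand)``
``phase     = [(G(w, w) - G(w, s)) + (G(s, w) - G(s, s))] / 2``
``interaction = delta_total - amplitude - phase``

and ``non_amplitude = phase + interaction``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .entropy import perm_entropy_batch, symbolize_batch


def phase_randomize(segment: np.ndarray, seed: int | np.random.Generator = 0
                    ) -> np.ndarray:
    """Phase-randomized surrogate preserving the amplitude spectrum exactly.

    DC and (for even lengths) Nyquist bins are untouched; all other phases
    are replaced by i.i.d. uniform draws, and the inverse FFT returns a
    real signal.
    """
    rng = np.random.default_rng(seed)
    x = np.asarray(segment, dtype=np.float64)
    n = x.shape[-1]
    spec = np.fft.rfft(x)
    hi = spec.shape[-1] - 1 if n % 2 == 0 else spec.shape[-1]
    phases = rng.uniform(0, 2 * np.pi, size=hi - 1)
    spec[..., 1:hi] = np.abs(spec[..., 1:hi]) * np.exp(1j * phases)
    return np.fft.irfft(spec, n=n)


def phase_swap(
    segment: np.ndarray,
    phase_donor: np.ndarray,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Surrogate with the amplitude spectrum of ``segment`` and the phases
    of a donor segment.

    ``phase_donor`` may be a single segment or a (k, n) stack, in which
    case one donor is drawn at random per call.  Donors must match the
    segment length.
    """
    rng = np.random.default_rng(seed)
    x = np.asarray(segment, dtype=np.float64)
    donors = np.atleast_2d(np.asarray(phase_donor, dtype=np.float64))
    if donors.shape[-1] != x.shape[-1]:
        raise ValueError("donor segments must match the segment length")
    donor = donors[rng.integers(0, donors.shape[0])]
    n = x.shape[-1]
    spec = np.abs(np.fft.rfft(x)).astype(complex)
    dphase = np.angle(np.fft.rfft(donor))
    hi = spec.shape[-1] - 1 if n % 2 == 0 else spec.shape[-1]
    out = np.fft.rfft(x).copy()
    out[1:hi] = spec[1:hi] * np.exp(1j * dphase[1:hi])
    return np.fft.irfft(out, n=n)


@dataclass
class DecompComponents:
    """Decomposition results for one participant-channel, keyed by tau (ms).

    Each entry carries the five terms (normalized PermEn units) and the
    Monte-Carlo standard error of the surrogate-estimated terms.
    """

    terms: dict[float, dict[str, float]] = field(default_factory=dict)
    n_surrogates: int = 1000
    n_segments: int = 20
    segment_ms: float = 5000.0

    def as_frame(self, **ids) -> pd.DataFrame:
        rows = []
        for tau, t in self.terms.items():
            for name in ("total", "amplitude", "phase", "interaction",
                         "non_amplitude"):
                rows.append({**ids, "tau_ms": tau, "term": name,
                             "value": t[name],
                             "mc_se": t.get(f"{name}_se", float("nan"))})
        return pd.DataFrame(rows)


def draw_segments(
    signal: np.ndarray,
    fs: float,
    n_segments: int = 20,
    segment_ms: float = 5000.0,
    mask: np.ndarray | None = None,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Randomly select usable segments (without replacement, 50% overlap
    permitted) from a signal; returns a (n_segments, seg_len) array."""
    rng = np.random.default_rng(seed)
    seg = int(round(segment_ms * fs / 1000.0))
    starts = np.arange(0, len(signal) - seg + 1, max(seg // 2, 1))
    if mask is not None:
        starts = np.array(
            [s for s in starts if mask[s:s + seg].all()], dtype=int
        )
    if len(starts) < n_segments:
        raise ValueError(
            f"only {len(starts)} candidate segments available, "
            f"{n_segments} requested"
        )
    chosen = rng.choice(starts, size=n_segments, replace=False)
    return np.stack([signal[s:s + seg] for s in np.sort(chosen)])


def _surrogate_permen_mean(
    amp_spec: np.ndarray,        # (k, n_bins) magnitudes
    donor_phase: np.ndarray | None,  # (k, n_bins) angles or None for random
    n: int,
    n_surrogates: int,
    tau: int,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Mean and SE of PermEn over surrogates combining random amplitude
    segments with random donor phases (or uniform random phases)."""
    k = amp_spec.shape[0]
    nb = amp_spec.shape[1]
    hi = nb - 1 if n % 2 == 0 else nb
    a_idx = rng.integers(0, k, size=n_surrogates)
    mags = amp_spec[a_idx]
    if donor_phase is None:
        ph = rng.uniform(0, 2 * np.pi, size=(n_surrogates, hi - 1))
    else:
        d_idx = rng.integers(0, donor_phase.shape[0], size=n_surrogates)
        ph = donor_phase[d_idx][:, 1:hi]
    spec = np.zeros((n_surrogates, nb), dtype=complex)
    spec[:, 0] = mags[:, 0]
    spec[:, 1:hi] = mags[:, 1:hi] * np.exp(1j * ph)
    if hi < nb:
        spec[:, -1] = mags[:, -1]
    X = np.fft.irfft(spec, n=n, axis=-1)
    codes = symbolize_batch(X, 3, tau)
    H = perm_entropy_batch(codes, 3)
    return float(H.mean()), float(H.std(ddof=1) / np.sqrt(n_surrogates))


def decompose_permen(
    wake_segments: np.ndarray,
    sleep_segments: np.ndarray,
    taus_samples: list[int],
    fs: float | None = None,
    n_surrogates: int = 1000,
    seed: int = 0,
) -> DecompComponents:
    """Three-term surrogate decomposition of the wake - sleep PermEn change.

    ``wake_segments`` and ``sleep_segments`` are (k, n) arrays with equal
    (balanced) segment counts; ``taus_samples`` are embedding delays in
    samples.  Results are keyed by tau in ms when ``fs`` is given, else by
    the delay in samples.
    """
    W = np.atleast_2d(np.asarray(wake_segments, dtype=np.float64))
    S = np.atleast_2d(np.asarray(sleep_segments, dtype=np.float64))
    if W.shape[0] != S.shape[0]:
        raise ValueError(
            "segment counts must be balanced between conditions"
        )
    if W.shape[1] != S.shape[1]:
        raise ValueError("segment lengths must match between conditions")
    n = W.shape[1]
    specW = np.fft.rfft(W, axis=-1)
    specS = np.fft.rfft(S, axis=-1)
    magW, phW = np.abs(specW), np.angle(specW)
    magS, phS = np.abs(specS), np.angle(specS)
    out = DecompComponents(
        n_surrogates=n_surrogates, n_segments=W.shape[0],
        segment_ms=1000.0 * n / fs if fs else float("nan"),
    )
    ss = np.random.SeedSequence([seed, 97])
    for tau, child in zip(taus_samples, ss.spawn(len(taus_samples))):
        rng = np.random.default_rng(child)
        Hw = float(perm_entropy_batch(symbolize_batch(W, 3, tau), 3).mean())
        Hs = float(perm_entropy_batch(symbolize_batch(S, 3, tau), 3).mean())
        total = Hw - Hs
        g = {}
        se = {}
        for key, (mag, donor) in {
            ("w", "rand"): (magW, None),
            ("s", "rand"): (magS, None),
            ("w", "w"): (magW, phW),
            ("w", "s"): (magW, phS),
            ("s", "w"): (magS, phW),
            ("s", "s"): (magS, phS),
        }.items():
            g[key], se[key] = _surrogate_permen_mean(
                mag, donor, n, n_surrogates, tau, rng
            )
        amplitude = g[("w", "rand")] - g[("s", "rand")]
        amp_se = float(np.hypot(se[("w", "rand")], se[("s", "rand")]))
        phase = 0.5 * ((g[("w", "w")] - g[("w", "s")])
                       + (g[("s", "w")] - g[("s", "s")]))
        phase_se = 0.5 * float(np.sqrt(sum(
            se[k] ** 2 for k in (("w", "w"), ("w", "s"), ("s", "w"), ("s", "s"))
        )))
        interaction = total - amplitude - phase
        key_tau = 1000.0 * tau / fs if fs else float(tau)
        out.terms[key_tau] = {
            "total": total,
            "amplitude": amplitude,
            "amplitude_se": amp_se,
            "phase": phase,
            "phase_se": phase_se,
            "interaction": interaction,
            "interaction_se": float(np.hypot(amp_se, phase_se)),
            "non_amplitude": phase + interaction,
            "non_amplitude_se": amp_se,  # total and amp carry the MC error
        }
    return out


def component_stats(
    components: pd.DataFrame, fdr_q: float = 0.05
) -> pd.DataFrame:
    """Per-tau mixed-model contrast of amplitude vs non-amplitude terms.

    ``components`` needs columns participant, tau_ms, term, value (one row
    per participant x tau x term, channel-averaged or per channel).  For
    each tau an LMM of the component value on the term label with
    participant random intercepts is fit; p-values are BH-corrected across
    taus and a paired Cohen's d (mean difference over SD of
    participant-level differences, non_amplitude - amplitude) is reported.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    from .classify import fdr_bh

    sub = components[components["term"].isin(["amplitude", "non_amplitude"])]
    if sub["participant"].nunique() < 3:
        raise ValueError("component_stats requires >= 3 participants")
    rows = []
    for tau, df in sub.groupby("tau_ms"):
        agg = (df.groupby(["participant", "term"])["value"].mean()
               .unstack("term"))
        diffs = (agg["non_amplitude"] - agg["amplitude"]).dropna()
        d = float(diffs.mean() / diffs.std(ddof=1)) \
            if len(diffs) > 1 and diffs.std(ddof=1) > 0 else float("nan")
        long = agg.stack().rename("value").reset_index()
        y = long["value"].to_numpy(dtype=float)
        x = (long["term"] == "non_amplitude").to_numpy(dtype=float)
        X = sm.add_constant(x)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                warnings.simplefilter("ignore", UserWarning)
                fit = sm.MixedLM(y, X, groups=long["participant"]).fit(
                    reml=True
                )
            coef = float(fit.params.iloc[1])
            p = float(fit.pvalues.iloc[1])
        except Exception:
            from scipy import stats as sstats
            coef = float(diffs.mean())
            p = float(sstats.ttest_1samp(diffs, 0.0).pvalue) \
                if len(diffs) > 1 else float("nan")
        rows.append({"tau_ms": tau, "coef": coef, "p": p, "cohens_d": d,
                     "n_participants": int(agg.shape[0])})
    out = pd.DataFrame(rows).sort_values("tau_ms").reset_index(drop=True)
    pv = out["p"].to_numpy(dtype=float)
    ok = np.isfinite(pv)
    adj = np.full(len(out), np.nan)
    rej = np.zeros(len(out), dtype=bool)
    if ok.sum():
        a, r = fdr_bh(pv[ok], fdr_q)
        adj[ok], rej[ok] = a, r
    out["p_fdr"] = adj
    out["significant"] = rej
    return out
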