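"""Synthetic multichannel EEG cohorts with a spectrum/complexity dissociation.

The generator emulates three oscillatory regimes observed in children:

* ``AS_like`` -- high-amplitude 2-4 Hz delta activity during *both*
  wakefulness and NREM sleep (the Angelman-syndrome phenotype in which slow
  waves are dissociated from unconsciousness);
* ``NT_like`` -- a neurotypical pattern with an alpha-sigma peak awake and
  slower activity asleep;
* ``DUP_like`` -- dominant beta activity in both states (the Dup15q
  phenotype of fast activity persisting into NREM sleep).

In every regime the wake signal has *higher temporal complexity* than the
sleep signal at a matched amplitude spectrum.  Mechanism: each sleep
channel is a nonsinusoidal oscillation -- a frequency-modulated
fundamental plus a phase-locked per-cycle spike transient, under a
deterministic burst envelope -- on a 1/f background; the wake channel is
rebuilt from the *same* per-channel amplitude spectrum after randomizing
the Fourier phases of a fraction ``complexity_gap`` of frequency bins
(independently per channel).  Phase randomization destroys waveform shape
and between-channel dependence but cannot change any amplitude spectrum,
so spectral features are blind to the state change wherever the dominant
band is state-invariant.

Inter-channel structure is injected into the *template*, before the
surrogate step, by two lagged couplings:

* a broadband source entering each coupled pair with symmetric +/- lags
  (several lag scales).  Its cross-spectrum is real, so it is invisible
  to the debiased weighted phase lag index, but its lagged dependence is
  visible to symbolic mutual information.  Because the wake surrogate
  randomizes phases per channel, the dependence survives only in sleep,
  giving a spectrum-neutral wSMI state signal in every regime;
* a narrowband theta source with a single asymmetric lag, which produces
  genuine dwPLI.  It is active only in the NT-like regime (stronger
  asleep, as in typical sleep EEG); the two dissociated regimes carry no
  phase-lag connectivity signal in either state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .montage import CANONICAL_ORDER
from .records import NREM, WAKE, EEGRecord

REGIMES = ("AS_like", "NT_like", "DUP_like")

#: channel pairs (by 10-20 label) receiving the lagged couplings; both sets
#: span the short-range (80-130 mm) and long-range (>= 130 mm) classes
DWPLI_COUPLED_PAIRS = (("F3", "Cz"), ("F4", "Cz"),
                       ("Fp1", "Pz"), ("Fp2", "Pz"),
                       ("F7", "O1"), ("F8", "O2"))
WSMI_COUPLED_PAIRS = (("Fz", "C3"), ("Fz", "C4"), ("T3", "P3"), ("Cz", "P4"),
                      ("Fp1", "O1"), ("Fp2", "O2"), ("F7", "P4"), ("F8", "P3"))


@dataclass
class CohortConfig:
    """Generative parameters for one cohort regime.

    ``dominant_band`` maps each state to the (lo, hi) Hz range from which a
    participant's fundamental oscillation frequency is drawn; the AS-like
    and DUP-like regimes use the same band for both states.
    ``complexity_gap`` is the fraction of Fourier bins whose phases are
    randomized in the wake signal relative to sleep (0 = no entropy gap,
    1 = fully linearized wake surrogate).
    """

    regime: str
    n_participants: int = 10
    n_channels: int = 19
    fs: float = 125.0
    duration_s: float = 120.0
    dominant_band: dict[str, tuple[float, float]] = field(default_factory=dict)
    complexity_gap: float = 0.9
    coupling_lag_ms: float = 24.0
    mixing_strength: float = 0.15
    osc_amplitude_uv: float = 30.0
    noise_amplitude_uv: float = 12.0
    noise_alpha: float = 2.0
    n_harmonics: int = 8
    #: deterministic burst-envelope rate range (Hz), depth and sharpness
    burst_freq_hz: tuple[float, float] | None = None
    burst_depth: float | None = None
    burst_power: float | None = None
    #: relative per-channel jitter of the fundamental frequency; distinct
    #: channel frequencies prevent spurious within-window symbolic
    #: dependence between independent same-rhythm channels
    channel_f0_jitter: float | None = None
    #: Wiener phase-noise rate (rad^2/s) of the dominant oscillation; the
    #: secondary slow component always uses moderate coherence
    phase_diffusion: float | None = None
    #: amplitude ratio of a secondary slow spike-wave component (gives
    #: beta-dominated regimes entropy structure at slow timescales too)
    secondary_slow_amp: float | None = None
    secondary_slow_band: tuple[float, float] = (2.0, 3.5)
    #: per-state gain of the symmetric-lag broadband coupling (wSMI signal)
    wsmi_coupling: dict[str, float] = field(default_factory=dict)
    #: per-state gain of the asymmetric-lag narrowband coupling (dwPLI)
    dwpli_coupling: dict[str, float] = field(default_factory=dict)
    mask_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"regime must be one of {REGIMES}")
        if not 0.0 <= self.complexity_gap <= 1.0:
            raise ValueError("complexity_gap must be in [0, 1]")
        if not 0.0 <= self.mixing_strength < 1.0:
            raise ValueError("mixing_strength must be in [0, 1)")
        defaults = _regime_defaults(self.regime)
        if not self.dominant_band:
            self.dominant_band = defaults["dominant_band"]
        if not self.wsmi_coupling:
            self.wsmi_coupling = defaults["wsmi_coupling"]
        if not self.dwpli_coupling:
            self.dwpli_coupling = defaults["dwpli_coupling"]
        if self.burst_freq_hz is None:
            self.burst_freq_hz = defaults["burst_freq_hz"]
        if self.burst_depth is None:
            self.burst_depth = defaults["burst_depth"]
        if self.burst_power is None:
            self.burst_power = defaults["burst_power"]
        if self.secondary_slow_amp is None:
            self.secondary_slow_amp = defaults["secondary_slow_amp"]
        if self.channel_f0_jitter is None:
            self.channel_f0_jitter = defaults["channel_f0_jitter"]
        if self.phase_diffusion is None:
            self.phase_diffusion = defaults["phase_diffusion"]
        if self.regime in ("AS_like", "DUP_like"):
            if self.dominant_band[WAKE] != self.dominant_band[NREM]:
                raise ValueError(
                    f"{self.regime} must use the same dominant band in both states"
                )

    @property
    def channel_labels(self) -> tuple[str, ...]:
        return CANONICAL_ORDER[: self.n_channels]


def _regime_defaults(regime: str) -> dict:
    # the wSMI coupling gain is state-equal everywhere: the wake surrogate
    # step, not the gain, removes the dependence during wakefulness, so
    # marginal spectra stay matched.  The dwPLI (asymmetric-lag) coupling
    # is active only in the NT-like regime, where spectral connectivity
    # legitimately tracks state; the two dissociated regimes carry no
    # phase-lag connectivity signal at all.
    if regime == "AS_like":
        return {
            "dominant_band": {WAKE: (2.0, 4.0), NREM: (2.0, 4.0)},
            "wsmi_coupling": {WAKE: 1.0, NREM: 1.0},
            "dwpli_coupling": {WAKE: 0.0, NREM: 0.0},
            "burst_freq_hz": (1.2, 2.2),
            "burst_depth": 0.9,
            "burst_power": 1.0,
            "secondary_slow_amp": 0.0,
            "channel_f0_jitter": 0.06,
            "phase_diffusion": 1.5,
        }
    if regime == "NT_like":
        return {
            "dominant_band": {WAKE: (8.0, 15.0), NREM: (4.0, 8.0)},
            "wsmi_coupling": {WAKE: 1.0, NREM: 1.0},
            "dwpli_coupling": {WAKE: 0.2, NREM: 0.6},
            "burst_freq_hz": (1.2, 2.2),
            "burst_depth": 0.9,
            "burst_power": 1.0,
            "secondary_slow_amp": 0.0,
            "channel_f0_jitter": 0.06,
            "phase_diffusion": 1.5,
        }
    # DUP_like: fundamental restricted to the lower beta band so that the
    # second harmonic stays below the 45 Hz lowpass at typical rates; the
    # fast bursts and the small slow spike-wave component give the regime
    # phase structure across timescales
    return {
        "dominant_band": {WAKE: (16.0, 21.0), NREM: (16.0, 21.0)},
        "wsmi_coupling": {WAKE: 1.0, NREM: 1.0},
        "dwpli_coupling": {WAKE: 0.0, NREM: 0.0},
        "burst_freq_hz": (3.0, 5.0),
        "burst_depth": 1.0,
        "burst_power": 3.0,
        "secondary_slow_amp": 0.7,
        "channel_f0_jitter": 0.15,
        "phase_diffusion": 4.0,
    }


# ---------------------------------------------------------------------------
# primitive generators
# ---------------------------------------------------------------------------

def generate_pink_noise(
    n_samples: int,
    fs: float,
    alpha: float = 2.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Zero-mean, unit-variance noise with expected 1/f^alpha power spectrum.

    Synthesized in the frequency domain: i.i.d. complex Gaussian spectrum
    shaped by f^(-alpha/2), inverse-transformed and standardized.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if fs <= 0:
        raise ValueError("fs must be positive")
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    rng = np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-alpha / 2.0)
    spec = amp * (rng.standard_normal(len(freqs))
                  + 1j * rng.standard_normal(len(freqs)))
    spec[0] = 0.0
    if n_samples % 2 == 0:
        spec[-1] = spec[-1].real
    x = np.fft.irfft(spec, n=n_samples)
    x -= x.mean()
    sd = x.std()
    if sd == 0:
        raise ValueError("degenerate noise realization")
    return x / sd


def _nonsinusoidal_oscillation(
    n: int,
    fs: float,
    f0: float,
    n_harmonics: int,
    rng: np.random.Generator,
    spike_amp: float = 1.4,
    spike_kappa: float = 30.0,
    burst_freq_hz: tuple[float, float] = (1.2, 2.2),
    burst_depth: float = 0.9,
    burst_power: float = 1.0,
    phase_diffusion: float = 0.8,
) -> np.ndarray:
    """Frequency-modulated nonsinusoidal oscillation with burst envelope.

    The waveform is a fundamental ``cos(theta)`` plus a periodic sharp
    transient ``exp(kappa (cos(theta) - 1))`` -- a von-Mises-shaped spike
    once per cycle whose harmonics decay smoothly, giving a pulse-like
    (temporally sparse) phase-locked fast component without ringing.  The
    instantaneous phase theta(t) wanders slowly around 2*pi*f0*t (plus a
    channel-specific offset), and a deterministic burst envelope adds
    phase-coherent sidebands.  All structure is deterministic given the
    drawn parameters, so a phase-randomized surrogate (same amplitude
    spectrum, Gaussianized phases) is genuinely more disordered in time.
    """
    t = np.arange(n) / fs
    fm = 0.2 + 0.3 * rng.random()           # Hz, slow frequency modulation
    depth = 0.6 + 0.4 * rng.random()        # rad
    # Wiener phase noise gives the oscillation a finite coherence time
    # (~1/phase_diffusion s), as in physiological rhythms; without it,
    # deterministic same-frequency channels would show spurious
    # within-window symbolic dependence
    walk = np.cumsum(rng.standard_normal(n)) * math.sqrt(phase_diffusion / fs)
    theta = (2 * np.pi * f0 * t
             + rng.uniform(0, 2 * np.pi)    # channel-specific phase offset
             + depth * np.sin(2 * np.pi * fm * t + rng.uniform(0, 2 * np.pi))
             + walk)
    x = np.cos(theta)
    # spike width is set by kappa; cap it so the harmonic content stays
    # below both the 45 Hz lowpass and ~88% of Nyquist
    f_max = min(0.88 * fs / 2.0, 44.0)
    k_max = f_max / f0
    kappa = min(spike_kappa, (k_max / 2.2) ** 2)
    if kappa > 1.0 and n_harmonics > 1:
        spike = np.exp(kappa * (np.cos(theta) - 1.0))
        sd = spike.std()
        if sd > 0:
            x = x + spike_amp * (spike - spike.mean()) / sd
    f_e = rng.uniform(*burst_freq_hz)
    env = 1.0 + burst_depth * np.cos(2 * np.pi * f_e * t
                                     + rng.uniform(0, 2 * np.pi))
    if burst_power != 1.0:
        # sharpened envelope: temporally sparse bursts with quiet gaps
        env = env ** burst_power
    return x * env


def _partial_phase_randomize(
    data: np.ndarray,
    fraction: float,
    rng: np.random.Generator,
    independent: bool = True,
) -> np.ndarray:
    """Randomize phases of a random fraction of rFFT bins, preserving each
    channel's amplitude spectrum exactly.

    With ``independent=True`` every channel draws its own phase offsets,
    destroying between-channel dependence as well as each channel's
    waveform structure; with ``independent=False`` the same offsets are
    applied to all channels, leaving every cross-spectrum untouched.
    """
    data = np.atleast_2d(data)
    n = data.shape[-1]
    spec = np.fft.rfft(data, axis=-1)
    n_bins = spec.shape[-1]
    hi = n_bins - 1 if n % 2 == 0 else n_bins  # exclude Nyquist bin
    candidates = np.arange(1, hi)
    k = int(round(fraction * len(candidates)))
    if k > 0:
        chosen = rng.choice(candidates, size=k, replace=False)
        if independent:
            shifts = np.exp(
                1j * rng.uniform(0, 2 * np.pi, size=(data.shape[0], k))
            )
        else:
            shifts = np.exp(1j * rng.uniform(0, 2 * np.pi, size=k))
        spec[..., chosen] = spec[..., chosen] * shifts
    return np.fft.irfft(spec, n=n, axis=-1)


def _bandpass_noise(
    n: int, fs: float, band: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    lo, hi = band
    sos = sps.butter(4, [lo / (fs / 2), min(hi / (fs / 2), 0.99)], "bandpass",
                     output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    return x / x.std()


def _random_mask(
    n: int, fs: float, fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Usability mask with ~``fraction`` of samples masked in ~1 s chunks."""
    mask = np.ones(n, dtype=bool)
    if fraction <= 0:
        return mask
    n_bad = int(round(fraction * n))
    chunk = max(int(fs), 1)
    while n_bad > 0:
        length = min(chunk, n_bad)
        start = rng.integers(0, max(n - length, 1))
        mask[start:start + length] = False
        n_bad -= length
    return mask


# ---------------------------------------------------------------------------
# recordings and datasets
# ---------------------------------------------------------------------------

#: analysis steps and the minimum duration (s) each requires
_MIN_DURATIONS = (
    ("0.5 Hz Morlet wavelet window", 10.9),
)


def generate_recording(
    config: CohortConfig,
    participant_id: str,
    state: str,
    seed: int,
) -> EEGRecord:
    """Generate one synthetic recording (one participant in one state).

    Passing the *same* ``seed`` for both states of a participant yields the
    matched wake/sleep pair: identical participant-level parameters and, in
    regimes with a state-invariant dominant band, identical per-channel
    amplitude spectra before mixing (the wake member being a partial
    phase-randomized surrogate of the sleep member).
    """
    if state not in (WAKE, NREM):
        raise ValueError(f"state must be '{WAKE}' or '{NREM}'")
    for name, need in _MIN_DURATIONS:
        if config.duration_s < need:
            raise ValueError(
                f"duration {config.duration_s} s is too short for one valid "
                f"analysis window: the {name} requires {need} s"
            )
    n = int(round(config.duration_s * config.fs))
    labels = config.channel_labels
    n_ch = config.n_channels

    ss = np.random.SeedSequence([seed, 2141592653])
    part_rng = np.random.default_rng(ss.spawn(1)[0])
    # participant-level parameters (state-invariant)
    band_by_state = {
        st: tuple(config.dominant_band[st]) for st in (WAKE, NREM)
    }
    # fundamentals are drawn from the central 60% of the dominant band so
    # the spectral peak sits inside the band for every participant
    u = 0.2 + 0.6 * part_rng.random()
    f0_by_state = {
        st: band_by_state[st][0] + u * (band_by_state[st][1] - band_by_state[st][0])
        for st in (WAKE, NREM)
    }
    lo2, hi2 = config.secondary_slow_band
    f0_slow = lo2 + part_rng.random() * (hi2 - lo2)
    osc_amp = config.osc_amplitude_uv * np.exp(0.15 * part_rng.standard_normal())
    noise_amp = config.noise_amplitude_uv * np.exp(0.1 * part_rng.standard_normal())
    chan_gains = np.exp(0.05 * part_rng.standard_normal(n_ch))
    f0_jitter = 1.0 + config.channel_f0_jitter * (2 * part_rng.random(n_ch) - 1)
    f0_slow_jitter = 1.0 + 0.06 * (2 * part_rng.random(n_ch) - 1)

    def build_base(f0: float, rng: np.random.Generator) -> np.ndarray:
        out = np.empty((n_ch, n))
        for c in range(n_ch):
            osc = _nonsinusoidal_oscillation(
                n, config.fs, f0 * f0_jitter[c], config.n_harmonics, rng,
                burst_freq_hz=tuple(config.burst_freq_hz),
                burst_depth=config.burst_depth,
                burst_power=config.burst_power,
                phase_diffusion=config.phase_diffusion,
            )
            osc = osc / osc.std()
            if config.secondary_slow_amp > 0:
                slow = _nonsinusoidal_oscillation(
                    n, config.fs, f0_slow * f0_slow_jitter[c],
                    config.n_harmonics, rng,
                    phase_diffusion=1.5,
                )
                osc = osc + config.secondary_slow_amp * slow / slow.std()
                osc = osc / osc.std()
            noise = generate_pink_noise(n, config.fs, config.noise_alpha, rng)
            out[c] = chan_gains[c] * (osc_amp * osc + noise_amp * noise)
        return out

    def add_couplings(data: np.ndarray, for_state: str) -> None:
        """Lagged inter-channel couplings, added to the template *before*
        the wake surrogate step (so wakefulness, which randomizes phases
        per channel, loses the dependence they create).

        The broadband source enters its pair with symmetric +/- lags: its
        cross-spectrum is real, so it produces symbolic dependence (wSMI)
        without any weighted-phase-lag (dwPLI) signature.  The narrowband
        theta source uses a single asymmetric lag and carries genuine
        dwPLI; its gain is state-dependent only in the NT-like regime.
        Coupling source realizations are state-independent, so equal gains
        imply identical marginal spectra in both states.
        """
        lag = max(int(round(config.coupling_lag_ms * config.fs / 1000.0)), 1)
        label_index = {lab: i for i, lab in enumerate(labels)}
        coup_rng = np.random.default_rng(np.random.SeedSequence([seed, 13]))
        g_w = config.wsmi_coupling[for_state] * noise_amp
        # symmetric lags at multiples of the base lag cover the pattern
        # spans of every tau used by the symbolic measures
        wsmi_lags = [max(int(round(k * config.coupling_lag_ms * config.fs
                                   / 1000.0)), 1) for k in (1, 4, 12)]
        for a_lab, b_lab in WSMI_COUPLED_PAIRS:
            z = generate_pink_noise(n, config.fs, 1.0, coup_rng)
            if g_w > 0 and a_lab in label_index and b_lab in label_index:
                data[label_index[a_lab]] += g_w * z
                mixed = np.zeros(n)
                for lg in wsmi_lags:
                    mixed += np.roll(z, lg) + np.roll(z, -lg)
                data[label_index[b_lab]] += g_w * mixed / np.sqrt(
                    2.0 * len(wsmi_lags)
                )
        g_p = config.dwpli_coupling[for_state] * noise_amp
        for a_lab, b_lab in DWPLI_COUPLED_PAIRS:
            z = _bandpass_noise(n, config.fs, (4.0, 8.0), coup_rng)
            if g_p > 0 and a_lab in label_index and b_lab in label_index:
                data[label_index[a_lab]] += g_p * z
                data[label_index[b_lab]] += g_p * np.roll(z, lag)

    state_idx = 0 if state == WAKE else 1
    state_rng = np.random.default_rng(np.random.SeedSequence([seed, 11, state_idx]))
    same_band = band_by_state[WAKE] == band_by_state[NREM]
    if state == NREM or same_band:
        # sleep template; for same-band regimes the wake surrogate is built
        # from this very realization (identical amplitude spectra)
        data = build_base(
            f0_by_state[NREM],
            np.random.default_rng(np.random.SeedSequence([seed, 7, 1])),
        )
    else:
        # state-specific dominant band (NT-like): separate wake template
        data = build_base(
            f0_by_state[WAKE],
            np.random.default_rng(np.random.SeedSequence([seed, 7, 2])),
        )
    add_couplings(data, state)
    if state == WAKE:
        data = _partial_phase_randomize(
            data, config.complexity_gap, state_rng, independent=True
        )

    # zero-lag volume-conduction mixing, rows sum to 1
    if config.mixing_strength > 0 and n_ch > 1:
        mu = config.mixing_strength
        mix = (1 - mu) * np.eye(n_ch) + mu / n_ch * np.ones((n_ch, n_ch))
        data = mix @ data

    mask = _random_mask(n, config.fs, config.mask_fraction, state_rng)
    return EEGRecord(
        data=data,
        fs=config.fs,
        channel_labels=labels,
        artifact_mask=mask,
        participant_id=participant_id,
        cohort=config.regime,
        state=state,
        meta={"f0_hz": f0_by_state[state], "seed": seed},
    )


def generate_dataset(
    train_config: CohortConfig,
    val_configs: list[CohortConfig],
    seed: int,
) -> tuple[list[EEGRecord], pd.DataFrame]:
    """Generate matched wake/sleep recordings for a training cohort and any
    number of validation cohorts, with a per-recording manifest.

    Deterministic given ``seed``; participant ids are of the form
    ``<regime>_p<k>`` and must be unique across cohorts.
    """
    records: list[EEGRecord] = []
    rows = []
    seen: set[str] = set()
    for cidx, config in enumerate([train_config, *val_configs]):
        ss = np.random.SeedSequence([seed, cidx])
        part_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in
                      ss.spawn(config.n_participants)]
        for p in range(config.n_participants):
            pid = f"{config.regime}_p{p}"
            if pid in seen:
                raise ValueError(f"duplicate participant id {pid}")
            seen.add(pid)
            for state in (WAKE, NREM):
                rec = generate_recording(config, pid, state, part_seeds[p])
                records.append(rec)
                rows.append({
                    "recording_id": rec.recording_id,
                    "participant_id": pid,
                    "cohort": config.regime,
                    "state": state,
                    "fs": config.fs,
                    "duration_s": config.duration_s,
                    "seed": part_seeds[p],
                    "role": "train" if cidx == 0 else "validation",
                })
    return records, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# window-length validation on pink noise
# ---------------------------------------------------------------------------

_ENTROPY_FEATURES = ("permen", "lz", "ctw", "mmse")

#: default window-length grids (seconds): 2-100 s in 2 s steps for the
#: slow-rate complexity measures, 0.5-20 s in 0.5 s steps for PermEn
WINDOW_GRID_SLOW_S = np.arange(2.0, 100.0 + 1e-9, 2.0)
WINDOW_GRID_PERMEN_S = np.arange(0.5, 20.0 + 1e-9, 0.5)


def window_length_validation(
    n_signals: int,
    feature: str,
    window_grid_s: np.ndarray | list[float],
    seed: int,
    alpha: float = 2.0,
    fs: float = 500.0,
    tau_ms: float = 32.0,
) -> pd.DataFrame:
    """Stability-vs-window-length curves for the entropy estimators.

    For each of ``n_signals`` pink-noise signals (spectral exponent
    ``alpha``, simulated at ``fs`` then filtered and downsampled exactly as
    EEG would be), the requested entropy feature is estimated on windows of
    each length in ``window_grid_s``.  For each grid step the absolute
    successive difference between adjacent window lengths is formed, and the
    running mean of all such differences up to that window length is
    reported, with its mean and normal-approximation 95% CI across signals.
    """
    from . import entropy as ent
    from .preprocess import FilterSpec, bandpass_array, resample_array

    if n_signals < 2:
        raise ValueError("n_signals must be >= 2")
    feature = feature.lower()
    if feature not in _ENTROPY_FEATURES:
        raise ValueError(
            f"feature must be one of {_ENTROPY_FEATURES}, got {feature!r}"
        )
    grid = np.asarray(list(window_grid_s), dtype=float)
    if grid.ndim != 1:
        raise ValueError("window grid must be one-dimensional")
    target_fs = 125.0 if feature == "permen" else 200.0
    ss = np.random.SeedSequence([seed, 421])
    estimates = np.empty((n_signals, len(grid)))
    spec = FilterSpec()
    for i, child in enumerate(ss.spawn(n_signals)):
        rng = np.random.default_rng(child)
        x = generate_pink_noise(int(round(grid.max() * fs)) + 1, fs, alpha, rng)
        x = bandpass_array(x, fs, spec)
        x = resample_array(x, fs, target_fs)
        for j, w in enumerate(grid):
            seg = x[: int(round(w * target_fs))]
            estimates[i, j] = _window_estimate(seg, feature, target_fs, tau_ms)

    rows = []
    diffs = np.abs(np.diff(estimates, axis=1))  # (n_signals, len(grid)-1)
    for j in range(1, len(grid)):
        running = diffs[:, :j].mean(axis=1)
        m = running.mean()
        sem = running.std(ddof=1) / np.sqrt(n_signals)
        rows.append({
            "window_s": grid[j],
            "mean_abs_diff": m,
            "ci_lo": m - 1.96 * sem,
            "ci_hi": m + 1.96 * sem,
        })
    return pd.DataFrame(rows, columns=["window_s", "mean_abs_diff", "ci_lo", "ci_hi"])


def _window_estimate(seg: np.ndarray, feature: str, fs: float, tau_ms: float) -> float:
    from . import entropy as ent

    if feature == "permen":
        tau = max(int(round(tau_ms * fs / 1000.0)), 1)
        series = ent.ordinal_symbolize(seg, 3, tau)
        return ent.perm_entropy_symbols(series.symbols)
    if feature == "lz":
        return ent.lz76_segment(seg)
    if feature == "ctw":
        return ent.ctw_segment(seg)
    # mmse on the single window as one segment, scales limited by length
    cfg = ent.MMSEConfig(segment_s=len(seg) / fs, fs=fs)
    return ent.mmse(seg, fs, cfg)
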