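"""Entropy estimators: hand oracles, calibration, and invariances."""

import math

import numpy as np
import pytest

from eegmarkers import entropy as ent
from eegmarkers._fast import ctw_log2_prob, lz76_phrase_count


# ---------------------------------------------------------------------------
# ordinal patterns and permutation entropy
# ---------------------------------------------------------------------------

class TestOrdinalSymbolize:
    def test_strictly_increasing_signal_is_one_pattern(self):
        s = ent.ordinal_symbolize(np.arange(50, dtype=float), 3, 1)
        assert len(set(s.symbols.tolist())) == 1

    def test_alphabet_size_is_six_for_m3(self):
        s = ent.ordinal_symbolize(np.random.default_rng(0).random(500), 3, 1)
        assert s.alphabet_size == 6
        assert set(s.symbols.tolist()) <= set(range(6))

    def test_hand_enumerated_patterns(self):
        # windows (4,1,3) and (1,3,2): ranks (2,0,1) and (0,2,1)
        s = ent.ordinal_symbolize(np.array([4.0, 1.0, 3.0, 2.0]), 3, 1)
        assert len(s.symbols) == 2
        assert s.symbols[0] != s.symbols[1]

    def test_ties_break_by_temporal_order(self):
        # constant signal: earlier samples rank lower -> ascending pattern
        const = ent.ordinal_symbolize(np.ones(10), 3, 1)
        asc = ent.ordinal_symbolize(np.arange(10, dtype=float), 3, 1)
        assert set(const.symbols.tolist()) == set(asc.symbols.tolist())

    def test_opposite_map_is_time_reversed_rank(self):
        s = ent.ordinal_symbolize(np.arange(10, dtype=float), 3, 1)
        d = ent.ordinal_symbolize(-np.arange(10, dtype=float), 3, 1)
        assert (s.opposite_map[s.symbols] == d.symbols).all()

    def test_too_short_signal_raises(self):
        with pytest.raises(ValueError):
            ent.ordinal_symbolize(np.array([1.0, 2.0]), 3, 2)


class TestPermEntropy:
    def test_single_symbol_gives_zero(self):
        assert ent.perm_entropy_symbols(np.zeros(100, dtype=int)) == 0.0

    def test_uniform_symbols_give_one(self):
        symbols = np.repeat(np.arange(6), 10)
        assert ent.perm_entropy_symbols(symbols) == pytest.approx(1.0)

    def test_two_equal_count_symbols(self):
        symbols = np.array([0, 0, 0, 1, 1, 1])
        expected = math.log(2) / math.log(6)  # ~0.3869
        assert ent.perm_entropy_symbols(symbols) == pytest.approx(expected)

    def test_windowed_average_and_missing(self):
        rng = np.random.default_rng(1)
        series = ent.ordinal_symbolize(rng.random(1250), 3, 1, fs=125.0)
        v = ent.perm_entropy(series)
        assert 0.9 < v <= 1.0
        mask = np.zeros(1250, dtype=bool)
        assert math.isnan(ent.perm_entropy(series, mask=mask))


class TestWsmi:
    def test_identical_channels_give_exact_zero(self):
        x = np.random.default_rng(2).random(2000)
        sx = ent.ordinal_symbolize(x, 3, 2)
        assert ent.wsmi(sx, sx) == 0.0

    def test_sign_flip_gives_exact_zero(self):
        x = np.random.default_rng(3).random(2000)
        sx = ent.ordinal_symbolize(x, 3, 2)
        sy = ent.ordinal_symbolize(-x, 3, 2)
        assert ent.wsmi(sx, sy) == 0.0

    def test_independent_streams_are_near_zero(self):
        rng = np.random.default_rng(4)
        sx = ent.ordinal_symbolize(rng.random(5000), 3, 1)
        sy = ent.ordinal_symbolize(rng.random(5000), 3, 1)
        assert abs(ent.wsmi(sx, sy)) < 0.02

    def test_mismatched_embeddings_rejected(self):
        x = np.random.default_rng(5).random(100)
        with pytest.raises(ValueError):
            ent.wsmi(ent.ordinal_symbolize(x, 3, 1),
                     ent.ordinal_symbolize(x, 3, 2))


# ---------------------------------------------------------------------------
# modified multiscale entropy
# ---------------------------------------------------------------------------

def fuzzy_sampen_direct(x: np.ndarray, m: int = 2, r: float = 0.15) -> float:
    """Straightforward O(n^2) reference with explicit loops over i < j."""
    n = len(x)
    N = n - m
    A = B = 0.0
    for i in range(N):
        for j in range(i + 1, N):
            dm = max(abs(x[i + k] - x[j + k]) for k in range(m))
            B += 1.0 / (1.0 + math.exp((dm - 0.5) / r))
            dm1 = max(dm, abs(x[i + m] - x[j + m]))
            A += 1.0 / (1.0 + math.exp((dm1 - 0.5) / r))
    return -math.log(A / B)


class TestMmse:
    def test_fast_path_equals_direct_computation(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(500)
        x = (x - x.mean()) / x.std()
        assert ent.fuzzy_sampen(x) == pytest.approx(
            fuzzy_sampen_direct(x), abs=1e-10
        )

    def test_scale_profile_flat_for_white_noise_lower_for_smooth(self):
        """The per-scale radius is recomputed from each coarse-grained
        series' SD, which removes the variance-driven entropy decline of
        the uncorrected estimator: white noise stays high and nearly flat
        across scales, while a smoothed (autocorrelated) signal sits
        clearly lower at fine scales."""
        cfg = ent.MMSEConfig(scales=(1, 2, 4, 8), fs=200.0)
        white, smooth = [], []
        for seed in range(5):
            x = np.random.default_rng(seed).standard_normal(6000)
            per = ent.mmse_per_scale(x, 200.0, cfg)
            vals = np.array([per[s] for s in cfg.scales])
            assert vals.min() > 0.9
            assert vals.max() - vals.min() < 0.05
            white.append(per[1])
            y = np.convolve(x, np.ones(8) / 8, mode="same")
            smooth.append(ent.mmse_per_scale(y, 200.0, cfg)[1])
        assert np.mean(smooth) < np.mean(white) - 0.2

    def test_alternating_square_wave_is_nearly_deterministic(self):
        x = np.tile([1.0, -1.0], 3000)
        x += 1e-6 * np.random.default_rng(7).standard_normal(len(x))
        cfg = ent.MMSEConfig(scales=(1,), average_scales=(1,), fs=200.0)
        assert ent.mmse(x, 200.0, cfg) < 0.1

    def test_constant_signal_gives_missing(self):
        cfg = ent.MMSEConfig(scales=(1,), average_scales=(1,), fs=200.0)
        assert math.isnan(ent.mmse(np.ones(6000), 200.0, cfg))


# ---------------------------------------------------------------------------
# LZ76 and CTW
# ---------------------------------------------------------------------------

def lz76_reference(s: np.ndarray) -> int:
    """Reference exhaustive-history parser using substring search."""
    b = bytes(bytearray(s))
    n = len(b)
    c = 1
    i = 1
    while i < n:
        ell = 1
        while i + ell <= n and b[:i + ell - 1].find(b[i:i + ell]) != -1:
            ell += 1
        c += 1
        i += ell
    return c


class TestLZ76:
    def test_parser_matches_reference_on_random_strings(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            s = (rng.random(64) < 0.5).astype(np.uint8)
            assert lz76_phrase_count(s) == lz76_reference(s)

    def test_random_binary_normalizes_near_one(self):
        rng = np.random.default_rng(9)
        s = (rng.random(100_000) < 0.5).astype(np.uint8)
        c = lz76_phrase_count(s)
        norm = c * math.log2(len(s)) / len(s)
        assert 0.95 <= norm <= 1.10

    def test_alternating_sequence_is_trivial(self):
        s = np.tile([0, 1], 5000).astype(np.uint8)
        norm = lz76_phrase_count(s) * math.log2(len(s)) / len(s)
        assert norm < 0.05

    def test_segment_validity_rule(self):
        rng = np.random.default_rng(10)
        x = rng.standard_normal(200 * 60)
        cfg = ent.LZCTWConfig(fs=200.0)
        mask = np.zeros(len(x), dtype=bool)  # all unusable -> no segments
        assert math.isnan(ent.lz76(x, 200.0, cfg, mask))
        assert not math.isnan(ent.lz76(x, 200.0, cfg))


class TestCTW:
    def test_depth_zero_equals_closed_form_kt(self):
        rng = np.random.default_rng(11)
        s = (rng.random(10) < 0.5).astype(np.uint8)
        n0 = n1 = 0
        logp = 0.0
        for b in s:
            logp += math.log(((n1 if b else n0) + 0.5) / (n0 + n1 + 1))
            n1, n0 = n1 + int(b), n0 + int(1 - b)
        assert ctw_log2_prob(s, 0) == pytest.approx(logp / math.log(2),
                                                    abs=1e-12)

    def test_fair_coin_rate_near_one_bit(self):
        rng = np.random.default_rng(12)
        s = (rng.random(100_000) < 0.5).astype(np.uint8)
        rate = -ctw_log2_prob(s, 20) / len(s)
        assert 0.99 <= rate <= 1.01

    def test_periodic_sequence_rate_near_zero(self):
        s = np.tile([0, 1], 5000).astype(np.uint8)
        assert -ctw_log2_prob(s, 20) / len(s) < 0.01


# ---------------------------------------------------------------------------
# shared invariances
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("a,b", [(2.5, 0.0), (0.3, -7.0), (10.0, 42.0)])
def test_affine_amplitude_invariance(a, b):
    """All five estimators are unchanged by x -> a*x + b with a > 0."""
    rng = np.random.default_rng(13)
    x = rng.standard_normal(4000)
    y = a * x + b
    s_x = ent.ordinal_symbolize(x, 3, 2)
    s_y = ent.ordinal_symbolize(y, 3, 2)
    np.testing.assert_array_equal(s_x.symbols, s_y.symbols)
    cfg = ent.LZCTWConfig(segment_s=20.0, fs=200.0, min_samples=1000)
    assert ent.lz76(x, 200.0, cfg) == ent.lz76(y, 200.0, cfg)
    assert ent.ctw_entropy_rate(x, 200.0, cfg) == ent.ctw_entropy_rate(
        y, 200.0, cfg)
    mcfg = ent.MMSEConfig(scales=(1, 2), average_scales=(1, 2),
                          segment_s=10.0, fs=200.0)
    assert ent.mmse(x, 200.0, mcfg) == pytest.approx(
        ent.mmse(y, 200.0, mcfg), abs=1e-9)


def test_wake_member_has_higher_entropy_on_matched_spectra(as_pair):
    """For a matched-amplitude-spectrum pair whose wake member is the
    phase-randomized surrogate, each single-channel complexity estimator
    (and PermEn at delays of two samples and up) is higher for wake."""
    _, wake, sleep = as_pair
    ch = 9  # Cz
    for tau in (2, 4, 8):
        gw = ent.perm_entropy_batch(ent.symbolize_batch(wake.data, 3, tau))
        gs = ent.perm_entropy_batch(ent.symbolize_batch(sleep.data, 3, tau))
        assert gw.mean() > gs.mean()
    cfg = ent.LZCTWConfig(segment_s=60.0, fs=125.0)
    assert ent.lz76(wake.data[ch], 125.0, cfg) > ent.lz76(
        sleep.data[ch], 125.0, cfg)
    assert ent.ctw_entropy_rate(wake.data[ch], 125.0, cfg) > \
        ent.ctw_entropy_rate(sleep.data[ch], 125.0, cfg)
    mcfg = ent.MMSEConfig(scales=tuple(range(1, 11)),
                          average_scales=tuple(range(1, 11)), fs=125.0)
    assert ent.mmse(wake.data[ch][:3750], 125.0, mcfg) > ent.mmse(
        sleep.data[ch][:3750], 125.0, mcfg)
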