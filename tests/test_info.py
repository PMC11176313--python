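"""Information estimators vs independent enumeration oracles and limits."""

import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import normalized_mutual_info_score

import wirevo as wv
from wirevo.info import InfoEstimatorConfig, discretize


def te_enumeration_oracle(sx, sy, k=1, l=1):
    """Brute-force plug-in TE (bits) over explicit probability tables."""
    n = len(sx)
    m = max(k, l)
    triples = [
        (sy[t + 1], tuple(sy[t - k + 1 : t + 1]), tuple(sx[t - l + 1 : t + 1]))
        for t in range(m - 1, n - 1)
    ]
    N = len(triples)
    c_full = Counter(triples)
    c_yh = Counter(t[1] for t in triples)
    c_yhxh = Counter((t[1], t[2]) for t in triples)
    c_yyh = Counter((t[0], t[1]) for t in triples)
    te = 0.0
    for (y1, yh, xh), c in c_full.items():
        p_cond_full = c / c_yhxh[(yh, xh)]
        p_cond_self = c_yyh[(y1, yh)] / c_yh[yh]
        te += (c / N) * math.log2(p_cond_full / p_cond_self)
    return te


def mi_enumeration_oracle(sx, sy):
    """Brute-force plug-in MI (bits) from joint counts."""
    N = len(sx)
    cx, cy = Counter(sx), Counter(sy)
    cxy = Counter(zip(sx, sy))
    return sum(
        (c / N) * math.log2((c / N) / ((cx[x] / N) * (cy[y] / N)))
        for (x, y), c in cxy.items()
    )


class TestTransferEntropy:
    def test_independent_series_near_zero(self):
        rng = np.random.default_rng(0)
        x, y = rng.random(10_000), rng.random(10_000)
        assert wv.transfer_entropy(x, y) < 0.05

    def test_binary_relay_is_one_bit(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 2, 10_000).astype(float)
        y = np.roll(x, 1)
        y[0] = 0.0
        te = wv.transfer_entropy(x, y, InfoEstimatorConfig(n_bins=2))
        assert abs(te - 1.0) < 0.01

    def test_asymmetry_of_the_relay(self):
        rng = np.random.default_rng(2)
        x = rng.integers(0, 2, 5_000).astype(float)
        y = np.roll(x, 1)
        y[0] = 0.0
        cfg = InfoEstimatorConfig(n_bins=2)
        assert wv.transfer_entropy(x, y, cfg) > 0.9
        assert wv.transfer_entropy(y, x, cfg) < 0.05

    def test_self_predictable_target_is_zero(self):
        rng = np.random.default_rng(3)
        x = rng.random(500)
        y = np.full(500, 0.0)
        y[0] = 0.3
        for t in range(499):
            y[t + 1] = y[t]
        assert wv.transfer_entropy(x, y) == 0.0

    def test_constant_series_defined_as_zero(self):
        x = np.arange(20.0)
        assert wv.transfer_entropy(x, np.zeros(20)) == 0.0

    def test_bounds(self):
        rng = np.random.default_rng(4)
        cfg = InfoEstimatorConfig(n_bins=8)
        te = wv.transfer_entropy(rng.random(300), rng.random(300), cfg)
        assert 0 <= te <= 3.0  # log2(8)

    def test_length_validation(self):
        with pytest.raises(ValueError):
            wv.transfer_entropy(np.zeros(3), np.zeros(3))
        with pytest.raises(ValueError):
            wv.transfer_entropy(np.zeros(5), np.zeros(6))

    @settings(deadline=None, max_examples=60)
    @given(
        data=st.data(),
        n=st.integers(6, 12),
        bins=st.integers(2, 3),
        k=st.integers(1, 2),
        l=st.integers(1, 2),
    )
    def test_matches_enumeration_oracle(self, data, n, bins, k, l):
        sx = data.draw(st.lists(st.integers(0, bins - 1), min_size=n, max_size=n))
        sy = data.draw(st.lists(st.integers(0, bins - 1), min_size=n, max_size=n))
        if n < k + l + 2:
            return
        # make both series span the full symbol range so equal-width binning
        # maps symbol i to bin i
        sx[:bins] = list(range(bins))
        sy[:bins] = list(range(bins))
        cfg = InfoEstimatorConfig(n_bins=bins, k=k, l=l)
        got = wv.transfer_entropy(np.array(sx, float), np.array(sy, float), cfg)
        want = te_enumeration_oracle(sx, sy, k, l)
        assert got == pytest.approx(want, abs=1e-12)


class TestMutualInformation:
    def test_independent_near_zero(self):
        rng = np.random.default_rng(5)
        assert wv.mutual_information(rng.random(10_000), rng.random(10_000)) < 0.01

    def test_identity_binary_is_one_bit(self):
        x = np.tile([0.0, 1.0], 5_000)
        assert wv.mutual_information(x, x, InfoEstimatorConfig(n_bins=2)) == 1.0

    def test_exact_symmetry(self):
        rng = np.random.default_rng(6)
        x, y = rng.random(400), rng.random(400)
        assert wv.mutual_information(x, y) == wv.mutual_information(y, x)

    @settings(deadline=None, max_examples=40)
    @given(data=st.data(), n=st.integers(4, 12), bins=st.integers(2, 3))
    def test_matches_enumeration_oracle(self, data, n, bins):
        sx = data.draw(st.lists(st.integers(0, bins - 1), min_size=n, max_size=n))
        sy = data.draw(st.lists(st.integers(0, bins - 1), min_size=n, max_size=n))
        sx[:bins] = list(range(bins))
        sy[:bins] = list(range(bins))
        cfg = InfoEstimatorConfig(n_bins=bins)
        got = wv.mutual_information(np.array(sx, float), np.array(sy, float), cfg)
        assert got == pytest.approx(mi_enumeration_oracle(sx, sy), abs=1e-12)


class TestNMI:
    def test_identical_labels(self):
        labels = np.array(["a", "b", "a", "c", "b", "a"])
        assert wv.nmi(labels, labels) == 1.0

    def test_permutation_invariance(self):
        a = np.array([0, 0, 1, 1, 2, 2, 0, 1])
        b = np.array(["z", "z", "x", "x", "y", "y", "z", "x"])
        assert wv.nmi(a, b) == pytest.approx(1.0, abs=1e-12)

    def test_independent_labels_near_zero(self):
        rng = np.random.default_rng(7)
        a = np.repeat([0, 1], 5_000)
        b = rng.integers(0, 2, 10_000)
        assert wv.nmi(a, b) < 0.01

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            wv.nmi(np.zeros(10), np.arange(10))

    def test_matches_sklearn_geometric(self):
        rng = np.random.default_rng(8)
        a = rng.integers(0, 4, 200)
        b = (a + (rng.random(200) < 0.3)) % 4
        ours = wv.nmi(a, b)
        ref = normalized_mutual_info_score(a, b, average_method="geometric")
        assert ours == pytest.approx(ref, abs=1e-10)


class TestPatternTE:
    def test_zero_wiring_low_te(self, pattern, params, long_series):
        pat0 = pattern.with_weights(np.zeros_like(pattern.W))
        te = wv.pattern_te(pat0, wv.init_readout_weights(params, 0),
                           long_series, params, seed=1)
        # 256 noise-driven pairs with finite-sample bias only
        assert te / 256 < 0.1

    def test_sum_aggregation_consistent_with_map(self, pattern, params, tiny_series):
        W_out = wv.init_readout_weights(params, 0)
        te = wv.pattern_te(pattern, W_out, tiny_series, params, seed=4)
        mat = wv.te_map(pattern, W_out, tiny_series, params, seed=4)
        assert te == pytest.approx(mat.sum(), abs=1e-9)

    def test_relay_chain_exceeds_unwired_baseline(self, pattern, params):
        # a strong direct input->readout relay must transfer more
        # information on that pair than no pathway at all (paired runs).
        # The stimulus reaches a readout activation two steps after arriving
        # at the input unit (input routing, then one synapse), so the source
        # history must span that delay (l=2); alpha=1 removes the additional
        # leaky-integration lag that would otherwise let the target's own
        # past absorb the signal.
        relay = np.zeros_like(pattern.W)
        relay[pattern.readout_units[0], pattern.input_units[0]] = 3.0
        pat_relay = pattern.with_weights(relay)
        pat0 = pattern.with_weights(np.zeros_like(pattern.W))
        p = wv.ReservoirParams(alpha=1.0)
        cfg = InfoEstimatorConfig(n_bins=4, l=2)
        rng = np.random.default_rng(6)
        held = np.repeat(rng.random((100, 16)), 20, axis=0)  # 20-step holds
        series = wv.StimulusSeries(
            vectors=held,
            labels=np.full(len(held), "training", dtype=object),
            clip_size=4,
        )
        W_out = wv.init_readout_weights(params, 0)
        m_relay = wv.te_map(pat_relay, W_out, series, p, cfg, seed=1)
        m_zero = wv.te_map(pat0, W_out, series, p, cfg, seed=1)
        assert m_relay[0, 0] > m_zero[0, 0] + 0.05

    def test_mean_aggregation(self, pattern, params, tiny_series):
        W_out = wv.init_readout_weights(params, 0)
        cfg = InfoEstimatorConfig(aggregate="mean")
        te_mean = wv.pattern_te(pattern, W_out, tiny_series, params, cfg, seed=4)
        te_sum = wv.pattern_te(pattern, W_out, tiny_series, params, seed=4)
        assert te_mean == pytest.approx(te_sum / 256, rel=1e-9)


def test_discretize_contract():
    x = np.array([0.0, 0.5, 1.0])
    np.testing.assert_array_equal(discretize(x, 2), [0, 1, 1])
    np.testing.assert_array_equal(discretize(np.full(5, 3.3), 8), np.zeros(5))


def test_config_validation():
    with pytest.raises(ValueError):
        InfoEstimatorConfig(n_bins=1)
    with pytest.raises(ValueError):
        InfoEstimatorConfig(k=0)
    with pytest.raises(ValueError):
        InfoEstimatorConfig(aggregate="median")
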