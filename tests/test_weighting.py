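import math

import numpy as np
import pytest

from dilifp.weighting import (
    SubstructureCounts,
    apply_weights,
    build_weight_vector,
    count_substructures,
    smoothed_stats,
    read_weight_table,
    write_weight_table,
)

from _oracles import count_bits_loop, pseudo_count_bayes
from conftest import make_dataset


class TestCounting:
    def test_direct_count(self, tiny_ds):
        c = count_substructures(tiny_ds)
        assert list(c.c_sp) == [2, 1]
        assert list(c.c_sn) == [0, 1]
        assert (c.n_pos, c.n_neg) == (2, 1)

    def test_all_zero_column(self):
        ds = make_dataset([[0, 1], [0, 1]], ["positive", "negative"])
        c = count_substructures(ds)
        assert c.c_sp[0] == 0 and c.c_sn[0] == 0

    def test_unlabeled_rows_ignored(self):
        ds = make_dataset([[1], [1], [1]], ["positive", "negative", "unlabeled"])
        c = count_substructures(ds)
        assert (c.n_pos, c.n_neg) == (1, 1)
        assert c.c_sp[0] == 1

    def test_single_class_rejected(self):
        ds = make_dataset([[1], [0]], ["positive", "positive"])
        with pytest.raises(ValueError, match="each class"):
            count_substructures(ds)

    def test_matches_per_cell_loop_oracle(self):
        rng = np.random.default_rng(7)
        X = (rng.random((50, 20)) < 0.3).astype(int)
        labels = ["positive" if b else "negative" for b in rng.integers(0, 2, 50)]
        ds = make_dataset(X, labels)
        c = count_substructures(ds)
        c_sp, c_sn = count_bits_loop(X.tolist(), labels)
        assert list(c.c_sp) == c_sp
        assert list(c.c_sn) == c_sn


class TestSmoothedStats:
    def test_worked_example_against_arithmetic_oracle(self):
        # 180 positives / 132 negatives, one bit in 90 positives and 11 negatives
        c = SubstructureCounts(c_sp=[90], c_sn=[11], n_pos=180, n_neg=132)
        s = smoothed_stats(c, k=1)
        post_ref, _, L_ref = pseudo_count_bayes(90, 11, 180, 132, 1)
        assert s.p_s_given_pos[0] == pytest.approx(91 / 182, abs=1e-15)
        assert s.p_s_given_neg[0] == pytest.approx(12 / 134, abs=1e-15)
        assert s.post_pos[0] == pytest.approx(post_ref, abs=1e-12)
        assert s.log_odds[0] == pytest.approx(L_ref, abs=1e-12)
        # printed-precision values
        assert round(s.post_pos[0], 4) == 0.8839
        assert round(s.log_odds[0], 3) == 2.929

    def test_symmetric_counts_give_even_odds(self):
        c = SubstructureCounts(c_sp=[7, 0], c_sn=[7, 0], n_pos=30, n_neg=30)
        for k in (0.5, 1, 5):
            s = smoothed_stats(c, k=k)
            assert np.allclose(s.post_pos, 0.5, atol=1e-15)
            assert np.allclose(s.log_odds, 0.0, atol=1e-12)

    def test_posterior_and_log_odds_identities_random(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            n_pos = int(rng.integers(2, 300))
            n_neg = int(rng.integers(2, 300))
            n_bits = int(rng.integers(1, 15))
            c = SubstructureCounts(
                c_sp=rng.integers(0, n_pos + 1, n_bits),
                c_sn=rng.integers(0, n_neg + 1, n_bits),
                n_pos=n_pos, n_neg=n_neg,
            )
            s = smoothed_stats(c, k=float(rng.choice([0.5, 1.0, 2.0])))
            assert np.all(np.abs(s.post_pos + s.post_neg - 1) < 1e-12)
            assert np.all(
                np.abs(s.log_odds - np.log2(s.post_pos / s.post_neg)) < 1e-12
            )
            assert np.all((s.p_s_given_pos > 0) & (s.p_s_given_pos < 1))

    def test_k_zero_with_degenerate_bit_rejected(self):
        c = SubstructureCounts(c_sp=[0], c_sn=[3], n_pos=10, n_neg=10)
        with pytest.raises(ValueError, match="k>0"):
            smoothed_stats(c, k=0)

    def test_k_zero_without_degenerate_bits_is_unsmoothed(self):
        c = SubstructureCounts(c_sp=[4], c_sn=[2], n_pos=10, n_neg=10)
        s = smoothed_stats(c, k=0)
        assert s.p_s_given_pos[0] == 0.4
        assert s.p_s_given_neg[0] == 0.2

    def test_monotone_in_counts(self):
        # more positive carriers never lowers L; more negative carriers never raises it
        rng = np.random.default_rng(9)
        for _ in range(50):
            n_pos, n_neg = int(rng.integers(5, 100)), int(rng.integers(5, 100))
            c_sp = int(rng.integers(0, n_pos))
            c_sn = int(rng.integers(0, n_neg))
            k = float(rng.choice([0.5, 1.0, 2.0]))

            def L(csp, csn):
                c = SubstructureCounts(c_sp=[csp], c_sn=[csn], n_pos=n_pos, n_neg=n_neg)
                return smoothed_stats(c, k=k).log_odds[0]

            assert L(c_sp + 1, c_sn) >= L(c_sp, c_sn) - 1e-12
            if c_sn + 1 <= n_neg:
                assert L(c_sp, c_sn + 1) <= L(c_sp, c_sn) + 1e-12

    def test_large_k_shrinks_posterior_to_prior(self):
        c = SubstructureCounts(c_sp=[90, 3], c_sn=[11, 60], n_pos=180, n_neg=132)
        s = smoothed_stats(c, k=1e9)
        assert np.allclose(s.post_pos, s.prior_pos, atol=1e-6)

    def test_smoothed_priors_flag(self):
        c = SubstructureCounts(c_sp=[5], c_sn=[5], n_pos=10, n_neg=30)
        s = smoothed_stats(c, k=1, smooth_priors=True)
        assert s.prior_pos == pytest.approx(11 / 42)


class TestWeightVector:
    def test_threshold_rule(self):
        stats = _stats_with_L([3.0, 0.4, -1.0])
        wv = build_weight_vector(stats, theta=2.5, n_mult=15)
        assert wv.w == pytest.approx([45.0, 1.0, 1.0])
        assert list(wv.selected) == [0]

    def test_tie_at_threshold_is_selected(self):
        stats = _stats_with_L([2.5, 2.4999])
        wv = build_weight_vector(stats, theta=2.5, n_mult=10)
        assert list(wv.selected) == [0]

    def test_infinite_threshold_disables_weighting(self):
        stats = _stats_with_L([5.0, 1.0])
        wv = build_weight_vector(stats, theta=math.inf, n_mult=15)
        assert np.array_equal(wv.w, [1.0, 1.0])
        assert wv.selected.size == 0

    def test_nonpositive_threshold_rejected(self):
        stats = _stats_with_L([1.0])
        for theta in (0.0, -1.0):
            with pytest.raises(ValueError, match="theta"):
                build_weight_vector(stats, theta=theta, n_mult=15)

    def test_nonpositive_multiplier_rejected(self):
        with pytest.raises(ValueError, match="n_mult"):
            build_weight_vector(_stats_with_L([1.0]), theta=1.0, n_mult=0)

    def test_round_trip_through_csv_and_json(self, tmp_path):
        stats = _stats_with_L([3.0, 0.4, 2.6])
        wv = build_weight_vector(stats, theta=2.5, n_mult=15)
        write_weight_table(wv, stats, tmp_path / "w.csv", tmp_path / "w.json")
        back = read_weight_table(tmp_path / "w.csv", tmp_path / "w.json")
        assert np.allclose(back.w, wv.w)
        assert back.theta == wv.theta and back.n_mult == wv.n_mult
        assert list(back.selected) == list(wv.selected)


class TestApplyWeights:
    def test_elementwise_product(self):
        from dilifp.weighting import WeightVector

        wv = WeightVector(w=[45.0, 1.0, 9.0], theta=1.0, n_mult=1.0, selected=[0, 2])
        out = apply_weights(np.array([[1, 0, 1]]), wv)
        assert np.array_equal(out, [[45.0, 0.0, 9.0]])

    def test_all_ones_is_identity(self):
        X = np.eye(4, dtype=int)
        out = apply_weights(X, np.ones(4))
        assert np.array_equal(out, X)

    def test_matches_nested_loop_oracle(self):
        rng = np.random.default_rng(1)
        X = (rng.random((30, 10)) < 0.4).astype(int)
        w = rng.uniform(0.5, 50, 10)
        out = apply_weights(X, w)
        for i in range(30):
            for j in range(10):
                assert out[i, j] == X[i, j] * w[j]

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            apply_weights(np.ones((2, 3), dtype=int), np.ones(4))


class TestPlantedSignal:
    def test_causal_bits_dominate_log_odds_ranking(self):
        """Bits planted at a higher rate in positives should top the L ranking."""
        from dilifp.synthetic import SyntheticSpec, generate

        hits = 0
        for seed in range(8):
            spec = SyntheticSpec(n_pos=200, n_neg=200, n_bits=200,
                                 causal_bits=tuple(range(10)),
                                 p_causal_pos=0.6, p_causal_neg=0.1,
                                 p_background=0.1, seed=seed)
            ds = generate(spec)
            s = smoothed_stats(count_substructures(ds), k=1)
            top10 = set(np.argsort(s.log_odds)[::-1][:10])
            hits += top10 == set(range(10))
        assert hits >= 7


def _stats_with_L(L_values):
    """Construct stats whose log_odds equal the given values (other fields dummy)."""
    L = np.asarray(L_values, dtype=float)
    n = L.shape[0]
    c = SubstructureCounts(c_sp=np.ones(n, int), c_sn=np.ones(n, int), n_pos=5, n_neg=5)
    s = smoothed_stats(c, k=1)
    s.log_odds = L
    post = 2.0 ** L / (1 + 2.0 ** L)
    s.post_pos, s.post_neg = post, 1 - post
    return s
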