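"""Differential-expression impact: clustering, DE calls, scores, subsampling."""

import warnings

import numpy as np
import pytest

from taafgex.dge_impact import (
    artificial_phenotypes,
    call_de,
    confusion_scores,
    rank_agreement,
    subsample_experiment,
)


class TestArtificialPhenotypes:
    def _blobs(self, n_per=300, sep=10.0, seed=0):
        rng = np.random.default_rng(seed)
        a = rng.normal(0.0, 1.0, size=(n_per, 5))
        b = rng.normal(sep, 1.0, size=(n_per, 5))
        x = np.vstack([a, b])
        membership = np.array([0] * n_per + [1] * n_per)
        return x, membership

    def test_recovers_planted_partition(self):
        x, membership = self._blobs()
        idx, labels = artificial_phenotypes(x, n_samples=600, min_cluster=250, seed=1)
        got = labels
        want = membership[idx]
        agree = np.mean(got == want)
        assert agree in (0.0, 1.0)  # exact up to label swap

    def test_deterministic(self):
        x, _ = self._blobs()
        a = artificial_phenotypes(x, n_samples=600, min_cluster=250, seed=3)
        b = artificial_phenotypes(x, n_samples=600, min_cluster=250, seed=3)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_min_cluster_too_large(self):
        x, _ = self._blobs()
        with pytest.raises(ValueError, match="min_cluster"):
            artificial_phenotypes(x, n_samples=600, min_cluster=301, seed=0)


class TestCallDe:
    def test_type_one_error_under_null(self):
        # identical class distributions, 5,000 genes: ~5% of raw p < 0.05
        rng = np.random.default_rng(0)
        x = rng.normal(size=(40, 5000))
        labels = np.array(["a"] * 20 + ["b"] * 20)
        tab = call_de(x, labels)
        frac = np.mean(tab["p"] < 0.05)
        assert 0.04 <= frac <= 0.06

    def test_planted_effect_recovered_exactly(self):
        # 10 genes shifted by 5 noise sds, 200 samples per class
        rng = np.random.default_rng(1)
        x = rng.normal(size=(400, 200))
        x[200:, :10] += 5.0
        labels = np.array(["a"] * 200 + ["b"] * 200)
        tab = call_de(x, labels, alpha_adj=0.01)
        np.testing.assert_array_equal(
            tab["de"].to_numpy(), np.arange(200) < 10
        )

    def test_bh_adjustment_properties(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(20, 50))
        x[10:, :5] += 2.0
        tab = call_de(x, ["a"] * 10 + ["b"] * 10)
        order = np.argsort(tab["p"].to_numpy())
        adj_sorted = tab["p_adj"].to_numpy()[order]
        assert np.all(np.diff(adj_sorted) >= -1e-12)  # monotone in raw-p order
        assert np.all(tab["p_adj"] >= tab["p"] - 1e-12)

    def test_small_class_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            call_de(np.zeros((3, 4)), ["a", "a", "b"])

    def test_zero_variance_equal_means_gives_p_one(self):
        x = np.ones((8, 3))
        tab = call_de(x, ["a"] * 4 + ["b"] * 4)
        np.testing.assert_array_equal(tab["p"].to_numpy(), np.ones(3))


def _brute_force_scores(truth, pred):
    tp = fp = fn = tn = 0
    for t, p in zip(truth, pred):
        if t and p:
            tp += 1
        elif not t and p:
            fp += 1
        elif t and not p:
            fn += 1
        else:
            tn += 1
    n = tp + fp + fn + tn
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0

    def fb(beta):
        d = beta**2 * prec + rec
        return (1 + beta**2) * prec * rec / d if d else 0.0

    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom else 0.0
    return {
        "accuracy": (tp + tn) / n,
        "f_half": fb(0.5),
        "f1": fb(1.0),
        "f2": fb(2.0),
        "mcc": mcc,
    }


class TestConfusionScores:
    def test_perfect_prediction(self):
        truth = [True, False, True, False]
        s = confusion_scores(truth, truth)
        assert all(v == 1.0 for v in s.values())

    def test_hand_case_tp2_fp1_fn1_tn6(self):
        truth = [1, 1, 1, 0, 0, 0, 0, 0, 0, 0]
        pred = [1, 1, 0, 1, 0, 0, 0, 0, 0, 0]
        s = confusion_scores(np.array(truth, bool), np.array(pred, bool))
        np.testing.assert_allclose(s["f1"], 2 / 3, atol=1e-12)
        np.testing.assert_allclose(s["accuracy"], 0.8, atol=1e-12)
        np.testing.assert_allclose(s["mcc"], 11 / 21, atol=1e-12)

    def test_f_beta_precision_recall_case(self):
        # P = 1, R = 0.5: F_0.5 = 5/6, F_2 = 5/9
        truth = [1, 1, 0, 0]
        pred = [1, 0, 0, 0]
        s = confusion_scores(np.array(truth, bool), np.array(pred, bool))
        np.testing.assert_allclose(s["f_half"], 5 / 6, atol=1e-12)
        np.testing.assert_allclose(s["f2"], 5 / 9, atol=1e-12)

    def test_matches_brute_force_on_random_flags(self):
        rng = np.random.default_rng(3)
        for _ in range(500):
            n = int(rng.integers(2, 30))
            truth = rng.random(n) < 0.4
            pred = rng.random(n) < 0.4
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                got = confusion_scores(truth, pred)
            want = _brute_force_scores(truth, pred)
            for k in want:
                np.testing.assert_allclose(got[k], want[k], atol=1e-12)

    def test_f1_is_harmonic_mean_where_positive(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            truth = rng.random(30) < 0.5
            pred = rng.random(30) < 0.5
            tp = np.sum(truth & pred)
            if tp == 0:
                continue
            p = tp / np.sum(pred)
            r = tp / np.sum(truth)
            s = confusion_scores(truth, pred)
            np.testing.assert_allclose(s["f1"], 2 / (1 / p + 1 / r), atol=1e-12)

    def test_degenerate_denominator_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            s = confusion_scores([False, False], [False, False])
        assert s["f1"] == 0.0 and s["mcc"] == 0.0


class TestRankAgreement:
    def test_identical_orderings(self):
        p = np.array([0.01, 0.2, 0.5])
        assert rank_agreement(p, p, ["a", "b", "c"], k=3) == 0.0

    def test_swapped_top_two(self):
        truth = np.array([0.01, 0.02, 0.03, 0.9])
        inferred = np.array([0.02, 0.01, 0.03, 0.9])
        got = rank_agreement(truth, inferred, list("abcd"), selection="top-k", k=3)
        np.testing.assert_allclose(got, 2 / 3)

    def test_reversed_top_k(self):
        # top-3 exactly reversed within the top-3 positions: mean (2+0+2)/3
        truth = np.array([0.01, 0.02, 0.03, 0.9])
        inferred = np.array([0.03, 0.02, 0.01, 0.9])
        got = rank_agreement(truth, inferred, list("abcd"), selection="top-k", k=3)
        np.testing.assert_allclose(got, 4 / 3)

    def test_p_threshold_mode_and_empty_set(self):
        truth = np.array([0.5, 0.6, 0.7])
        inferred = np.array([0.7, 0.6, 0.5])
        with pytest.warns(UserWarning, match="empty"):
            got = rank_agreement(truth, inferred, list("abc"), selection="p-threshold")
        assert np.isnan(got)

    def test_ties_broken_by_gene_id(self):
        truth = np.array([0.1, 0.1, 0.9])
        inferred = np.array([0.1, 0.1, 0.9])
        # deterministic despite ties -> zero displacement
        assert rank_agreement(truth, inferred, ["b", "a", "c"], k=2) == 0.0


class TestSubsampleExperiment:
    def _phenotype_data(self, seed=0, n=240, genes=60):
        # graded effect sizes keep truth DE calls genuinely uncertain at
        # realistic study sizes instead of saturating
        rng = np.random.default_rng(seed)
        truth = rng.normal(size=(n, genes))
        truth[n // 2 :, :12] += np.linspace(0.8, 3.0, 12)
        labels = np.array(["a"] * (n // 2) + ["b"] * (n // 2))
        gene_ids = [f"g{j:02d}" for j in range(genes)]
        return truth, labels, gene_ids

    def test_self_comparison_is_perfect(self):
        truth, labels, gene_ids = self._phenotype_data()
        results, _ = subsample_experiment(
            truth, {"self": truth}, labels, gene_ids,
            sizes=[20], repetitions=10, seed=0,
        )
        assert (results["f1"] == 1.0).all()
        assert (results["rank_mae_top100"] == 0.0).all()

    def test_deterministic(self):
        truth, labels, gene_ids = self._phenotype_data()
        noisy = truth + np.random.default_rng(1).normal(scale=0.3, size=truth.shape)
        kw = dict(sizes=[16], repetitions=5, seed=7)
        r1, t1 = subsample_experiment(truth, {"m": noisy}, labels, gene_ids, **kw)
        r2, t2 = subsample_experiment(truth, {"m": noisy}, labels, gene_ids, **kw)
        assert r1.equals(r2) and t1.equals(t2)

    def test_lower_noise_wins(self):
        # truth + noise at sd 0.1 vs 0.5: the cleaner method has higher
        # median F1 at every size, Wilcoxon p < 0.01
        truth, labels, gene_ids = self._phenotype_data(seed=2)
        rng = np.random.default_rng(3)
        methods = {
            "low": truth + rng.normal(scale=0.1, size=truth.shape),
            "high": truth + rng.normal(scale=0.5, size=truth.shape),
        }
        results, tests = subsample_experiment(
            truth, methods, labels, gene_ids, sizes=[12, 24], repetitions=60, seed=4
        )
        for size in (12, 24):
            at = results[results["sample_size"] == size]
            med = at.groupby("method")["f1"].median()
            assert med["low"] > med["high"]
            row = tests[(tests["sample_size"] == size) & (tests["metric"] == "f1")]
            assert float(row["wilcoxon_p"].iloc[0]) < 0.01

    def test_unsupported_size_skipped_with_warning(self):
        truth, labels, gene_ids = self._phenotype_data(n=20)
        with pytest.warns(UserWarning, match="skipped"):
            results, _ = subsample_experiment(
                truth, {"m": truth}, labels, gene_ids, sizes=[500], repetitions=2,
            )
        assert results.empty
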