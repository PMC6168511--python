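"""Classification machinery: folds, classifiers, exact binomial tests, transfer."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest

from vocalsig import classify, features, synth


def brute_force_binomial_p(k: int, n: int, p: float = 0.5) -> float:
    """Two-sided exact binomial p by full enumeration (small-sample oracle)."""
    probs = [comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(n + 1)]
    pk = probs[k]
    return min(1.0, sum(q for q in probs if q <= pk * (1 + 1e-12)))


def make_features(n_voc=2, n_rend=10, sep=5.0, seed=0, call_type="DC"):
    """Gaussian feature table with controllable class separation."""
    rng = np.random.default_rng(seed)
    rows = []
    for v in range(n_voc):
        center = rng.standard_normal(18) * sep
        for r in range(n_rend):
            vals = center + rng.standard_normal(18)
            row = {"vocalizer_id": f"v{v:02d}", "call_type": call_type, "rendition_id": f"r{r:03d}"}
            row.update(dict(zip(features.PAF_FEATURES, vals)))
            rows.append(row)
    return pd.DataFrame(rows)


class TestFilterMinRenditions:
    def test_boundary(self):
        df = pd.concat([make_features(1, 4, seed=1), make_features(1, 5, seed=2).assign(vocalizer_id="v99")])
        out = classify.filter_min_renditions(df, min_n=5)
        assert set(out["vocalizer_id"]) == {"v99"}

    def test_no_op_when_all_large(self):
        df = make_features(3, 8)
        pd.testing.assert_frame_equal(classify.filter_min_renditions(df, 5), df)

    def test_empty_result_aborts(self):
        with pytest.raises(ValueError, match="renditions"):
            classify.filter_min_renditions(make_features(2, 3), min_n=5)


class TestMakeFolds:
    def test_tenfold_for_thirty_per_class(self):
        labels = np.repeat(["a", "b"], 30)
        folds = classify.make_folds(labels, seed=1)
        assert len(folds) == 10
        assert all(len(te) == 6 for _, te in folds)

    def test_fivefold_for_small_classes(self):
        labels = np.array(["a"] * 7 + ["b"] * 9)
        assert len(classify.make_folds(labels, seed=1)) == 5

    def test_partition_property(self):
        labels = np.repeat(["a", "b", "c"], 13)
        folds = classify.make_folds(labels, seed=2)
        tested = np.concatenate([te for _, te in folds])
        assert sorted(tested) == list(range(len(labels)))
        for tr, te in folds:
            assert not set(tr) & set(te)

    def test_class_below_minimum_rejected(self):
        with pytest.raises(ValueError):
            classify.make_folds(np.array(["a"] * 3 + ["b"] * 10))

    def test_determinism(self):
        labels = np.repeat(["a", "b"], 20)
        f1 = classify.make_folds(labels, seed=3)
        f2 = classify.make_folds(labels, seed=3)
        for (tr1, te1), (tr2, te2) in zip(f1, f2):
            np.testing.assert_array_equal(te1, te2)


class TestFitPredict:
    @pytest.mark.parametrize("clf", ["lda", "qda", "rf"])
    def test_separable_clouds_perfect(self, clf):
        rng = np.random.default_rng(0)
        Xa = rng.standard_normal((30, 5)) + 20.0
        Xb = rng.standard_normal((30, 5)) - 20.0
        X = np.vstack([Xa, Xb])
        y = np.array(["a"] * 30 + ["b"] * 30)
        pred = classify.fit_predict(X, y, X, classifier=clf, seed=0)
        assert np.all(pred == y)

    def test_lda_matches_closed_form_boundary(self):
        """Shrinkage LDA at large n approaches the population linear rule."""
        rng = np.random.default_rng(1)
        mu_a, mu_b = np.array([1.0, 0.0]), np.array([-1.0, 0.5])
        cov = np.array([[1.0, 0.3], [0.3, 0.5]])
        L = np.linalg.cholesky(cov)
        Xa = rng.standard_normal((2000, 2)) @ L.T + mu_a
        Xb = rng.standard_normal((2000, 2)) @ L.T + mu_b
        X = np.vstack([Xa, Xb])
        y = np.array(["a"] * 2000 + ["b"] * 2000)
        grid = rng.uniform(-3, 3, size=(400, 2))
        pred = classify.fit_predict(X, y, grid, classifier="lda", seed=0)
        # population rule: assign "a" iff w.(x - m) > 0 with w = inv(cov).(mu_a - mu_b)
        w = np.linalg.solve(cov, mu_a - mu_b)
        score = (grid - (mu_a + mu_b) / 2) @ w
        oracle = np.where(score > 0, "a", "b")
        margin = np.abs(score) > 0.2  # away from the boundary
        assert np.mean(pred[margin] == oracle[margin]) > 0.99

    def test_missing_values_imputed_with_indicator(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((40, 3))
        X[:20, 2] = np.nan  # class-aligned missingness is itself informative
        y = np.array(["a"] * 20 + ["b"] * 20)
        pred = classify.fit_predict(X, y, X, classifier="lda", seed=0)
        assert np.all(pred == y)

    def test_unknown_classifier_rejected(self):
        with pytest.raises(ValueError):
            classify.fit_predict(np.zeros((4, 2)), np.array(list("aabb")), np.zeros((1, 2)), "svm")


class TestExactBinomial:
    def test_matches_enumeration_up_to_25(self):
        for n in (5, 10, 17, 25):
            for k in range(n + 1):
                assert classify.exact_binomial_p(k, n) == pytest.approx(
                    brute_force_binomial_p(k, n), abs=1e-12
                )

    def test_null_pcc_example(self):
        assert classify.exact_binomial_p(30, 60) == pytest.approx(1.0)
        # 45/60 correct: clearly above chance
        assert classify.exact_binomial_p(45, 60) == pytest.approx(
            brute_force_binomial_p(45, 60), abs=1e-12
        )
        assert classify.exact_binomial_p(45, 60) < 0.001


class TestPairwise:
    def test_strong_signature_discriminated(self, strong_signature_features):
        res = classify.pairwise_within_type(strong_signature_features, "DC", seed=0)
        assert len(res) == 3  # 3 vocalizers -> 3 pairs
        for r in res:
            assert r.pcc >= 90.0
            assert r.significant
            assert r.n_correct <= r.n_tested

    def test_fold_seed_determinism(self, strong_signature_features):
        a = classify.pairwise_within_type(strong_signature_features, "DC", seed=4)
        b = classify.pairwise_within_type(strong_signature_features, "DC", seed=4)
        assert [(r.n_correct, r.n_tested) for r in a] == [(r.n_correct, r.n_tested) for r in b]

    def test_per_type_signature_strength_ordering(self):
        """A strongly individualized type beats a weak one in mean pairwise PCC."""
        strong = make_features(4, 12, sep=3.0, seed=5, call_type="DC")
        weak = make_features(4, 12, sep=0.3, seed=6, call_type="Ws")
        df = pd.concat([strong, weak], ignore_index=True)
        m_strong = np.mean([r.pcc for r in classify.pairwise_within_type(df, "DC", seed=0)])
        m_weak = np.mean([r.pcc for r in classify.pairwise_within_type(df, "Ws", seed=0)])
        assert m_strong > m_weak


class TestMulticlass:
    def test_confusion_rows_sum_to_test_counts(self, strong_signature_features):
        pcc, conf = classify.multiclass_within_type(strong_signature_features, "DC", seed=0)
        assert conf.sum(axis=1).tolist() == [20, 20, 20]
        assert pcc >= 90.0

    def test_needs_three_vocalizers(self):
        with pytest.raises(ValueError):
            classify.multiclass_within_type(make_features(2, 10), "DC")


@pytest.fixture(scope="module")
def voice_features():
    """Two vocalizers, three types, fully shared voice offsets."""
    cfg = synth.SignatureConfig(
        n_individuals=2, renditions_per_type=10,
        sigma_between=4.0, sigma_within=0.5, rho_voice=1.0, seed=8,
    )
    calls = synth.generate_calls(cfg, synth.default_templates(("DC", "Te", "Tu")))
    return features.extract_paf_table(calls)


class TestCrossType:
    def test_matrix_diagonal_equals_same(self, voice_features):
        res = classify.cross_type_generalization(voice_features, ("v00", "v01"), seed=0)
        for ct in ("DC", "Te", "Tu"):
            assert res["matrix"].loc[ct, ct] == pytest.approx(res["same"][ct].pcc)

    def test_voice_regime_transfers(self, voice_features):
        res = classify.cross_type_generalization(voice_features, ("v00", "v01"), seed=0)
        same = np.mean([r.pcc for r in res["same"].values()])
        other = np.mean([r.pcc for r in res["other"].values()])
        assert other >= same - 15.0

    def test_missing_pair_type_rejected(self):
        df = make_features(2, 10)
        with pytest.raises(ValueError, match="fewer than 2 call types"):
            classify.cross_type_generalization(df, ("v00", "v01"))


class TestSubspaces:
    def test_nested_space_training_separability(self):
        """All (18 features) must fit the training set at least as well as Spect (8)."""
        rng = np.random.default_rng(9)
        df = make_features(2, 15, sep=0.8, seed=9)
        X_all = df[features.PAF_FEATURES].to_numpy()
        X_sp = df[features.SPECTRAL_FEATURES].to_numpy()
        y = df["vocalizer_id"].to_numpy()
        acc_all = np.mean(classify.fit_predict(X_all, y, X_all, "lda", 0) == y)
        acc_sp = np.mean(classify.fit_predict(X_sp, y, X_sp, "lda", 0) == y)
        assert acc_all >= acc_sp

    def test_fund_only_signature_favors_fund_space(self):
        """Signature injected only into f0 shows up in Fund, not Temp, space."""
        rng = np.random.default_rng(10)
        rows = []
        for v in range(2):
            f0_off = 80.0 * (v - 0.5)
            for r in range(15):
                vals = {k: rng.standard_normal() for k in features.PAF_FEATURES}
                for k in ("fund_mean", "fund_min", "fund_max"):
                    vals[k] = 600.0 + f0_off + rng.standard_normal() * 5
                row = {"vocalizer_id": f"v{v:02d}", "call_type": "DC", "rendition_id": f"r{r:03d}"}
                row.update(vals)
                rows.append(row)
        df = pd.DataFrame(rows)
        fund = classify.pairwise_within_type(df, "DC", "Fund", seed=0)[0].pcc
        temp = classify.pairwise_within_type(df, "DC", "Temp", seed=0)[0].pcc
        assert fund > temp
        assert fund >= 90.0

    def test_unvoiced_only_fund_space_at_chance(self):
        """With every f0 feature missing, Fund space carries no identity signal."""
        df = make_features(2, 15, sep=4.0, seed=11)
        df[features.FUNDAMENTAL_FEATURES[:4]] = np.nan
        df["saliency_mean"] = 0.1
        res = classify.pairwise_within_type(df, "DC", "Fund", seed=0)[0]
        assert 20.0 <= res.pcc <= 80.0  # wide binomial band around 50 at n=30
        assert not res.significant

    def test_subspace_table_shape(self, strong_signature_features):
        # call-type objective needs >= 2 types; duplicate as a second type
        other = strong_signature_features.copy()
        other["call_type"] = "Te"
        other[features.PAF_FEATURES] += 3.0
        df = pd.concat([strong_signature_features, other], ignore_index=True)
        # call-type folds need >= 5 samples per class: 3 vocalizers is too few,
        # so widen with jittered copies
        extra = df.copy()
        extra["vocalizer_id"] = extra["vocalizer_id"] + "x"
        extra[features.PAF_FEATURES] += np.random.default_rng(1).normal(0, 0.1, (len(extra), 18))
        df = pd.concat([df, extra], ignore_index=True)
        table = classify.subspace_comparison(df, spaces=("All", "Fund"), seed=0)
        assert set(table["space"]) == {"All", "Fund"}
        assert set(table["objective"]) == {"Identity", "CallType"}
        assert ((table["pcc"] >= 0) & (table["pcc"] <= 100)).all()


class TestSpectrogramSpace:
    def test_spectrogram_classification_separates_strong_signature(self):
        cfg = synth.SignatureConfig(
            n_individuals=2, renditions_per_type=10,
            sigma_between=4.0, sigma_within=0.5, seed=12,
        )
        calls = synth.generate_calls(cfg, synth.default_templates(("DC",)))
        table = classify.spectrogram_table(calls)
        assert table.shape[0] == 20
        res = classify.pairwise_within_type(table, "DC", "Spectrogram", seed=0)[0]
        assert res.pcc >= 80.0
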