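import itertools
import warnings

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from tdmnorm import (
    ClassifierModel,
    ExpressionMatrix,
    LabeledDataset,
    NoiseLadder,
    SimulationConfig,
    cluster_majority_accuracy,
    mean_kendall_tau,
    pam_assign,
    pam_fit,
    predict_classes,
    run_noise_sweep_benchmark,
    score_predictions,
    train_l1_multinomial,
    variability_f_score,
)


def _matrix(values, space="log2"):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    return ExpressionMatrix(
        [f"g{i}" for i in range(values.shape[0])],
        [f"s{j}" for j in range(values.shape[1])], values, space)


def brute_force_pam_cost(X, k):
    """Global optimum over all medoid subsets (samples in columns)."""
    D = cdist(X.T, X.T)
    n = X.shape[1]
    return min(D[:, list(subset)].min(axis=1).sum()
               for subset in itertools.combinations(range(n), k))


class TestPam:
    def test_k_equals_n_zero_cost(self):
        rng = np.random.default_rng(0)
        m = _matrix(rng.normal(size=(4, 5)))
        model = pam_fit(m, k=5)
        assert model.cost == pytest.approx(0.0)
        assert sorted(model.medoid_ids) == sorted(m.sample_ids)

    def test_build_swap_against_exhaustive_search(self):
        """On small random instances the BUILD+SWAP cost is single-swap
        locally optimal, never beats the exhaustive optimum, and matches
        it on the vast majority of instances.  Classic PAM (verified
        against the reference implementation) does land in single-swap
        local optima on a few percent of unstructured instances."""
        matches = 0
        for seed in range(30):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(4, 9))
            k = int(rng.integers(2, 4))
            m = _matrix(rng.normal(size=(3, n)))
            model = pam_fit(m, k=k)
            best = brute_force_pam_cost(m.values, k)
            assert model.cost >= best - 1e-9
            if model.cost == pytest.approx(best):
                matches += 1
            # single-swap local optimality
            D = cdist(m.values.T, m.values.T)
            pos = {s: i for i, s in enumerate(m.sample_ids)}
            medoids = [pos[s] for s in model.medoid_ids]
            for mi in range(k):
                for h in range(n):
                    if h in medoids:
                        continue
                    trial = medoids[:mi] + [h] + medoids[mi + 1:]
                    assert D[:, trial].min(axis=1).sum() >= model.cost - 1e-9
        assert matches >= 27

    def test_separated_blobs_recovered(self):
        rng = np.random.default_rng(1)
        centers = np.array([[0.0, 10.0, 20.0, 30.0]])
        values = np.repeat(centers, 25, axis=1) + rng.normal(scale=1.0, size=(5, 100))
        truth = np.repeat(np.arange(4), 25)
        m = _matrix(values)
        model = pam_fit(m, k=4)
        assert cluster_majority_accuracy(pam_assign(model, m), truth) == 1.0

    def test_assign_training_medoids_to_themselves(self):
        rng = np.random.default_rng(2)
        m = _matrix(rng.normal(size=(4, 12)))
        model = pam_fit(m, k=3)
        medoids = ExpressionMatrix(m.gene_ids, model.medoid_ids,
                                   model.medoid_samples, "log2")
        np.testing.assert_array_equal(pam_assign(model, medoids), [0, 1, 2])

    def test_assign_on_training_matches_fit_clustering(self):
        rng = np.random.default_rng(3)
        m = _matrix(rng.normal(size=(6, 20)))
        model = pam_fit(m, k=3)
        np.testing.assert_array_equal(pam_assign(model, m), model.labels)

    def test_equidistant_point_goes_to_lower_medoid(self):
        m = _matrix(np.array([[0.0, 2.0]]))
        model = pam_fit(m, k=2)  # each sample is its own medoid
        tie = ExpressionMatrix(m.gene_ids, ["t"], np.array([[1.0]]), "log2")
        d = np.abs(model.medoid_samples - 1.0)
        assert d[0, 0] == d[0, 1]
        assert pam_assign(model, tie)[0] == 0

    def test_gene_mismatch_rejected(self):
        rng = np.random.default_rng(4)
        m = _matrix(rng.normal(size=(4, 10)))
        model = pam_fit(m, k=2)
        other = ExpressionMatrix([f"x{i}" for i in range(4)], m.sample_ids,
                                 m.values, "log2")
        with pytest.raises(ValueError, match="gene"):
            pam_assign(model, other)

    def test_k_out_of_range(self):
        m = _matrix(np.random.default_rng(5).normal(size=(3, 4)))
        with pytest.raises(ValueError):
            pam_fit(m, k=5)


class TestClusterMajorityAccuracy:
    def test_perfect_clustering(self):
        assert cluster_majority_accuracy([0, 0, 1, 1], list("AABB")) == 1.0

    def test_hand_counted_example(self):
        # cluster 1 holds (A, A, B), cluster 2 holds (B, B): 4 of 5 samples
        # match their cluster's modal class
        clusters = [1, 1, 1, 2, 2]
        truth = ["A", "A", "B", "B", "B"]
        assert cluster_majority_accuracy(clusters, truth) == pytest.approx(0.8)

    def test_single_cluster_gives_modal_frequency(self):
        assert cluster_majority_accuracy([0] * 5, list("AABBB")) == pytest.approx(0.6)

    def test_modal_tie_broken_alphabetically(self):
        assert cluster_majority_accuracy([0, 0], ["B", "A"]) == pytest.approx(0.5)

    def test_empty_or_mismatched_inputs(self):
        with pytest.raises(ValueError):
            cluster_majority_accuracy([], [])
        with pytest.raises(ValueError):
            cluster_majority_accuracy([1], ["A", "B"])


def separable_dataset(seed=0, n_per=20, n_genes=10):
    rng = np.random.default_rng(seed)
    shift = np.zeros((n_genes, 1))
    shift[:3] = 5.0
    a = rng.normal(size=(n_genes, n_per))
    b = rng.normal(size=(n_genes, n_per)) + shift
    m = _matrix(np.hstack([a, b]))
    return LabeledDataset(m, ["low"] * n_per + ["high"] * n_per)


class TestL1Multinomial:
    def test_separable_classes_fit_perfectly(self):
        data = separable_dataset()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            model = train_l1_multinomial(data, n_folds=5, seed=0)
        assert predict_classes(model, data.matrix) == data.labels
        assert model.penalty > 0

    def test_folds_capped_at_smallest_class(self):
        data = separable_dataset(n_per=6)
        with pytest.warns(RuntimeWarning, match="capped"):
            train_l1_multinomial(data, n_folds=100, seed=0)

    def test_single_class_rejected(self):
        m = _matrix(np.random.default_rng(0).normal(size=(5, 8)))
        with pytest.raises(ValueError, match="2 classes"):
            train_l1_multinomial(LabeledDataset(m, ["x"] * 8), n_folds=3)

    def test_all_zero_coefficients_predict_largest_intercept(self):
        model = ClassifierModel(
            classes=["a", "b", "c"],
            coefficients=np.zeros((3, 2)),
            intercepts=np.array([0.1, 0.7, 0.2]),
            penalty=1.0,
            gene_ids=["g0", "g1"])
        m = _matrix(np.random.default_rng(1).normal(size=(2, 6)))
        assert predict_classes(model, m) == ["b"] * 6

    def test_single_sample_prediction(self):
        data = separable_dataset()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            model = train_l1_multinomial(data, n_folds=4, seed=1)
        one = ExpressionMatrix(data.matrix.gene_ids, ["only"],
                               data.matrix.values[:, :1], "log2")
        assert len(predict_classes(model, one)) == 1

    def test_gene_mismatch_rejected(self):
        data = separable_dataset()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            model = train_l1_multinomial(data, n_folds=4, seed=2)
        other = ExpressionMatrix([f"y{i}" for i in range(10)],
                                 data.matrix.sample_ids, data.matrix.values, "log2")
        with pytest.raises(ValueError, match="gene"):
            predict_classes(model, other)


class TestScorePredictions:
    def test_perfect_agreement(self):
        rep = score_predictions(list("ABAB"), list("ABAB"))
        assert rep.total_accuracy == 1.0
        assert rep.kappa == 1.0
        assert all(v == 1.0 for v in rep.balanced_accuracy.values())

    def test_two_class_confusion_hand_computation(self):
        # confusion (rows truth, cols pred): [[25, 5], [10, 60]]
        truth = ["c1"] * 30 + ["c2"] * 70
        pred = ["c1"] * 25 + ["c2"] * 5 + ["c1"] * 10 + ["c2"] * 60
        rep = score_predictions(pred, truth)
        assert rep.total_accuracy == pytest.approx(0.85)
        assert rep.kappa == pytest.approx(0.6591, abs=1e-4)
        assert rep.balanced_accuracy["c1"] == pytest.approx(0.8452, abs=1e-4)
        assert rep.balanced_accuracy["c2"] == pytest.approx(0.8452, abs=1e-4)
        assert rep.no_information_rate == pytest.approx(0.7)
        assert rep.confusion.to_numpy().sum() == 100
        np.testing.assert_array_equal(rep.confusion.to_numpy(), [[25, 5], [10, 60]])

    def test_constant_majority_prediction_is_chance_level(self):
        truth = ["a"] * 6 + ["b"] * 4
        rep = score_predictions(["a"] * 10, truth)
        assert rep.total_accuracy == pytest.approx(rep.no_information_rate)
        assert rep.kappa == pytest.approx(0.0)

    def test_both_sides_constant_kappa_one(self):
        rep = score_predictions(["x"] * 4, ["x"] * 4)
        assert rep.kappa == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            score_predictions(["a"], ["a", "b"])


class TestVariabilityFScore:
    def test_exchangeable_null_concentrates_near_one(self):
        """When class labels carry no information, the between/within
        variability ratio sits near 1 (median within [0.5, 2]) and rarely
        strays above 2."""
        scores = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            m = _matrix(rng.normal(size=(40, 200)))
            data = LabeledDataset(m, ["a"] * 100 + ["b"] * 100)
            scores.append(variability_f_score(data, n_quantiles=100))
        med = float(np.median(scores))
        assert 0.5 <= med <= 2.0
        assert sum(s < 2.0 for s in scores) >= 90

    def test_shifted_classes_score_far_above_one(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(40, 30))
        b = rng.normal(size=(40, 30)) + 5.0
        data = LabeledDataset(_matrix(np.hstack([a, b])), ["a"] * 30 + ["b"] * 30)
        assert variability_f_score(data) > 10.0

    def test_invariant_to_within_class_permutation(self):
        rng = np.random.default_rng(2)
        values = rng.normal(size=(30, 40))
        labels = ["a"] * 20 + ["b"] * 20
        base = variability_f_score(LabeledDataset(_matrix(values), labels))
        perm = np.concatenate([rng.permutation(20), 20 + rng.permutation(20)])
        shuffled = variability_f_score(
            LabeledDataset(_matrix(values[:, perm]), labels))
        assert shuffled == pytest.approx(base, abs=1e-12)

    def test_singleton_class_rejected(self):
        m = _matrix(np.random.default_rng(3).normal(size=(10, 5)))
        with pytest.raises(ValueError):
            variability_f_score(LabeledDataset(m, ["a"] * 4 + ["b"]))


class TestMeanKendallTau:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(0)
        m = _matrix(rng.normal(size=(20, 5)))
        assert mean_kendall_tau(m, m) == pytest.approx(1.0)

    def test_rank_reversal_is_minus_one(self):
        rng = np.random.default_rng(1)
        m = _matrix(rng.normal(size=(20, 5)))
        rev = m.with_values(-m.values)
        assert mean_kendall_tau(m, rev) == pytest.approx(-1.0)

    def test_hand_counted_column(self):
        a = _matrix(np.array([[1.0], [3.0], [2.0], [4.0]]))
        b = _matrix(np.array([[1.0], [2.0], [3.0], [4.0]]))
        assert mean_kendall_tau(a, b) == pytest.approx(4.0 / 6.0)

    def test_dimension_mismatch_rejected(self):
        a = _matrix(np.ones((3, 2)))
        b = _matrix(np.ones((2, 3)))
        with pytest.raises(ValueError):
            mean_kendall_tau(a, b)


class TestNoiseSweepBenchmark:
    @pytest.fixture(scope="class")
    def small_sweep(self):
        cfg = SimulationConfig(n_genes=40, n_samples=40, seed=5)
        ladder = NoiseLadder(percentages=(0.0, 1.0, 3.8))
        return run_noise_sweep_benchmark(cfg, ladder=ladder), ladder

    def test_table_shape_contract(self, small_sweep):
        table, ladder = small_sweep
        assert len(table) == len(ladder) * 5
        assert set(table.columns) == {"noise_pct", "method", "accuracy"}
        assert table["accuracy"].between(0, 1).all()

    def test_refit_mode_runs(self):
        cfg = SimulationConfig(n_genes=40, n_samples=40, seed=6)
        ladder = NoiseLadder(percentages=(0.0, 2.0))
        table = run_noise_sweep_benchmark(cfg, ladder=ladder,
                                          methods=("tdm", "qn"), refit=True)
        assert len(table) == 4

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown method"):
            run_noise_sweep_benchmark(SimulationConfig(n_genes=20, n_samples=20),
                                      methods=("tdm", "bogus"))
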