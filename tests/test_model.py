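import numpy as np
import pytest

from ppikernel.curation import OrganismTier
from ppikernel.io_formats import EvidencedInteraction
from ppikernel.kernel import Hyperparams, PairVector, kernel_matrix
from ppikernel.model import (
    Dataset,
    PairKernelModel,
    aggregate_curves,
    binomial_error,
    cross_validate,
    grid_search,
    pr_curve,
    predict,
    selection_statistic,
    train,
)
from ppikernel.profiles import ProfileStore
from ppikernel.synthetic import SyntheticSpec, generate_dataset

HP = Hyperparams(3, 4.0)


def separable_pair_vectors(n=40):
    """Two well-separated clusters in k-mer feature space: positives share a
    'POS' feature block, negatives a disjoint 'NEG' block."""
    vectors, labels = [], []
    for i in range(n // 2):
        vectors.append(PairVector(f"pa{i}", f"pb{i}", {"AAA": 1.0, f"PP{i % 5}": 0.4}))
        labels.append(1)
    for i in range(n // 2):
        vectors.append(PairVector(f"na{i}", f"nb{i}", {"CCC": 1.0, f"NN{i % 5}": 0.4}))
        labels.append(-1)
    return vectors, labels


def tiny_planted_dataset(n_positives=20, n_proteins=90, seed=5):
    spec = SyntheticSpec(
        n_proteins=n_proteins,
        length_range=(60, 90),
        n_families=0,
        n_positives=n_positives,
        motif_length=3,
        n_motif_pairs=2,
        fraction_failing=0.0,
        seed=seed,
    )
    proteome, _, interactions, _ = generate_dataset(spec)
    return Dataset(interactions, proteome, ProfileStore(None, pseudo_alpha=0.0))


class TestTrainPredict:
    def test_separable_clusters_fit_perfectly(self):
        vectors, labels = separable_pair_vectors()
        km = kernel_matrix(vectors)
        model = train(km, labels, vectors, HP, seed=0)
        decision, probs = predict(model, vectors)
        assert np.all(np.sign(decision) == np.asarray(labels))
        assert np.all((probs > 0) & (probs < 1))

    def test_model_records_positive_pair_proteins_separately(self):
        # downstream candidate enumeration excludes only proteins of positive
        # training pairs, never the sampled negatives
        vectors, labels = separable_pair_vectors(8)
        km = kernel_matrix(vectors)
        model = train(km, labels, vectors, HP, seed=0)
        assert model.positive_proteins == sorted(
            pid for vec, lab in zip(vectors, labels) if lab == 1 for pid in vec.pair
        )
        assert set(model.positive_proteins) < set(model.training_proteins)

    def test_calibrated_probability_increases_with_decision_value(self):
        vectors, labels = separable_pair_vectors()
        km = kernel_matrix(vectors)
        model = train(km, labels, vectors, HP, seed=0)
        d = np.linspace(-3, 3, 20)
        p = model.probabilities(d)
        assert np.all(np.diff(p) > 0)

    def test_retraining_is_deterministic(self):
        vectors, labels = separable_pair_vectors()
        km = kernel_matrix(vectors)
        m1 = train(km, labels, vectors, HP, seed=3)
        m2 = train(km, labels, vectors, HP, seed=3)
        np.testing.assert_array_equal(m1.dual_coefs, m2.dual_coefs)
        assert m1.bias == m2.bias and m1.calib_a == m2.calib_a

    def test_duplicate_query_rows_give_identical_outputs(self):
        vectors, labels = separable_pair_vectors()
        km = kernel_matrix(vectors)
        model = train(km, labels, vectors, HP, seed=0)
        d, p = predict(model, [vectors[0], vectors[0]])
        assert d[0] == d[1] and p[0] == p[1]

    def test_single_class_labels_rejected(self):
        vectors, _ = separable_pair_vectors(8)
        km = kernel_matrix(vectors)
        with pytest.raises(ValueError, match="both"):
            train(km, [1] * len(vectors), vectors, HP)

    def test_save_load_reproduces_predictions(self, tmp_path):
        vectors, labels = separable_pair_vectors()
        km = kernel_matrix(vectors)
        model = train(km, labels, vectors, HP, seed=0)
        path = tmp_path / "model.json"
        model.save(path)
        back = PairKernelModel.load(path)
        d1, p1 = predict(model, vectors[:5])
        d2, p2 = predict(back, vectors[:5])
        np.testing.assert_array_equal(d1, d2)
        np.testing.assert_array_equal(p1, p2)


class TestBinomialError:
    @pytest.mark.parametrize(
        "p,n,mode,expected",
        [
            (0.5, 100, "as_printed", 25.0),
            (0.0, 50, "as_printed", 0.0),
            (1.0, 50, "standard_error", 0.0),
            (0.5, 100, "standard_error", 0.05),
        ],
    )
    def test_both_modes(self, p, n, mode, expected):
        assert binomial_error(p, n, mode) == pytest.approx(expected)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            binomial_error(1.5, 10)
        with pytest.raises(ValueError):
            binomial_error(0.5, 0)
        with pytest.raises(ValueError):
            binomial_error(0.5, 10, "variance")


class TestPRCurve:
    def test_perfect_ranking_has_unit_precision_everywhere(self):
        scores = [0.9, 0.8, 0.7, 0.3, 0.2, 0.1]
        labels = [1, 1, 1, -1, -1, -1]
        curve = pr_curve(scores, labels)
        assert np.all(curve.precisions() == 1.0)

    def test_hand_enumerated_thresholds(self):
        curve = pr_curve([0.9, 0.8, 0.3], [1, -1, 1], recall_grid=[0.5, 1.0])
        assert curve.points[0].precision == pytest.approx(1.0)
        assert curve.points[1].precision == pytest.approx(2 / 3)
        assert curve.points[0].n_predictions == 1
        assert curve.points[1].n_predictions == 3

    def test_full_recall_precision_equals_prevalence_when_tail_is_positive(self):
        # the smallest set at recall 1 is the whole ranking when the
        # worst-scored item is a positive, so precision equals prevalence
        scores = [0.9, 0.5, 0.4, 0.1]
        labels = [1, -1, -1, 1]
        curve = pr_curve(scores, labels, recall_grid=[1.0])
        assert curve.points[0].precision == pytest.approx(0.5)

    def test_random_scores_hover_near_prevalence_baseline(self, rng):
        n = 2200
        labels = np.where(np.arange(n) < 200, 1, -1)
        scores = rng.uniform(size=n)
        curve = pr_curve(scores, labels, recall_grid=[1.0])
        p = curve.points[0].precision
        prevalence = 200 / 2200
        sd = 3 * np.sqrt(prevalence * (1 - prevalence) / n)
        assert abs(p - prevalence) < 3 * sd + 0.01

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError, match="positives"):
            pr_curve([0.5, 0.4], [-1, -1])


class TestSelectionStatistic:
    def test_constant_curve(self):
        curve = pr_curve([0.9, 0.8, 0.7, 0.1], [1, 1, 1, -1], recall_grid=[0.1, 0.2])
        assert selection_statistic(curve) == pytest.approx(1.0)

    def test_arithmetic_mean_of_low_recall_points(self):
        from ppikernel.model import PRCurve, PRPoint

        curve = PRCurve(
            [PRPoint(0.1, 1.0, 0.0, 5), PRPoint(0.2, 0.6, 0.0, 10), PRPoint(0.5, 0.2, 0.0, 50)]
        )
        assert selection_statistic(curve, 0.2) == pytest.approx(0.8)

    def test_never_increases_as_the_recall_window_grows_on_decreasing_curve(self):
        from ppikernel.model import PRCurve, PRPoint

        curve = PRCurve(
            [PRPoint(r, 1.0 - r, 0.0, 10) for r in np.linspace(0.05, 1.0, 20)]
        )
        stats = [selection_statistic(curve, m) for m in (0.2, 0.4, 0.6, 1.0)]
        assert stats == sorted(stats, reverse=True)

    def test_empty_window_rejected(self):
        from ppikernel.model import PRCurve, PRPoint

        curve = PRCurve([PRPoint(0.5, 1.0, 0.0, 5)])
        with pytest.raises(ValueError, match="no PR points"):
            selection_statistic(curve, 0.2)


class TestCrossValidate:
    def test_trains_folds_times_repetitions_models(self, monkeypatch):
        import ppikernel.model as model_mod

        dataset = tiny_planted_dataset()
        calls = []
        original = model_mod.train

        def counting_train(*args, **kwargs):
            calls.append(1)
            return original(*args, **kwargs)

        monkeypatch.setattr(model_mod, "train", counting_train)
        cross_validate(dataset, HP, folds=5, repetitions=5, seed=1, negative_ratio=2)
        assert len(calls) == 25

    def test_same_seed_gives_identical_curve(self):
        dataset = tiny_planted_dataset()
        c1 = cross_validate(dataset, HP, folds=3, repetitions=1, seed=9, negative_ratio=2)
        c2 = cross_validate(dataset, HP, folds=3, repetitions=1, seed=9, negative_ratio=2)
        assert [(p.recall, p.precision, p.error) for p in c1.points] == [
            (p.recall, p.precision, p.error) for p in c2.points
        ]

    def test_planted_signal_beats_prevalence_baseline(self):
        dataset = tiny_planted_dataset()
        curve = cross_validate(dataset, HP, folds=3, repetitions=1, seed=2, negative_ratio=10)
        assert selection_statistic(curve) >= 3 * (1 / 11)

    def test_positive_sharing_a_protein_across_folds_is_rejected(self):
        dataset = tiny_planted_dataset()
        # corrupt the positive set: two interactions sharing one protein
        first = dataset.positives[0]
        shared = EvidencedInteraction(first.id_a, "sp00088", [("m", 10.0)])
        dataset.positives.append(shared)
        with pytest.raises(ValueError, match="not redundancy reduced"):
            cross_validate(dataset, HP, folds=5, repetitions=3, seed=1, negative_ratio=1)


class TestGridSearch:
    def test_recovers_planted_motif_length_and_reports_holdout(self):
        """With motifs of length 3 planted into delta profiles, a k matching
        the motif length must beat a k too long to ever see a shared k-mer."""
        dataset = tiny_planted_dataset(n_positives=24, n_proteins=100, seed=13)
        grid = [Hyperparams(3, 4.0), Hyperparams(6, 4.0)]
        report = grid_search(
            dataset, grid=grid, folds=3, repetitions=1, seed=4, negative_ratio=5
        )
        assert report.chosen.k == 3
        assert set(report.statistics) == set(grid)
        assert report.final_model is not None
        assert report.holdout_curve is not None
        assert report.statistics[report.chosen] == max(report.statistics.values())

    def test_fixed_hyperparameter_tier_is_redirected(self):
        dataset = tiny_planted_dataset()
        with pytest.raises(ValueError, match="cross_validate"):
            grid_search(dataset, tier=OrganismTier.FIXED_HYPERPARAMS)


def test_aggregate_curves_mean_and_sd():
    from ppikernel.model import PRCurve, PRPoint

    c1 = PRCurve([PRPoint(0.1, 1.0, 0.0, 10)])
    c2 = PRCurve([PRPoint(0.1, 0.5, 0.0, 10)])
    agg = aggregate_curves([c1, c2])
    assert agg.points[0].precision == pytest.approx(0.75)
    assert agg.points[0].error == pytest.approx(np.std([1.0, 0.5], ddof=1))
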