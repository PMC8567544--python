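import numpy as np
import pytest

from lmfda.evaluation import (
    UndefinedMetricError,
    auprc,
    auroc,
    best_f_threshold,
    confusion_metrics,
    cross_validate,
    make_folds,
    rank_drugs_for_disease,
    roc_curve_points,
)
from lmfda.completion import TrainConfig
from lmfda.io_datasets import LabeledMatrix


def _auroc_bruteforce(scores, labels):
    """O(n^2) pair counting, ties counted one half."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


FAST = dict(
    rank_disease=4,
    rank_drug=4,
    out_dim_disease=24,
    out_dim_drug=24,
    f_p=8,
    epochs=3,
    als_max_iter=10,
)


class TestMakeFolds:
    def _O(self, rng, n=8, m=10, npos=20):
        O = np.zeros((n, m))
        cells = rng.choice(n * m, npos, replace=False)
        O.flat[cells] = 1.0
        return LabeledMatrix(O, [f"d{i}" for i in range(n)], [f"g{j}" for j in range(m)])

    def test_equal_fold_sizes(self, rng):
        plan = make_folds(self._O(rng), k=10, seed=0)
        assert all(len(f) == 2 for f in plan.folds)

    def test_partition_of_positive_set(self, rng):
        O = self._O(rng)
        plan = make_folds(O, k=7, seed=1)
        cells = [c for f in plan.folds for c in f]
        assert len(cells) == len(set(cells)) == 20
        assert set(cells) == {tuple(c) for c in np.argwhere(O.values == 1)}

    def test_seed_determinism(self, rng):
        O = self._O(rng)
        assert make_folds(O, 5, 9).folds == make_folds(O, 5, 9).folds
        assert make_folds(O, 5, 9).folds != make_folds(O, 5, 10).folds

    def test_bad_k_rejected(self, rng):
        O = self._O(rng)
        with pytest.raises(ValueError):
            make_folds(O, 1, 0)
        with pytest.raises(ValueError):
            make_folds(O, 21, 0)


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([3, 2, 1, 0], [1, 1, 0, 0]) == 1.0

    def test_all_ties_half(self):
        assert auroc([1, 1, 1, 1], [1, 0, 1, 0]) == 0.5

    def test_hand_counted_example(self):
        # 3 of the 4 positive-negative pairs are concordant
        assert auroc([0.9, 0.8, 0.7, 0.1], [1, 0, 1, 0]) == pytest.approx(0.75)

    def test_single_class_undefined(self):
        with pytest.raises(UndefinedMetricError):
            auroc([1.0, 2.0], [1, 1])

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(5, 200))
            scores = np.round(rng.normal(size=n), 1)  # coarse grid forces ties
            labels = rng.random(n) < 0.4
            if labels.all() or not labels.any():
                continue
            assert auroc(scores, labels) == pytest.approx(
                _auroc_bruteforce(scores, labels), abs=1e-12
            )

    def test_monotone_transform_invariance(self, rng):
        scores = rng.normal(size=100)
        labels = rng.random(100) < 0.3
        labels[0], labels[1] = True, False
        assert auroc(np.exp(scores), labels) == pytest.approx(
            auroc(scores, labels), abs=1e-12
        )
        assert auprc(np.exp(scores), labels) == pytest.approx(
            auprc(scores, labels), abs=1e-12
        )


class TestConfusionMetrics:
    def test_hand_counted_fixture(self):
        # TP=3 FP=1 FN=1 TN=5 at threshold 0.5
        scores = [0.9, 0.8, 0.7, 0.2, 0.6, 0.1, 0.1, 0.1, 0.1, 0.1]
        labels = [1, 1, 1, 1, 0, 0, 0, 0, 0, 0]
        acc, prec, rec, f = confusion_metrics(scores, labels, 0.5)
        assert acc == pytest.approx(0.8)
        assert prec == pytest.approx(0.75)
        assert rec == pytest.approx(0.75)
        assert f == pytest.approx(0.75)

    def test_threshold_extremes(self, rng):
        scores = rng.normal(size=50)
        labels = rng.random(50) < 0.5
        labels[0], labels[1] = True, False
        _, _, rec, _ = confusion_metrics(scores, labels, scores.min() - 1)
        assert rec == 1.0
        _, _, _, f = confusion_metrics(scores, labels, scores.max() + 1)
        assert f == 0.0  # TP = FP = 0 convention

    def test_best_f_threshold_maximises(self, rng):
        scores = rng.normal(size=60)
        labels = rng.random(60) < 0.3
        labels[0], labels[1] = True, False
        t = best_f_threshold(scores, labels)
        f_best = confusion_metrics(scores, labels, t)[3]
        for cand in np.unique(scores):
            assert f_best >= confusion_metrics(scores, labels, cand)[3] - 1e-12


class TestRocCurve:
    def test_curve_endpoints_and_monotone(self, rng):
        scores = rng.normal(size=80)
        labels = rng.random(80) < 0.4
        labels[0], labels[1] = True, False
        pts = roc_curve_points(scores, labels)
        np.testing.assert_allclose(pts[0], [0, 0])
        np.testing.assert_allclose(pts[-1], [1, 1])
        assert (np.diff(pts[:, 0]) >= 0).all() and (np.diff(pts[:, 1]) >= 0).all()


class TestCrossValidate:
    def test_no_leakage_into_training_matrix(self, small_bundle):
        from lmfda.evaluation import _train_matrix

        bundle, _ = small_bundle
        plan = make_folds(bundle.associations, 5, seed=2)
        for fold in plan.folds:
            Ot = _train_matrix(bundle.associations, fold)
            for i, j in fold:
                assert Ot.values[i, j] == 0.0
            # everything not held out is untouched
            diff = bundle.associations.values - Ot.values
            assert diff.sum() == len(fold)

    def test_report_structure_and_ranges(self, small_bundle):
        bundle, _ = small_bundle
        plan = make_folds(bundle.associations, 3, seed=0)
        rep = cross_validate(bundle, plan, TrainConfig(**FAST, seed=0))
        assert len(rep.per_fold) == 3
        for f in rep.per_fold:
            assert 0.0 <= f["auroc"] <= 1.0 and 0.0 <= f["auprc"] <= 1.0
        assert rep.pooled is not None and 0.0 <= rep.pooled["auroc"] <= 1.0

    def test_neg_sampling_reduces_test_set(self, small_bundle):
        bundle, _ = small_bundle
        plan = make_folds(bundle.associations, 3, seed=0)
        rep = cross_validate(bundle, plan, TrainConfig(**FAST, seed=0), neg_sample=50)
        assert all(f["n_test_neg"] == 50 for f in rep.per_fold)


class TestRankDrugs:
    def test_full_ranking_sorted(self, small_bundle):
        bundle, _ = small_bundle
        did = bundle.associations.row_ids[0]
        rl = rank_drugs_for_disease(
            bundle, did, top_k=10_000, config=TrainConfig(**FAST, seed=0)
        )
        assert len(rl.drug_ids) == bundle.n_drugs
        assert all(a >= b for a, b in zip(rl.scores, rl.scores[1:]))

    def test_unknown_disease_raises(self, small_bundle):
        bundle, _ = small_bundle
        with pytest.raises(KeyError):
            rank_drugs_for_disease(bundle, "NOT_A_DISEASE", 10)

    def test_planted_drug_recovered_in_top10(self, small_bundle):
        """Plant one strongly-associated drug per disease (shared with that
        disease's semantic neighbours); after deleting the disease's whole
        row the planted drug must resurface via the similarity networks."""
        from lmfda.io_datasets import DatasetBundle

        bundle, truth = small_bundle
        O = bundle.associations.values.copy()
        S = bundle.disease_semantic_sim.values
        planted = {}
        for i in range(bundle.n_diseases):
            j = int(np.argmax(truth.signal[i]))
            planted[i] = j
            O[i, j] = 1.0
            neighbours = np.argsort(-S[i])[1:5]
            O[neighbours, j] = 1.0
        pb = DatasetBundle(
            LabeledMatrix(
                O, bundle.associations.row_ids, bundle.associations.col_ids
            ),
            bundle.fingerprints,
            bundle.disease_semantic_sim,
        )
        cfg = TrainConfig(**{**FAST, "epochs": 0}, seed=0)
        hits = 0
        for i in range(10):
            did = pb.associations.row_ids[i]
            rl = rank_drugs_for_disease(pb, did, top_k=10, config=cfg)
            hits += pb.associations.col_ids[planted[i]] in rl.drug_ids
        assert hits >= 8
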