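import logging

import numpy as np
import pandas as pd
import pytest

from adrgraph.evaluation import (auc_aupr, evaluate_scores, make_folds,
                                 mask_test_positives, per_drug_metrics,
                                 recall_at_k)

from ._oracles import auc_loop, aupr_step_loop


class TestMakeFolds:
    @pytest.fixture
    def small_o(self, rng):
        o = np.zeros((5, 6))
        idx = rng.choice(30, size=10, replace=False)
        o.ravel()[idx] = 1.0
        return o

    def test_equal_partition_of_ten_positives(self, small_o):
        split = make_folds(small_o, seed=0)
        sizes = sorted(len(f.test_pos) for f in split.folds)
        assert sizes == [2, 2, 2, 2, 2]

    def test_subsets_cover_all_positives(self, small_o):
        split = make_folds(small_o, seed=0)
        got = np.concatenate([f.test_pos for f in split.folds])
        expect = np.argwhere(small_o == 1)
        assert {tuple(p) for p in got} == {tuple(p) for p in expect}

    def test_balanced_training_negatives(self, small_o):
        for fold in make_folds(small_o, seed=0).folds:
            assert len(fold.train_neg) == len(fold.train_pos)

    def test_train_and_test_negatives_disjoint(self, small_o):
        for fold in make_folds(small_o, seed=0).folds:
            train = {tuple(p) for p in fold.train_neg}
            test = {tuple(p) for p in fold.test_neg}
            assert not train & test
            assert len(train) + len(test) == (small_o == 0).sum()

    def test_reproducible(self, small_o):
        a, b = make_folds(small_o, seed=5), make_folds(small_o, seed=5)
        for fa, fb in zip(a.folds, b.folds):
            np.testing.assert_array_equal(fa.test_pos, fb.test_pos)
            np.testing.assert_array_equal(fa.train_neg, fb.train_neg)

    def test_too_few_positives_rejected(self):
        with pytest.raises(ValueError):
            make_folds(np.eye(2), seed=0)

    def test_near_equal_subsets_uneven_count(self, rng):
        o = np.zeros((4, 6))
        o.ravel()[rng.choice(24, size=13, replace=False)] = 1.0
        sizes = [len(f.test_pos) for f in make_folds(o, seed=1).folds]
        assert sum(sizes) == 13
        assert max(sizes) - min(sizes) <= 1

    def test_negative_pool_accounting(self, small_o):
        split = make_folds(small_o, seed=0)
        assert split.n_negative_pool == 20
        assert split.negative_positive_ratio == pytest.approx(2.0)


def test_mask_test_positives(rng):
    o = (rng.random((6, 8)) < 0.4).astype(float)
    fold = make_folds(o, seed=2).folds[1]
    o_train = mask_test_positives(o, fold)
    assert o_train[fold.test_pos[:, 0], fold.test_pos[:, 1]].sum() == 0
    assert o_train.sum() == o.sum() - len(fold.test_pos)
    # original untouched
    assert o.sum() > o_train.sum()


class TestAucAupr:
    def test_perfect_separation(self):
        auc, aupr = auc_aupr([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == pytest.approx(1.0)
        assert aupr == pytest.approx(1.0)

    def test_perfectly_wrong(self):
        auc, _ = auc_aupr([0.1, 0.2, 0.8, 0.9], [1, 1, 0, 0])
        assert auc == pytest.approx(0.0)

    def test_three_of_four_concordant(self):
        auc, _ = auc_aupr([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0])
        assert auc == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_aupr([0.5, 0.6], [1, 1])

    def test_auc_matches_pairwise_loop_oracle(self, rng):
        for _ in range(5):
            n = int(rng.integers(10, 50))
            scores = rng.random(n).round(1)    # force some ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            auc, _ = auc_aupr(scores, labels)
            assert auc == pytest.approx(auc_loop(scores, labels), abs=1e-10)

    def test_aupr_matches_step_integration_oracle(self, rng):
        for _ in range(5):
            scores = rng.random(30)
            labels = rng.integers(0, 2, 30)
            if labels.min() == labels.max():
                continue
            _, aupr = auc_aupr(scores, labels)
            assert aupr == pytest.approx(aupr_step_loop(scores, labels),
                                         abs=1e-10)


def scores_frame(rows):
    return pd.DataFrame(rows, columns=["drug", "side_effect", "score",
                                       "label", "fold"])


class TestRecallAtK:
    def test_all_positives_ranked_first(self):
        df = scores_frame([(0, j, 1.0 - 0.01 * j, 1 if j < 3 else 0, 0)
                           for j in range(50)])
        rec = recall_at_k(df, ks=[3, 30])
        assert rec[3] == pytest.approx(1.0)
        assert rec[30] == pytest.approx(1.0)

    def test_monotone_in_k(self, rng):
        df = scores_frame([(d, j, rng.random(), int(rng.random() < 0.2), 0)
                           for d in range(3) for j in range(80)])
        rec = recall_at_k(df, ks=[30, 60])
        assert rec[30] <= rec[60] + 1e-12

    def test_positives_at_known_ranks(self):
        # positives at ranks 1, 40, 100 -> recall@30 = 1/3
        rows = []
        for j in range(120):
            rank = j + 1
            label = 1 if rank in (1, 40, 100) else 0
            rows.append((0, j, 1.0 - rank / 1000, label, 0))
        assert recall_at_k(scores_frame(rows), ks=[30])[30] == pytest.approx(1 / 3)

    def test_pooled_mode(self):
        rows = [(d, j, (d * 37 + j) % 11 / 11, int(j % 7 == 0), 0)
                for d in range(2) for j in range(40)]
        df = scores_frame(rows)
        ranked = df.sort_values(["score", "side_effect"],
                                ascending=[False, True], kind="stable")
        expect = ranked["label"].to_numpy()[:10].sum() / df["label"].sum()
        assert recall_at_k(df, ks=[10], mode="pooled")[10] == pytest.approx(expect)

    def test_k_must_be_positive(self):
        with pytest.raises(ValueError):
            recall_at_k(scores_frame([(0, 0, 0.5, 1, 0)]), ks=[0])


class TestPerDrugMetrics:
    def test_single_drug_reduces_to_auc_aupr(self, rng):
        scores = rng.random(20)
        labels = np.array([1] * 5 + [0] * 15)
        df = scores_frame([(7, j, scores[j], labels[j], 0) for j in range(20)])
        table = per_drug_metrics(df)
        auc, aupr = auc_aupr(scores, labels)
        assert table.loc[0, "auc"] == pytest.approx(auc)
        assert table.loc[0, "aupr"] == pytest.approx(aupr)

    def test_single_class_drugs_skipped_and_logged(self, caplog):
        rows = ([(0, j, 0.5, 1, 0) for j in range(3)]        # all positive
                + [(1, j, float(j) / 4, j % 2, 0) for j in range(4)])
        with caplog.at_level(logging.WARNING):
            table = per_drug_metrics(scores_frame(rows))
        assert list(table["drug"]) == [1]
        assert any("skipped" in r.message for r in caplog.records)

    def test_three_drug_hand_average(self, rng):
        frames = []
        per_drug = []
        for d in range(3):
            scores = rng.random(12)
            labels = rng.integers(0, 2, 12)
            labels[0], labels[1] = 1, 0   # both classes present
            frames.extend((d, j, scores[j], labels[j], 0) for j in range(12))
            per_drug.append(auc_aupr(scores, labels))
        table = per_drug_metrics(scores_frame(frames))
        assert table["auc"].mean() == pytest.approx(
            np.mean([m[0] for m in per_drug]))


def test_evaluate_scores_report_structure(rng):
    rows = [(d, j, rng.random(), int(rng.random() < 0.3), f)
            for f in range(2) for d in range(4) for j in range(25)]
    report = evaluate_scores(scores_frame(rows), ks=[5, 10])
    assert set(report) == {"per_fold", "average_auc", "average_aupr",
                           "recall_at_k"}
    assert set(report["per_fold"]) == {0, 1}
    assert 0.0 <= report["average_auc"] <= 1.0
    assert report["recall_at_k"]["5"] <= report["recall_at_k"]["10"] + 1e-12


def test_cross_validate_subset_of_folds(tiny_dataset):
    from adrgraph.evaluation import cross_validate
    from adrgraph.gan import GanConfig
    from adrgraph.model import TrainConfig

    cfg = TrainConfig(seed=0, head_epochs=2, batch_size=32,
                      gan=GanConfig(encoder_dims=(12, 8),
                                    decoder_dims=(12, None),
                                    disc_dims=(12, 6), epochs=10))
    scores, report = cross_validate(tiny_dataset.matrices, cfg, seed=3,
                                    folds=[0, 1])
    assert sorted(scores["fold"].unique()) == [0, 1]
    assert set(report["per_fold"]) == {0, 1}
    assert 0.0 <= report["average_auc"] <= 1.0
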