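import numpy as np
import pytest

from msiclf import (ConvNetSpec, MLPSpec, RawSpectrum, TissueGroup,
                    compute_metrics, fuse_group, make_balanced_folds,
                    make_leave_one_tma_out_splits, run_cross_validation)
from msiclf.crossval import CVSplit, LeakageError, assert_patient_disjoint


def brute_force_auc(y, conf):
    """All-pairs probability that a positive outranks a negative; ties count 1/2."""
    pos = conf[np.asarray(y) == 1]
    neg = conf[np.asarray(y) == 0]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def _group(gid, pid, label, tma, n_spectra=1):
    mz = np.linspace(800.0, 810.0, 5)
    spectra = [RawSpectrum(coords=(i + 1, 1), mz=mz, intensity=np.ones(5),
                           tma_id=tma) for i in range(n_spectra)]
    return TissueGroup(group_id=gid, patient_id=pid, label=label, spectra=spectra)


class TestComputeMetrics:
    def test_hand_checked_mixed_fold(self):
        m = compute_metrics(np.array([1, 1, 0, 0]),
                            np.array([0.9, 0.4, 0.2, 0.6]), threshold=0.5)
        assert m.accuracy == 0.5
        assert m.sensitivity == 0.5
        assert m.specificity == 0.5
        assert m.balanced_accuracy == 0.5
        assert m.auc == 0.75
        assert (m.tp, m.fp, m.tn, m.fn) == (1, 1, 1, 1)

    def test_perfect_classifier(self):
        y = np.array([0, 1, 1, 0])
        m = compute_metrics(y, y.astype(float))
        assert (m.accuracy, m.balanced_accuracy, m.sensitivity,
                m.specificity, m.auc) == (1.0, 1.0, 1.0, 1.0, 1.0)

    def test_constant_confidence_gives_chance_auc(self):
        m = compute_metrics(np.array([1, 0, 1, 0]), np.full(4, 0.7))
        assert m.auc == 0.5

    def test_single_class_fold_has_undefined_auc(self):
        m = compute_metrics(np.ones(4, dtype=int), np.array([0.9, 0.8, 0.2, 0.6]))
        assert np.isnan(m.auc)
        assert m.accuracy == 0.75          # other metrics still reported
        assert np.isnan(m.specificity)

    def test_auc_equals_all_pairs_oracle(self):
        r = np.random.default_rng(99)
        for _ in range(100):
            n = int(r.integers(4, 201))
            y = r.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                continue
            conf = np.round(r.uniform(0, 1, n), 2)   # coarse grid forces ties
            m = compute_metrics(y, conf)
            assert m.auc == pytest.approx(brute_force_auc(y, conf), abs=1e-12)

    def test_balanced_accuracy_identity(self):
        r = np.random.default_rng(3)
        y = r.integers(0, 2, 50)
        conf = r.uniform(0, 1, 50)
        m = compute_metrics(y, conf)
        assert m.balanced_accuracy == pytest.approx((m.sensitivity + m.specificity) / 2)
        assert m.accuracy == pytest.approx((m.tp + m.tn) / 50)


class TestFuseGroup:
    @pytest.mark.parametrize("conf,median,label", [
        ((0.2, 0.6, 0.9), 0.6, 1),
        ((0.0, 0.0, 0.0), 0.0, 0),
        ((0.2, 0.8), 0.5, 1),        # even count: mean of middles; >= is positive
    ])
    def test_median_and_boundary_rule(self, conf, median, label):
        p = fuse_group(np.array(conf))
        assert p.median_confidence == pytest.approx(median)
        assert p.predicted_label == label

    def test_unanimous_confidence_is_returned_unchanged(self, rng):
        c = float(rng.uniform(0, 1))
        assert fuse_group(np.full(7, c)).median_confidence == pytest.approx(c)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            fuse_group(np.array([]))


class TestLeaveOneTmaOut:
    def test_each_tma_validated_exactly_once(self):
        groups = [_group(f"g{t}_{i}", f"p{t}_{i}", i % 2, f"tma{t:02d}")
                  for t in range(15) for i in range(4)]
        splits = make_leave_one_tma_out_splits(groups)
        assert len(splits) == 15
        validated = [g for s in splits for g in s.val_group_ids]
        assert sorted(validated) == sorted(g.group_id for g in groups)

    def test_two_tmas_give_complementary_splits(self):
        groups = [_group("a", "p1", 0, "t0"), _group("b", "p2", 1, "t1")]
        splits = make_leave_one_tma_out_splits(groups)
        assert len(splits) == 2
        assert set(splits[0].val_group_ids) == set(splits[1].train_group_ids)

    def test_patient_sides_are_disjoint(self):
        groups = [_group(f"g{t}_{i}", f"p{t}_{i}", i % 2, f"t{t}")
                  for t in range(4) for i in range(6)]
        patient_of = {g.group_id: g.patient_id for g in groups}
        for s in make_leave_one_tma_out_splits(groups):
            assert_patient_disjoint(s, patient_of)   # must not raise

    def test_patient_spanning_tmas_is_fatal(self):
        groups = [_group("a", "p1", 0, "t0"), _group("b", "p1", 1, "t1")]
        with pytest.raises(LeakageError):
            make_leave_one_tma_out_splits(groups)

    def test_single_tma_rejected(self):
        with pytest.raises(ValueError):
            make_leave_one_tma_out_splits([_group("a", "p1", 0, "t0")])


@pytest.fixture(scope="module")
def imbalanced_groups():
    # mirrors a nodal-metastasis cohort: 42 positive vs 209 negative patients
    groups = [_group(f"pos{i}", f"pp{i}", 1, f"t{i % 3}") for i in range(42)]
    groups += [_group(f"neg{i}", f"pn{i}", 0, f"t{i % 3}") for i in range(209)]
    return groups


class TestBalancedFolds:
    def test_ten_folds_of_twenty_validation_groups(self, imbalanced_groups):
        splits = make_balanced_folds(imbalanced_groups, k=10, n_per_class=10, seed=1)
        assert len(splits) == 10
        assert all(len(s.val_group_ids) == 20 for s in splits)
        assert sum(len(s.val_group_ids) for s in splits) == 200

    def test_each_fold_balanced_and_leak_free(self, imbalanced_groups):
        labels = {g.group_id: g.label for g in imbalanced_groups}
        splits = make_balanced_folds(imbalanced_groups, k=10, n_per_class=10, seed=1)
        for s in splits:
            val_labels = [labels[g] for g in s.val_group_ids]
            assert val_labels.count(1) == 10 and val_labels.count(0) == 10
            assert len(set(s.val_group_ids)) == 20          # no replacement within fold
            assert not set(s.val_group_ids) & set(s.train_group_ids)

    def test_same_seed_same_folds(self, imbalanced_groups):
        a = make_balanced_folds(imbalanced_groups, seed=4)
        b = make_balanced_folds(imbalanced_groups, seed=4)
        assert a == b

    def test_class_smaller_than_quota_rejected(self):
        groups = [_group(f"pos{i}", f"p{i}", 1, "t0") for i in range(5)]
        groups += [_group(f"neg{i}", f"q{i}", 0, "t0") for i in range(30)]
        with pytest.raises(ValueError):
            make_balanced_folds(groups, k=10, n_per_class=10, seed=0)


class TestSplitIntegrity:
    def test_group_on_both_sides_rejected(self):
        with pytest.raises(ValueError):
            CVSplit(split_id="s", train_group_ids=("a", "b"), val_group_ids=("b",))

    def test_leaky_split_detected(self):
        split = CVSplit(split_id="s", train_group_ids=("a",), val_group_ids=("b",))
        with pytest.raises(LeakageError):
            assert_patient_disjoint(split, {"a": "p1", "b": "p1"})


FAST_SPECS = [
    MLPSpec(input_dim=20, hidden=(16,), schedule=((40, 0.05), (10, 0.005)),
            batch_size=64),
    ConvNetSpec(filters=(8, 1), strides=(2, 1), n_batchnorm=1,
                schedule=((30, 0.05), (10, 0.005)), batch_size=64),
]


class TestRunCrossValidation:
    def test_end_to_end_bookkeeping_and_aggregation(self, tiny_groups, tiny_bin_spec):
        res = run_cross_validation(tiny_groups, tiny_bin_spec,
                                   design="leave_one_tma_out", seed=3,
                                   specs=FAST_SPECS)
        assert len(res.fold_metrics) == len(res.splits) == 2
        accs = [m.accuracy for m in res.fold_metrics]
        # aggregate is the unweighted mean over folds, not pooled accuracy
        assert res.mean_spectrum_metrics["accuracy"] == pytest.approx(np.mean(accs))
        assert set(res.fold_group_accuracy.columns) >= {
            "split_id", "accuracy_all", "accuracy_negative", "accuracy_positive"}
        table = res.group_table()
        assert len(table) == sum(len(p) for p in res.group_predictions)
        assert ((table.median_confidence >= 0) & (table.median_confidence <= 1)).all()

    def test_strong_effect_is_recovered(self, tiny_groups, tiny_bin_spec):
        res = run_cross_validation(tiny_groups, tiny_bin_spec, seed=3,
                                   specs=FAST_SPECS)
        assert res.mean_spectrum_metrics["auc"] > 0.9
        assert res.mean_group_accuracy > 0.9

    def test_unknown_design_rejected(self, tiny_groups, tiny_bin_spec):
        with pytest.raises(ValueError):
            run_cross_validation(tiny_groups, tiny_bin_spec, design="holdout")
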