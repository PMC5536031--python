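"""Ensemble training protocol, voting rule and cross-validation."""

import numpy as np
import pytest

from hotspot_rp import (
    EnsembleConfig,
    KnnModel,
    assign_folds,
    cross_validate,
    encode_dataset,
    predict_ensemble,
    train_ensemble,
)
from hotspot_rp.ensemble import EnsembleModel, RankedMember
from hotspot_rp.errors import ConfigError, DegenerateInputError
from hotspot_rp.projection import ProjectionMatrix, project


@pytest.fixture(scope="module")
def separable_instances():
    """Linearly separable 2-class cloud, 40 positives / 160 negatives."""
    rng = np.random.default_rng(42)
    n_pos, n_neg = 40, 160
    X_pos = rng.standard_normal((n_pos, 8)) + 4.0
    X_neg = rng.standard_normal((n_neg, 8))
    X = np.vstack([X_pos, X_neg])
    y = np.concatenate([np.ones(n_pos, dtype=int), np.zeros(n_neg, dtype=int)])
    perm = rng.permutation(len(y))
    return X[perm], y[perm]


def make_voting_ensemble(member_labels):
    """Ensemble of 1-D members engineered to cast the given votes."""
    members = []
    for rank, vote in enumerate(member_labels, start=1):
        proj = ProjectionMatrix(entries=np.array([[1.0]]), seed=rank, l1=1, l2=1)
        model = KnnModel(k=1).fit(np.array([[0.0], [100.0]]), np.array([vote, 1 - vote]))
        members.append(
            RankedMember(projection=proj, model=model, train_f1=1.0, rank=rank)
        )
    config = EnsembleConfig(n_projections=len(members), top_n=len(members))
    return EnsembleModel(members=tuple(members), config=config)


class TestTrainEnsemble:
    def test_k1_n1_is_a_single_classifier(self, separable_instances):
        X, y = separable_instances
        config = EnsembleConfig(n_projections=1, top_n=1, target_dim=3, master_seed=5)
        model = train_ensemble(X, y, config)
        assert model.n_members == 1
        member = model.members[0]
        labels, fractions = predict_ensemble(model, X)
        single_labels, _ = member.model.predict(project(X, member.projection))
        np.testing.assert_array_equal(labels, single_labels)

    def test_members_sorted_by_train_f1_desc(self, separable_instances):
        X, y = separable_instances
        config = EnsembleConfig(n_projections=5, top_n=5, target_dim=3, master_seed=1)
        model = train_ensemble(X, y, config)
        f1s = [m.train_f1 for m in model.members]
        assert f1s == sorted(f1s, reverse=True)
        assert [m.rank for m in model.members] == [1, 2, 3, 4, 5]

    def test_same_master_seed_reproduces_member_list(self, separable_instances):
        X, y = separable_instances
        config = EnsembleConfig(n_projections=6, top_n=3, target_dim=2, master_seed=9)
        a = train_ensemble(X, y, config)
        b = train_ensemble(X, y, config)
        assert [m.projection.seed for m in a.members] == [
            m.projection.seed for m in b.members
        ]
        assert [m.train_f1 for m in a.members] == [m.train_f1 for m in b.members]

    def test_single_class_data_rejected(self, rng):
        X = rng.standard_normal((30, 4))
        config = EnsembleConfig(n_projections=2, top_n=1)
        with pytest.raises(DegenerateInputError):
            train_ensemble(X, np.zeros(30, dtype=int), config)

    def test_top_n_cannot_exceed_k(self):
        with pytest.raises(ConfigError):
            EnsembleConfig(n_projections=3, top_n=4)


class TestVoting:
    @pytest.mark.parametrize(
        "votes, expected_label, expected_fraction",
        [
            ((1, 1, 0), 1, 2 / 3),
            ((1, 0, 0), 0, 1 / 3),
            ((1, 0), 1, 1 / 2),  # even N: exactly half of the members suffices
            ((0, 0), 0, 0.0),
            ((1, 1, 1, 1, 1), 1, 1.0),
        ],
    )
    def test_majority_rule(self, votes, expected_label, expected_fraction):
        model = make_voting_ensemble(votes)
        labels, fractions = predict_ensemble(model, np.array([[0.0]]))
        assert labels[0] == expected_label
        assert fractions[0] == pytest.approx(expected_fraction)

    def test_unanimous_positive_wins_for_any_n(self):
        for n in (1, 2, 3, 4, 7):
            model = make_voting_ensemble((1,) * n)
            labels, _ = predict_ensemble(model, np.array([[0.0]]))
            assert labels[0] == 1


class TestFoldsAndCV:
    def test_folds_partition_with_balanced_sizes(self):
        y = np.zeros(23, dtype=int)
        y[:4] = 1
        folds = assign_folds(y, n_folds=5, seed=0, stratify=True)
        sizes = np.bincount(folds, minlength=5)
        assert sizes.sum() == 23
        assert sizes.max() - sizes.min() <= 1

    def test_stratified_positive_counts_differ_by_at_most_one(self):
        y = np.zeros(2949, dtype=int)
        y[:54] = 1
        folds = assign_folds(y, n_folds=10, seed=3, stratify=True)
        per_fold_pos = [int(y[folds == f].sum()) for f in range(10)]
        assert set(per_fold_pos) <= {5, 6}
        assert sum(per_fold_pos) == 54

    def test_every_instance_predicted_exactly_once(self, separable_instances):
        X, y = separable_instances
        config = EnsembleConfig(
            n_projections=3, top_n=1, target_dim=2, n_folds=10, master_seed=2
        )
        result = cross_validate(X, y, config)
        assert len(result.labels) == len(y)
        assert np.bincount(result.folds, minlength=10).sum() == len(y)
        assert result.confusion.total == len(y)

    def test_cv_deterministic_in_seed(self, separable_instances):
        X, y = separable_instances
        config = EnsembleConfig(
            n_projections=3, top_n=3, target_dim=2, n_folds=5, master_seed=7
        )
        a = cross_validate(X, y, config)
        b = cross_validate(X, y, config)
        np.testing.assert_array_equal(a.folds, b.folds)
        np.testing.assert_array_equal(a.labels, b.labels)
        np.testing.assert_allclose(a.fractions, b.fractions)

    def test_separable_data_recovered_well(self, separable_instances):
        X, y = separable_instances
        config = EnsembleConfig(
            n_projections=5, top_n=3, target_dim=3, n_folds=5, master_seed=0
        )
        result = cross_validate(X, y, config)
        assert result.metrics.f1 > 0.9
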