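"""Cohort split, vote-fraction scoring, OOB discipline, permutation test."""

import math
from datetime import date

import numpy as np
import pandas as pd
import pytest

import metabrisk as mb
from metabrisk.rf_risk_model import (
    CohortSplit,
    PerformanceMetrics,
    RiskScore,
    oob_metric,
)
from metabrisk.spectral_processing import FeatureMatrix, bin_label

from conftest import auc_allpairs_oracle


def _gaussian_matrix(n_per_class=20, p=30, informative=5, shift=3.0, seed=0):
    """Two-class toy: `informative` shifted features, the rest noise."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(2 * n_per_class, p))
    X[n_per_class:, :informative] += shift
    ids = [f"N{i}" for i in range(n_per_class)] + [
        f"P{i}" for i in range(n_per_class)
    ]
    edges = [(9.98 - 0.02 * k, 10.0 - 0.02 * k) for k in range(p)]
    df = pd.DataFrame(X, index=ids, columns=[bin_label(*e) for e in edges])
    fm = FeatureMatrix(df, edges, pd.Series([date(2010, 1, 1)] * len(ids), index=ids))
    labels = {i: ("eBC" if i.startswith("N") else "aBC") for i in ids}
    split = CohortSplit(tuple(ids), (), labels)
    return fm, split


def _score(sid, score, thr=0.5):
    return RiskScore(sid, score, 100, False, mb.classify_risk(score, thr))


class TestSplit:
    def test_study_sized_partition(self):
        patients, _ = mb.generate_cohort(mb.CohortConfig(seed=1, pulse_sequences=()))
        split = mb.build_split(patients)
        assert len(split.training_ids) == 111 + 27
        assert len(split.validation_ids) == 29
        assert sum(split.label_map[i] == "aBC" for i in split.training_ids) == 27

    def test_no_advanced_patients_is_an_error(self):
        patients, _ = mb.generate_cohort(
            mb.CohortConfig(n_ebc=10, n_ebc_relapsed=2, n_abc=0, seed=1,
                            pulse_sequences=())
        )
        with pytest.raises(mb.InputError, match="advanced"):
            mb.build_split(patients)

    def test_no_relapsed_warns_with_empty_validation(self):
        patients, _ = mb.generate_cohort(
            mb.CohortConfig(n_ebc=10, n_ebc_relapsed=0, n_abc=4, seed=1,
                            pulse_sequences=())
        )
        with pytest.warns(UserWarning, match="validation"):
            split = mb.build_split(patients)
        assert split.validation_ids == ()

    def test_overlapping_partitions_rejected(self):
        with pytest.raises(mb.InputError, match="both partitions"):
            CohortSplit(("A", "B"), ("B",), {"A": "eBC", "B": "aBC"})


class TestEnsemble:
    def test_candidate_features_sqrt_p(self):
        fm, split = _gaussian_matrix(n_per_class=10, p=456, seed=1)
        ens = mb.fit_rf(fm, split, n_trees=5, seed=1)
        assert ens.max_features_per_split == math.floor(math.sqrt(456)) == 21

    def test_separated_classes_high_oob_accuracy(self):
        fm, split = _gaussian_matrix(seed=2)
        acc = oob_metric(fm, split, n_trees=200, seed=3)
        assert acc > 0.9

    def test_same_seed_identical_vote_tallies(self):
        fm, split = _gaussian_matrix(seed=4)
        X = fm.values.to_numpy()
        e1 = mb.fit_rf(fm, split, n_trees=50, seed=9)
        e2 = mb.fit_rf(fm, split, n_trees=50, seed=9)
        assert np.array_equal(e1.votes(X), e2.votes(X))
        assert np.array_equal(e1.inbag, e2.inbag)

    def test_tiny_class_rejected(self):
        fm, split = _gaussian_matrix(n_per_class=5, seed=5)
        labels = dict(split.label_map)
        for i in list(labels)[:9]:  # leave a single positive
            labels[i] = "eBC"
        bad = CohortSplit(split.training_ids, (), labels)
        with pytest.raises(mb.InputError, match="2 training samples"):
            mb.fit_rf(fm, bad, n_trees=5, seed=0)


class TestRiskScore:
    def test_training_scores_use_oob_votes_only(self):
        fm, split = _gaussian_matrix(seed=6)
        ens = mb.fit_rf(fm, split, n_trees=60, seed=7)
        X = fm.values.to_numpy()
        votes = ens.votes(X)
        for k, sid in enumerate(split.training_ids):
            rs = mb.rf_risk_score(ens, sid, fm)
            mask = ens.oob_mask(sid)
            assert rs.oob_only and rs.n_trees_used == mask.sum() < ens.n_trees
            assert rs.score == pytest.approx(votes[k, mask].mean())

    def test_external_sample_uses_full_forest(self):
        fm, split = _gaussian_matrix(seed=8)
        train_ids = list(split.training_ids)[:-1]
        labels = {i: split.label_map[i] for i in train_ids}
        sub = CohortSplit(tuple(train_ids), (split.training_ids[-1],), labels | {split.training_ids[-1]: "eBC"})
        ens = mb.fit_rf(fm, sub, n_trees=40, seed=9)
        rs = mb.rf_risk_score(ens, split.training_ids[-1], fm)
        assert not rs.oob_only and rs.n_trees_used == 40

    def test_zero_oob_trees_raises(self):
        fm, split = _gaussian_matrix(n_per_class=3, seed=10)
        # with very few trees some training sample is in every bootstrap
        for seed in range(50):
            ens = mb.fit_rf(fm, split, n_trees=2, seed=seed)
            fully_inbag = [
                sid for k, sid in enumerate(split.training_ids)
                if ens.inbag[:, k].all()
            ]
            if fully_inbag:
                with pytest.raises(mb.InputError, match="zero OOB"):
                    mb.rf_risk_score(ens, fully_inbag[0], fm)
                return
        pytest.fail("no fully in-bag sample found across seeds")

    @pytest.mark.parametrize(
        "score,expected", [(0.6, "high"), (0.4, "low"), (0.5, "high")]
    )
    def test_threshold_rule(self, score, expected):
        assert mb.classify_risk(score) == expected

    def test_score_out_of_range_rejected(self):
        with pytest.raises(mb.InputError):
            mb.classify_risk(1.2)


class TestPerformance:
    def test_toy_auc_three_quarters(self):
        scores = [_score("P1", 0.9), _score("P2", 0.8),
                  _score("N1", 0.7), _score("N2", 0.85)]
        truth = {"P1": "aBC", "P2": "aBC", "N1": "eBC", "N2": "eBC"}
        pm = mb.performance_metrics(scores, truth)
        assert pm.auc == pytest.approx(0.75)

    def test_perfect_separation(self):
        scores = [_score(f"P{i}", 0.9) for i in range(3)] + [
            _score(f"N{i}", 0.1) for i in range(4)
        ]
        truth = {s.sample_id: ("aBC" if s.sample_id[0] == "P" else "eBC")
                 for s in scores}
        pm = mb.performance_metrics(scores, truth)
        assert (pm.sensitivity, pm.specificity, pm.accuracy, pm.auc) == (1, 1, 1, 1)

    def test_study_confusion_rounds_to_reported_percentages(self):
        """22/27 detected metastatic and 74/111 correct early gives the
        81/67/70 percent triple."""
        scores, truth = [], {}
        for i in range(27):
            s = 0.9 if i < 22 else 0.1
            scores.append(_score(f"P{i}", s)); truth[f"P{i}"] = "aBC"
        for i in range(111):
            s = 0.1 if i < 74 else 0.9
            scores.append(_score(f"N{i}", s)); truth[f"N{i}"] = "eBC"
        pm = mb.performance_metrics(scores, truth)
        assert round(100 * pm.sensitivity) == 81
        assert round(100 * pm.specificity) == 67
        assert round(100 * pm.accuracy) == 70

    def test_single_class_truth_rejected(self):
        scores = [_score("A", 0.2), _score("B", 0.7)]
        with pytest.raises(mb.InputError, match="AUC undefined"):
            mb.performance_metrics(scores, {"A": "eBC", "B": "eBC"})

    @pytest.mark.parametrize("seed", range(5))
    def test_auc_matches_allpairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 50))
        vals = np.round(rng.uniform(0, 1, n), 2)  # rounding forces ties
        y = rng.integers(0, 2, n)
        if len(np.unique(y)) < 2:
            y[0], y[1] = 0, 1
        scores = [_score(f"S{i}", v) for i, v in enumerate(vals)]
        truth = {f"S{i}": ("aBC" if c else "eBC") for i, c in enumerate(y)}
        pm = mb.performance_metrics(scores, truth)
        assert pm.auc == pytest.approx(
            auc_allpairs_oracle(vals[y == 1], vals[y == 0])
        )


class TestPermutation:
    def test_observed_beats_all_permutations_gives_min_p(self):
        fm, split = _gaussian_matrix(n_per_class=15, p=20, shift=4.0, seed=11)
        p, obs, perm = mb.permutation_test(
            fm, split, n_trees=60, n_perm=99, seed=12
        )
        assert obs > perm.max()
        assert p == pytest.approx(0.01)

    def test_p_value_bounds(self):
        fm, split = _gaussian_matrix(n_per_class=8, p=10, shift=0.0, seed=13)
        for n_perm in (1, 4, 9):
            p, _, _ = mb.permutation_test(fm, split, n_trees=20, n_perm=n_perm, seed=14)
            assert 1.0 / (n_perm + 1) <= p <= 1.0

    def test_zero_permutations_rejected(self):
        fm, split = _gaussian_matrix(n_per_class=5, p=5, seed=15)
        with pytest.raises(mb.InputError):
            mb.permutation_test(fm, split, n_trees=5, n_perm=0, seed=0)
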