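"""Random-forest vote-fraction risk model.

An ensemble of unpruned decision trees is trained to separate relapse-free
early-stage (eBC) sera from metastatic (aBC) sera.  The training set holds
all relapse-free early patients plus all advanced patients; the validation
set holds every early patient who later relapsed.  The fraction of eligible
trees voting a sample into the metastatic class is the "RF risk score";
samples at or above the threshold (default 0.5) are called high risk.

Out-of-bag (OOB) discipline: a training sample's score only uses trees
whose bootstrap excluded it — resubstitution votes would be near-perfect
and uninformative.  Bagging and OOB bookkeeping are explicit here (each
tree is an unpruned sklearn ``DecisionTreeClassifier`` with
floor(sqrt(p)) candidate features per split, fit on its own bootstrap), so
per-sample eligible-tree counts are exact.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.tree import DecisionTreeClassifier

from .errors import InputError
from .spectral_processing import FeatureMatrix
from .synthetic_cohort import PatientRecord

POSITIVE_LABEL = "aBC"
NEGATIVE_LABEL = "eBC"


@dataclass(frozen=True)
class CohortSplit:
    """Deterministic training/validation partition.

    Training: relapse-free early + all advanced patients (labels eBC/aBC).
    Validation: all early patients who relapsed (true class eBC).
    """

    training_ids: tuple[str, ...]
    validation_ids: tuple[str, ...]
    label_map: Mapping[str, str]

    def __post_init__(self) -> None:
        overlap = set(self.training_ids) & set(self.validation_ids)
        if overlap:
            raise InputError(f"ids in both partitions: {sorted(overlap)}")


@dataclass(frozen=True)
class RiskScore:
    """Vote fraction for the metastatic class plus its dichotomization."""

    sample_id: str
    score: float
    n_trees_used: int
    oob_only: bool
    risk_class: str  # high | low

    def __post_init__(self) -> None:
        if not (0.0 <= self.score <= 1.0):
            raise InputError("score must lie in [0, 1]")


@dataclass(frozen=True)
class PerformanceMetrics:
    sensitivity: float
    specificity: float
    accuracy: float
    auc: float
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def confusion(self) -> tuple[int, int, int, int]:
        return self.tp, self.fp, self.tn, self.fn


def build_split(patients: Sequence[PatientRecord]) -> CohortSplit:
    """Partition patients by stage group into training and validation."""
    training, validation, labels = [], [], {}
    for p in patients:
        if p.stage_group == "aBC":
            training.append(p.patient_id)
            labels[p.patient_id] = POSITIVE_LABEL
        elif p.stage_group == "eBC_FFDR":
            training.append(p.patient_id)
            labels[p.patient_id] = NEGATIVE_LABEL
        elif p.stage_group == "eBC_relapsed":
            validation.append(p.patient_id)
            labels[p.patient_id] = NEGATIVE_LABEL
    if not any(v == POSITIVE_LABEL for v in labels.values()):
        raise InputError("no advanced-stage patients: classifier undefined")
    if not validation:
        warnings.warn("no relapsed patients: validation set is empty")
    return CohortSplit(tuple(training), tuple(validation), labels)


class RFVoteEnsemble:
    """Bagged unpruned trees with explicit bootstrap membership."""

    def __init__(self, trees, bootstrap_idx, training_ids, feature_names):
        self.trees = trees
        self.bootstrap_idx = bootstrap_idx  # (n_trees, n_train) int
        self.training_ids = list(training_ids)
        self.feature_names = list(feature_names)
        self.n_trees = len(trees)
        n = len(self.training_ids)
        # inbag[t, i]: tree t's bootstrap contained training sample i
        self.inbag = np.zeros((self.n_trees, n), dtype=bool)
        for t in range(self.n_trees):
            self.inbag[t, np.unique(bootstrap_idx[t])] = True
        self._train_pos = {sid: i for i, sid in enumerate(self.training_ids)}

    @property
    def max_features_per_split(self) -> int:
        return int(self.trees[0].max_features_)

    def votes(self, X: np.ndarray) -> np.ndarray:
        """(n_samples, n_trees) boolean matrix of metastatic votes."""
        X = np.asarray(X, dtype=float)
        out = np.empty((X.shape[0], self.n_trees), dtype=bool)
        for t, tree in enumerate(self.trees):
            out[:, t] = tree.predict(X) == 1
        return out

    def oob_mask(self, sample_id: str) -> np.ndarray:
        """Boolean mask over trees for which the training sample is OOB."""
        i = self._train_pos[sample_id]
        return ~self.inbag[:, i]


def fit_rf(
    matrix: FeatureMatrix,
    split: CohortSplit,
    n_trees: int = 500,
    seed: int | None = None,
) -> RFVoteEnsemble:
    """Fit the bagged ensemble on the training partition.

    Each tree is grown unpruned on its own bootstrap of the training rows,
    with floor(sqrt(p)) candidate features per split.  A fixed seed yields
    an identical ensemble.
    """
    missing = [i for i in split.training_ids if i not in matrix.values.index]
    if missing:
        raise InputError(f"feature matrix lacks training samples {missing}")
    X = matrix.values.loc[list(split.training_ids)].to_numpy(dtype=float)
    y = np.array(
        [1 if split.label_map[i] == POSITIVE_LABEL else 0 for i in split.training_ids]
    )
    for cls in (0, 1):
        if (y == cls).sum() < 2:
            raise InputError("each class needs at least 2 training samples")
    n, p = X.shape
    mf = max(1, math.floor(math.sqrt(p)))
    rng = np.random.default_rng(seed)
    trees, boot = [], np.empty((n_trees, n), dtype=np.int64)
    for t in range(n_trees):
        idx = rng.integers(0, n, size=n)
        boot[t] = idx
        tree = DecisionTreeClassifier(
            max_features=mf, random_state=int(rng.integers(0, 2**31 - 1))
        )
        tree.fit(X[idx], y[idx])
        trees.append(tree)
    return RFVoteEnsemble(trees, boot, split.training_ids, matrix.values.columns)


def classify_risk(score: float, threshold: float = 0.5) -> str:
    """Dichotomize a vote fraction; a tie at the threshold goes to high."""
    if not (0.0 <= score <= 1.0):
        raise InputError(f"score {score} outside [0, 1]")
    return "high" if score >= threshold else "low"


def rf_risk_score(
    ensemble: RFVoteEnsemble,
    sample_id: str,
    matrix: FeatureMatrix,
    threshold: float = 0.5,
) -> RiskScore:
    """Vote fraction for one sample.

    Training samples use only their OOB trees (raising if none exist);
    validation or external samples use the whole forest.
    """
    if sample_id not in matrix.values.index:
        raise InputError(f"sample {sample_id} not in feature matrix")
    x = matrix.values.loc[[sample_id]].to_numpy(dtype=float)
    votes = ensemble.votes(x)[0]
    if sample_id in ensemble._train_pos:
        mask = ensemble.oob_mask(sample_id)
        if not mask.any():
            raise InputError(
                f"training sample {sample_id} has zero OOB trees; "
                "increase n_trees rather than falling back to in-bag votes"
            )
        used = votes[mask]
        oob_only = True
    else:
        used = votes
        oob_only = False
    score = float(used.mean())
    return RiskScore(
        sample_id=sample_id,
        score=score,
        n_trees_used=int(used.size),
        oob_only=oob_only,
        risk_class=classify_risk(score, threshold),
    )


def score_samples(
    ensemble: RFVoteEnsemble,
    matrix: FeatureMatrix,
    sample_ids: Sequence[str] | None = None,
    threshold: float = 0.5,
) -> list[RiskScore]:
    ids = list(sample_ids) if sample_ids is not None else matrix.sample_ids
    return [rf_risk_score(ensemble, i, matrix, threshold) for i in ids]


def scores_to_frame(scores: Sequence[RiskScore]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in scores],
            "score": [s.score for s in scores],
            "n_trees_used": [s.n_trees_used for s in scores],
            "oob_only": [s.oob_only for s in scores],
            "risk_class": [s.risk_class for s in scores],
        }
    )


def performance_metrics(
    scores: Sequence[RiskScore], truth: Mapping[str, str]
) -> PerformanceMetrics:
    """Confusion metrics and Mann-Whitney AUC, positives = metastatic.

    The AUC is the probability that a random metastatic sample scores above
    a random early sample, ties counting one half.
    """
    missing = [s.sample_id for s in scores if s.sample_id not in truth]
    if missing:
        raise InputError(f"no truth label for samples {missing}")
    y = np.array([1 if truth[s.sample_id] == POSITIVE_LABEL else 0 for s in scores])
    pred = np.array([1 if s.risk_class == "high" else 0 for s in scores])
    vals = np.array([s.score for s in scores])
    if len(np.unique(y)) < 2:
        raise InputError("single-class truth: AUC undefined")
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    return PerformanceMetrics(
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        accuracy=(tp + tn) / len(scores),
        auc=float(roc_auc_score(y, vals)),
        tp=tp, fp=fp, tn=tn, fn=fn,
    )


def _oob_scores(ensemble: RFVoteEnsemble, X: np.ndarray) -> np.ndarray:
    """OOB vote fraction per training sample (rows of X = training order)."""
    votes = ensemble.votes(X)  # (n, n_trees)
    oob = ~ensemble.inbag.T  # (n, n_trees)
    n_used = oob.sum(axis=1)
    if np.any(n_used == 0):
        raise InputError("a training sample has zero OOB trees; increase n_trees")
    return (votes & oob).sum(axis=1) / n_used


def oob_metric(
    matrix: FeatureMatrix,
    split: CohortSplit,
    n_trees: int,
    seed: int | None,
    metric: str = "oob_accuracy",
    y_override: np.ndarray | None = None,
) -> float:
    """Fit an ensemble and compute an OOB summary statistic."""
    X = matrix.values.loc[list(split.training_ids)].to_numpy(dtype=float)
    y = np.array(
        [1 if split.label_map[i] == POSITIVE_LABEL else 0 for i in split.training_ids]
    )
    if y_override is not None:
        y = y_override
        labels = {
            sid: (POSITIVE_LABEL if v else NEGATIVE_LABEL)
            for sid, v in zip(split.training_ids, y)
        }
        split = CohortSplit(split.training_ids, split.validation_ids, labels)
    ens = fit_rf(matrix, split, n_trees=n_trees, seed=seed)
    s = _oob_scores(ens, X)
    if metric == "oob_accuracy":
        return float(((s >= 0.5).astype(int) == y).mean())
    if metric == "oob_auc":
        return float(roc_auc_score(y, s))
    raise InputError(f"unknown permutation metric {metric!r}")


def permutation_test(
    matrix: FeatureMatrix,
    split: CohortSplit,
    n_trees: int = 500,
    n_perm: int = 99,
    seed: int | None = None,
    metric: str = "oob_accuracy",
) -> tuple[float, float, np.ndarray]:
    """Label-permutation significance of the classifier.

    Training labels are shuffled within the training set, the forest refit,
    and the OOB statistic recomputed; p = (1 + #{permuted >= observed})
    / (1 + n_perm), so the smallest attainable p is 1/(n_perm + 1).
    Returns (p, observed, permuted values).
    """
    if n_perm < 1:
        raise InputError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    observed = oob_metric(
        matrix, split, n_trees, int(rng.integers(0, 2**31 - 1)), metric
    )
    y = np.array(
        [1 if split.label_map[i] == POSITIVE_LABEL else 0 for i in split.training_ids]
    )
    permuted = np.empty(n_perm)
    for k in range(n_perm):
        y_perm = rng.permutation(y)
        permuted[k] = oob_metric(
            matrix, split, n_trees, int(rng.integers(0, 2**31 - 1)), metric, y_perm
        )
    p = (1.0 + float((permuted >= observed).sum())) / (1.0 + n_perm)
    return p, observed, permuted
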