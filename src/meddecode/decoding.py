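"""Repeated-split MVPA: subject-level 75/25 splits, fold-wise ANOVA top-k
feature selection, linear SVM (C=1), accuracy accounting.

Each of the (default 200) repetitions partitions *subjects* — never samples —
into 75% train / 25% test, computes per-edge one-way ANOVA F scores on the
training rows only, keeps the k (default 200) highest-F edges, fits a linear
soft-margin SVM (C=1) on those features, and scores accuracy on the held-out
subjects' samples.  Splitting at the subject level prevents identity leakage
between train and test.  FA is the positive class, so positive SVM weights
mark edges whose higher connectivity favours focused-attention meditation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from sklearn.svm import SVC

from .connectivity import DecodingDataset
from .util import ConfigurationError, ValidationError, log, rng_stream

POSITIVE_CLASS = "FA"  # encoded +1; OM encoded -1


@dataclass(frozen=True)
class CVConfig:
    n_repetitions: int = 200
    train_fraction: float = 0.75
    k_features: int = 200
    C: float = 1.0
    standardize: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ConfigurationError("train_fraction must lie in (0, 1)")
        if self.k_features < 1 or self.n_repetitions < 1:
            raise ConfigurationError("k_features and n_repetitions must be >= 1")
        if self.C <= 0:
            raise ConfigurationError("C must be positive")


@dataclass
class FoldResult:
    accuracy: float
    selected_edges: np.ndarray       # sorted edge ids, size min(k, n_edges)
    weights: np.ndarray              # per selected edge, FA-positive convention
    intercept: float
    train_subjects: tuple[str, ...]
    test_subjects: tuple[str, ...]


@dataclass
class CVResult:
    folds: list[FoldResult]
    config: CVConfig
    n_edges: int

    @property
    def accuracies(self) -> np.ndarray:
        return np.array([f.accuracy for f in self.folds])

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracies.mean())

    @property
    def n_repetitions(self) -> int:
        return len(self.folds)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": self.config.__dict__,
            "n_edges": self.n_edges,
            "folds": [
                {"accuracy": f.accuracy,
                 "selected_edges": f.selected_edges.tolist(),
                 "weights": f.weights.tolist(),
                 "intercept": f.intercept,
                 "train_subjects": list(f.train_subjects),
                 "test_subjects": list(f.test_subjects)}
                for f in self.folds
            ],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "CVResult":
        payload = json.loads(Path(path).read_text())
        folds = [
            FoldResult(accuracy=f["accuracy"],
                       selected_edges=np.array(f["selected_edges"], dtype=int),
                       weights=np.array(f["weights"]),
                       intercept=f["intercept"],
                       train_subjects=tuple(f["train_subjects"]),
                       test_subjects=tuple(f["test_subjects"]))
            for f in payload["folds"]
        ]
        return cls(folds=folds, config=CVConfig(**payload["config"]),
                   n_edges=payload["n_edges"])


def train_subject_count(n_subjects: int, train_fraction: float) -> int:
    """round-half-to-even of fraction*n, clamped so >= 1 subject tests."""
    n_train = int(round(train_fraction * n_subjects))
    return min(max(n_train, 1), n_subjects - 1)


def subject_level_split(dataset: DecodingDataset, config: CVConfig,
                        repetition: int) -> tuple[np.ndarray, np.ndarray]:
    """Random subject partition for one repetition; returns sample index arrays."""
    subjects = np.array(dataset.subjects)
    if subjects.size < 4:
        raise ValidationError("need at least 4 subjects for subject-level splits")
    rng = rng_stream(config.seed, "split", repetition)
    perm = rng.permutation(subjects.size)
    n_train = train_subject_count(subjects.size, config.train_fraction)
    train_subj = set(subjects[perm[:n_train]])
    train_mask = np.array([s in train_subj for s in dataset.subject])
    return np.nonzero(train_mask)[0], np.nonzero(~train_mask)[0]


def anova_f_scores(X_train: np.ndarray, y_train: np.ndarray) -> np.ndarray:
    """Per-feature one-way ANOVA F for the two-class case.

    Equals the squared pooled-variance two-sample t statistic.  Features that
    are constant across all training samples get F = 0; features with zero
    within-class variance but distinct class means get F = inf.
    """
    classes = np.unique(y_train)
    if classes.size < 2:
        raise ValidationError("training set contains a single class")
    n = X_train.shape[0]
    grand = X_train.mean(axis=0)
    ssb = np.zeros(X_train.shape[1])
    ssw = np.zeros(X_train.shape[1])
    for c in classes:
        rows = X_train[y_train == c]
        m = rows.mean(axis=0)
        ssb += rows.shape[0] * (m - grand) ** 2
        ssw += ((rows - m) ** 2).sum(axis=0)
    df1 = classes.size - 1
    df2 = n - classes.size
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / df1) / (ssw / df2)
    F[ssb == 0] = 0.0  # covers the constant-feature 0/0 case
    return F


def select_top_k(F: np.ndarray, k: int) -> np.ndarray:
    """Edge ids of the k largest F values; ties broken by ascending edge id.

    Returned sorted by edge id (selection is a set; order carries no rank).
    """
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    if k >= F.shape[0]:
        return np.arange(F.shape[0])
    order = np.lexsort((np.arange(F.shape[0]), -F))
    return np.sort(order[:k])


def fit_linear_classifier(X_sel: np.ndarray, y: np.ndarray,
                          C: float = 1.0) -> tuple[np.ndarray, float, SVC]:
    """Soft-margin linear SVM; FA encoded +1 so positive weights favour FA."""
    if not np.all(np.isfinite(X_sel)):
        raise ValidationError("non-finite features passed to the classifier")
    y_enc = np.where(y == POSITIVE_CLASS, 1, -1)
    if np.unique(y_enc).size < 2:
        raise ValidationError("training set contains a single class")
    clf = SVC(kernel="linear", C=C)
    clf.fit(X_sel, y_enc)
    # sklearn orders classes ascending (-1, +1): decision > 0 predicts +1 = FA
    return clf.coef_.ravel().copy(), float(clf.intercept_[0]), clf


def run_cv(dataset: DecodingDataset, config: CVConfig) -> CVResult:
    """The full repeated-split decoding loop.

    Feature selection is computed inside each repetition on training rows
    only (no test-set leakage).  Deterministic given (dataset, config.seed).
    """
    folds: list[FoldResult] = []
    mu = sigma = None
    for rep in range(config.n_repetitions):
        train_idx, test_idx = _usable_split(dataset, config, rep)
        X_tr, y_tr = dataset.X[train_idx], dataset.y[train_idx]
        X_te, y_te = dataset.X[test_idx], dataset.y[test_idx]
        if config.standardize:
            mu = X_tr.mean(axis=0)
            sigma = X_tr.std(axis=0)
            sigma[sigma == 0] = 1.0
            X_tr = (X_tr - mu) / sigma
            X_te = (X_te - mu) / sigma
        F = anova_f_scores(X_tr, y_tr)
        selected = select_top_k(F, config.k_features)
        w, b, clf = fit_linear_classifier(X_tr[:, selected], y_tr, C=config.C)
        pred = np.where(X_te[:, selected] @ w + b > 0, "FA", "OM")
        acc = float((pred == y_te).mean())
        subj_tr = tuple(dict.fromkeys(str(s) for s in dataset.subject[train_idx]))
        subj_te = tuple(dict.fromkeys(str(s) for s in dataset.subject[test_idx]))
        folds.append(FoldResult(accuracy=acc, selected_edges=selected,
                                weights=w, intercept=b,
                                train_subjects=subj_tr, test_subjects=subj_te))
    return CVResult(folds=folds, config=config, n_edges=dataset.n_edges)


def _usable_split(dataset: DecodingDataset, config: CVConfig,
                  rep: int) -> tuple[np.ndarray, np.ndarray]:
    """Split for repetition ``rep``; redraw (offset stream) if a side would
    miss a class — possible only when scrubbing unbalanced the dataset."""
    for attempt in range(20):
        train_idx, test_idx = subject_level_split(
            dataset, config if attempt == 0 else replace(
                config, seed=config.seed + 90001 * attempt), rep)
        if (np.unique(dataset.y[train_idx]).size == 2
                and np.unique(dataset.y[test_idx]).size == 2):
            if attempt:
                log.info("run_cv: repetition %d redrawn %d time(s)", rep, attempt)
            return train_idx, test_idx
    raise ValidationError("could not draw a split with both classes on both sides")
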