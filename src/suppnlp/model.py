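"""Bigram-feature linear SVM over snippet observations.

Features follow the bag-of-bigrams design: binary presence indicators for
every unique ordered pair of adjacent (case-folded) tokens seen in the
training snippets, plus a single categorical feature identifying which
lexicon keyword the observation classifies (one-hot encoded, with an
explicit level for keywords unseen at training time).  The classifier is a
soft-margin linear SVM; no feature selection and no hyperparameter tuning
are performed.

Both pieces are scikit-learn estimators (``SnippetVectorizer`` a
transformer, ``SupplementUseClassifier`` a classifier), so they compose
with sklearn pipelines and model selection; the module-level
``build_feature_space`` / ``vectorize`` / ``train`` / ``cross_validate``
functions are thin wrappers over them.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin, clone
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .snippets import SnippetObservation

UNKNOWN_KEYWORD = "<unknown>"
YES, NO = "yes", "no"


def snippet_bigrams(tokens: Sequence[str]) -> set[tuple[str, str]]:
    """Unique ordered adjacent case-folded token pairs of one snippet."""
    folded = [t.casefold() for t in tokens]
    return set(zip(folded, folded[1:]))


@dataclass(frozen=True)
class FeatureSpace:
    """Column layout: bigram indicators first, then the keyword one-hot."""

    bigram_index: dict[tuple[str, str], int]
    keyword_index: dict[str, int]

    @property
    def n_features(self) -> int:
        return len(self.bigram_index) + len(self.keyword_index)


class SnippetVectorizer(BaseEstimator, TransformerMixin):
    """Binary bigram-presence features plus a one-hot keyword indicator.

    ``fit`` builds the feature space from the training observations only;
    bigrams first seen at transform time are ignored, and unseen keywords
    are routed to an explicit unknown level.  Column order is lexicographic
    and therefore deterministic.
    """

    def fit(self, X: Sequence[SnippetObservation], y=None) -> "SnippetVectorizer":
        if len(X) == 0:
            raise ValueError("cannot build a feature space from zero observations")
        bigrams: set[tuple[str, str]] = set()
        keywords: set[str] = set()
        for obs in X:
            bigrams |= snippet_bigrams(obs.tokens)
            keywords.add(obs.keyword)
        self.feature_space_ = FeatureSpace(
            bigram_index={bg: i for i, bg in enumerate(sorted(bigrams))},
            keyword_index={
                kw: i for i, kw in enumerate(sorted(keywords) + [UNKNOWN_KEYWORD])
            },
        )
        return self

    def transform(self, X: Sequence[SnippetObservation]) -> sp.csr_matrix:
        check_is_fitted(self, "feature_space_")
        space = self.feature_space_
        n_bigrams = len(space.bigram_index)
        indptr = [0]
        indices: list[int] = []
        for obs in X:
            cols = sorted(
                space.bigram_index[bg]
                for bg in snippet_bigrams(obs.tokens)
                if bg in space.bigram_index
            )
            kw_col = space.keyword_index.get(
                obs.keyword, space.keyword_index[UNKNOWN_KEYWORD]
            )
            cols.append(n_bigrams + kw_col)
            indices.extend(cols)
            indptr.append(len(indices))
        data = np.ones(len(indices), dtype=np.float64)
        return sp.csr_matrix(
            (data, np.asarray(indices, dtype=np.int64), np.asarray(indptr, dtype=np.int64)),
            shape=(len(X), space.n_features),
        )


class SupplementUseClassifier(BaseEstimator, ClassifierMixin):
    """Linear SVM deciding whether a keyword occurrence indicates active use.

    Parameters
    ----------
    C : float
        Soft-margin penalty of the SVM (hinge loss + L2, linear kernel).
    seed : int
        Recorded for provenance; the linear-kernel SMO fit is itself
        deterministic, so identical data and parameters give identical
        weights regardless.

    Attributes (after ``fit``)
    --------------------------
    vectorizer_ : SnippetVectorizer
    classes_ : ndarray of the two labels, sorted ("no", "yes")
    coef_, intercept_ : the linear decision function w, b
    """

    def __init__(self, C: float = 1.0, seed: int = 0):
        self.C = C
        self.seed = seed

    def fit(self, X: Sequence[SnippetObservation], y=None) -> "SupplementUseClassifier":
        if y is None:
            y = [obs.label for obs in X]
        y = np.asarray(y, dtype=object)
        if any(lab is None for lab in y):
            raise ValueError("all training observations must be labeled")
        if len(set(y)) < 2:
            raise ValueError("degenerate training set: only one class present")
        self.vectorizer_ = SnippetVectorizer().fit(X)
        Xm = self.vectorizer_.transform(X)
        svm = SVC(kernel="linear", C=self.C, random_state=self.seed)
        svm.fit(Xm, y)
        self.classes_ = svm.classes_
        coef = svm.coef_
        self.coef_ = np.asarray(coef.todense()).ravel() if sp.issparse(coef) else np.ravel(coef)
        self.intercept_ = float(svm.intercept_[0])
        return self

    @property
    def feature_space_(self) -> FeatureSpace:
        check_is_fitted(self, "vectorizer_")
        return self.vectorizer_.feature_space_

    def decision_function(self, X: Sequence[SnippetObservation]) -> np.ndarray:
        check_is_fitted(self, "coef_")
        Xm = self.vectorizer_.transform(X)
        return Xm @ self.coef_ + self.intercept_

    def predict(self, X: Sequence[SnippetObservation]) -> np.ndarray:
        scores = self.decision_function(X)
        return self.classes_[(scores > 0).astype(int)]


# ---------------------------------------------------------------------------
# Metrics and cross-validation


@dataclass(frozen=True)
class ClassMetrics:
    precision: float
    recall: float
    f1: float
    support: int


@dataclass
class CVReport:
    """Per-class and support-weighted precision/recall/F1 from k-fold CV."""

    per_class: dict[str, ClassMetrics]
    weighted_avg: ClassMetrics
    fold_assignments: list[int]
    k: int
    seed: int
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def row(m: ClassMetrics) -> dict:
            return {
                "precision": m.precision,
                "recall": m.recall,
                "f1": m.f1,
                "support": m.support,
            }

        return {
            "classes": {c: row(m) for c, m in self.per_class.items()},
            "weighted_avg": row(self.weighted_avg),
            "k": self.k,
            "seed": self.seed,
            "config": self.config,
            "fold_assignments": self.fold_assignments,
        }

    def table(self) -> str:
        lines = [f"{'Class':<14}{'Precision':>10}{'Recall':>10}{'F1':>10}"]
        for cls in (YES, NO):
            if cls in self.per_class:
                m = self.per_class[cls]
                lines.append(
                    f"{cls.capitalize():<14}{m.precision:>10.3f}{m.recall:>10.3f}{m.f1:>10.3f}"
                )
        w = self.weighted_avg
        lines.append(f"{'Weighted Avg.':<14}{w.precision:>10.3f}{w.recall:>10.3f}{w.f1:>10.3f}")
        return "\n".join(lines)


def per_class_metrics(y_true: Sequence[str], y_pred: Sequence[str]) -> dict[str, ClassMetrics]:
    """Precision/recall/F1 per class from one-vs-rest confusion counts.

    Zero denominators yield NaN rather than a silent 0.
    """
    y_true = list(y_true)
    y_pred = list(y_pred)
    out: dict[str, ClassMetrics] = {}
    for cls in sorted(set(y_true) | set(y_pred)):
        tp = sum(1 for t, p in zip(y_true, y_pred) if t == cls and p == cls)
        fp = sum(1 for t, p in zip(y_true, y_pred) if t != cls and p == cls)
        fn = sum(1 for t, p in zip(y_true, y_pred) if t == cls and p != cls)
        prec = tp / (tp + fp) if (tp + fp) else math.nan
        rec = tp / (tp + fn) if (tp + fn) else math.nan
        f1 = (
            2 * prec * rec / (prec + rec)
            if (tp + fp) and (tp + fn) and (prec + rec) > 0
            else (0.0 if (tp + fp) and (tp + fn) else math.nan)
        )
        out[cls] = ClassMetrics(prec, rec, f1, support=tp + fn)
    return out


def weighted_average(per_class: dict[str, ClassMetrics]) -> ClassMetrics:
    total = sum(m.support for m in per_class.values())
    if total == 0:
        raise ValueError("no support")
    return ClassMetrics(
        precision=sum(m.precision * m.support for m in per_class.values()) / total,
        recall=sum(m.recall * m.support for m in per_class.values()) / total,
        f1=sum(m.f1 * m.support for m in per_class.values()) / total,
        support=total,
    )


def cross_validate(
    observations: Sequence[SnippetObservation],
    k: int = 10,
    seed: int = 0,
    C: float = 1.0,
    estimator: Optional[SupplementUseClassifier] = None,
) -> CVReport:
    """Stratified k-fold CV with the feature space rebuilt inside each fold.

    A fresh vectorizer and SVM are fitted on every training fold, so no
    test-fold token or keyword ever contributes a feature column or a weight
    (no leakage).  Fully deterministic for a fixed seed.
    """
    labels = np.asarray([obs.label for obs in observations], dtype=object)
    if any(lab is None for lab in labels):
        raise ValueError("all observations must be labeled for cross-validation")
    if k > len(observations):
        raise ValueError(f"k={k} exceeds the number of observations ({len(observations)})")
    if len(set(labels)) < 2:
        raise ValueError("degenerate training set: only one class present")
    base = estimator if estimator is not None else SupplementUseClassifier(C=C, seed=seed)

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    y_pred = np.empty(len(observations), dtype=object)
    fold_of = [0] * len(observations)
    for fold, (train_idx, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        clf = clone(base)
        clf.fit([observations[i] for i in train_idx], labels[train_idx])
        y_pred[test_idx] = clf.predict([observations[i] for i in test_idx])
        for i in test_idx:
            fold_of[i] = fold
    per_class = per_class_metrics(labels, y_pred)
    return CVReport(
        per_class=per_class,
        weighted_avg=weighted_average(per_class),
        fold_assignments=fold_of,
        k=k,
        seed=seed,
        config={"C": base.C},
    )


# ---------------------------------------------------------------------------
# Thin functional wrappers and model persistence

def build_feature_space(observations: Sequence[SnippetObservation]) -> FeatureSpace:
    return SnippetVectorizer().fit(observations).feature_space_


def vectorize(observation: SnippetObservation, space: FeatureSpace) -> sp.csr_matrix:
    vec = SnippetVectorizer()
    vec.feature_space_ = space
    return vec.transform([observation])


def train(
    observations: Sequence[SnippetObservation], C: float = 1.0, seed: int = 0
) -> SupplementUseClassifier:
    return SupplementUseClassifier(C=C, seed=seed).fit(observations)


MODEL_FORMAT_VERSION = 1


def save_model(clf: SupplementUseClassifier, path: str | Path) -> None:
    """Serialise to versioned JSON; floats round-trip exactly via repr."""
    check_is_fitted(clf, "coef_")
    space = clf.feature_space_
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "config": {"C": clf.C, "seed": clf.seed},
        "bigrams": [list(bg) for bg, _ in sorted(space.bigram_index.items(), key=lambda kv: kv[1])],
        "keywords": [kw for kw, _ in sorted(space.keyword_index.items(), key=lambda kv: kv[1])],
        "classes": [str(c) for c in clf.classes_],
        "coef": clf.coef_.tolist(),
        "intercept": clf.intercept_,
    }
    Path(path).write_text(json.dumps(payload), encoding="utf-8")


def load_model(path: str | Path) -> SupplementUseClassifier:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format: {payload.get('format_version')!r}")
    clf = SupplementUseClassifier(**payload["config"])
    vec = SnippetVectorizer()
    vec.feature_space_ = FeatureSpace(
        bigram_index={tuple(bg): i for i, bg in enumerate(payload["bigrams"])},
        keyword_index={kw: i for i, kw in enumerate(payload["keywords"])},
    )
    clf.vectorizer_ = vec
    clf.classes_ = np.asarray(payload["classes"], dtype=object)
    clf.coef_ = np.asarray(payload["coef"], dtype=np.float64)
    clf.intercept_ = float(payload["intercept"])
    return clf
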