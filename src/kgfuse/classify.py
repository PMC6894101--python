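"""One-vs-rest linear SVM classification, label ranking, and the
alternative integration strategies: upsampling, Borda late fusion, and
pseudo-document augmentation.

The classifier of record is a linear maximum-margin one-vs-rest model
(hinge loss, squared-norm penalty, C = 1 by default) over sparse
document vectors; decision scores are used raw for ranking labels from
most to least probable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.svm import LinearSVC
from sklearn.exceptions import ConvergenceWarning

from .corpus import LabeledCorpus, TokenizedDocument

__all__ = [
    "LinearOvRModel",
    "RankedPrediction",
    "C_GRID",
    "train_ovr",
    "rank_labels",
    "score_matrix",
    "borda_fuse",
    "upsample_training",
    "augment_pseudo_docs",
]

#: Regularization grid searched in the reference experiments; C=1 won.
C_GRID = (0.001, 0.01, 0.1, 1.0, 10.0, 100.0)


@dataclass(frozen=True)
class LinearOvRModel:
    """Per-class linear scorers: score_c(x) = coef[c]·x + intercept[c]."""

    classes: tuple[str, ...]
    coef: np.ndarray        # (n_classes, n_features)
    intercept: np.ndarray   # (n_classes,)
    C: float

    @property
    def n_features(self) -> int:
        return self.coef.shape[1]


def train_ovr(
    X: sp.spmatrix,
    y: Sequence[str],
    C: float = 1.0,
    tol: float = 1e-4,
    max_iter: int = 10000,
) -> LinearOvRModel:
    """Fit one hinge-loss linear scorer per class (one-vs-rest).

    Deterministic for fixed input: the dual coordinate-descent solver is
    seeded and capped (tolerance 1e-4, documented iteration cap).
    """
    if C <= 0:
        raise ValueError("C must be positive")
    if C not in C_GRID:
        warnings.warn(f"C={C} is outside the usual grid {C_GRID}", stacklevel=2)
    classes = tuple(sorted(set(y)))
    if len(classes) < 2:
        raise ValueError("one-vs-rest training requires at least two classes")
    y = np.asarray(list(y), dtype=object)
    if X.shape[0] != len(y):
        raise ValueError("X rows and y length differ")
    svc = LinearSVC(
        C=C, loss="hinge", tol=tol, max_iter=max_iter, random_state=0
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        svc.fit(X, y)
    if len(classes) == 2:
        # liblinear fits a single boundary for two classes; expand to
        # one scorer per class so ranking code is uniform.
        coef = np.vstack([-svc.coef_[0], svc.coef_[0]])
        intercept = np.array([-svc.intercept_[0], svc.intercept_[0]])
    else:
        coef = np.asarray(svc.coef_)
        intercept = np.asarray(svc.intercept_)
    assert tuple(svc.classes_) == classes
    return LinearOvRModel(classes, coef, intercept, C)


def score_matrix(model: LinearOvRModel, X: sp.spmatrix) -> np.ndarray:
    """Decision scores, one row per document, one column per class."""
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"feature dimension mismatch: {X.shape[1]} != {model.n_features}"
        )
    return np.asarray(X @ model.coef.T) + model.intercept[None, :]


@dataclass(frozen=True)
class RankedPrediction:
    """Every training label exactly once, most to least probable.

    Exact score ties are broken lexicographically by label, so the order
    is deterministic.
    """

    doc_id: str
    labels: tuple[str, ...]
    scores: tuple[float, ...]

    def rank_of(self, label: str) -> int:
        """1-based rank of a label."""
        return self.labels.index(label) + 1

    @property
    def top(self) -> str:
        return self.labels[0]


def rank_labels(
    model: LinearOvRModel, x, doc_id: str = ""
) -> RankedPrediction:
    """Sort all labels by decision score descending (ties lexicographic)."""
    x = sp.csr_matrix(x) if not sp.issparse(x) else x
    scores = score_matrix(model, x)[0]
    order = sorted(range(len(model.classes)), key=lambda i: (-scores[i], model.classes[i]))
    return RankedPrediction(
        doc_id,
        tuple(model.classes[i] for i in order),
        tuple(float(scores[i]) for i in order),
    )


def borda_fuse(rank_a: RankedPrediction, rank_b: RankedPrediction) -> RankedPrediction:
    """Borda rank aggregation of two label rankings.

    A label at 1-based rank r in a list of L labels earns (L − r) points
    from that list; labels are re-sorted by total points descending,
    ties broken by the better rank in the first list, then
    lexicographically. The fused "scores" are the Borda points.
    """
    if set(rank_a.labels) != set(rank_b.labels):
        raise ValueError("rankings cover different label sets")
    L = len(rank_a.labels)
    pos_a = {l: r for r, l in enumerate(rank_a.labels, start=1)}
    pos_b = {l: r for r, l in enumerate(rank_b.labels, start=1)}
    points = {l: (L - pos_a[l]) + (L - pos_b[l]) for l in rank_a.labels}
    order = sorted(rank_a.labels, key=lambda l: (-points[l], pos_a[l], l))
    return RankedPrediction(
        rank_a.doc_id, tuple(order), tuple(float(points[l]) for l in order)
    )


def upsample_training(train: LabeledCorpus, seed: int = 0) -> LabeledCorpus:
    """Resample every class (with replacement) up to the majority size.

    Original documents are always retained; duplicates get suffixed ids.
    A common imbalanced-learning baseline — the comparison arms show it
    is unstable under extreme imbalance.
    """
    if len(train) == 0:
        raise ValueError("empty training corpus")
    rng = np.random.default_rng(seed)
    grouped = train.by_label()
    target = max(len(v) for v in grouped.values())
    docs = list(train.documents)
    for label in sorted(grouped):
        pool = sorted(grouped[label], key=lambda d: d.doc_id)
        deficit = target - len(pool)
        if deficit <= 0:
            continue
        picks = rng.integers(0, len(pool), size=deficit)
        for j, i in enumerate(picks):
            src = pool[i]
            docs.append(
                TokenizedDocument(
                    f"{src.doc_id}::up{j}", src.raw_text, src.tokens, src.label
                )
            )
    return LabeledCorpus(tuple(docs))


def augment_pseudo_docs(train: LabeledCorpus, K: frozenset[str] | set[str]) -> LabeledCorpus:
    """Rationale-style augmentation: per training document, append a
    same-labeled pseudo document containing only its knowledge tokens.

    Documents sharing no token with K contribute nothing — which is why
    this strategy widens, rather than narrows, the class imbalance:
    large classes generate proportionally more pseudo examples.
    """
    if not K:
        raise ValueError("K must be non-empty")
    docs = list(train.documents)
    for d in train.documents:
        kept = tuple(t for t in d.tokens if t in K)
        if kept:
            docs.append(
                TokenizedDocument(
                    f"{d.doc_id}::rationale", " ".join(kept), kept, d.label
                )
            )
    return LabeledCorpus(tuple(docs))
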