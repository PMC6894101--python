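"""Binned evaluation: macro-F1, mean reciprocal rank, paired
randomization significance testing, and the multi-run comparison driver.

Classifiers are always trained on *all* classes; rarity bins partition
only the reporting, so a per-bin score answers "how well are classes of
this prevalence recognized inside the full multiclass problem".
Per-bin scores from several independent train/test splits are averaged,
and each method is compared against a designated baseline with a paired
randomization test on the pooled per-document outcomes (predicted label
for macro-F1, reciprocal rank for MRR).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp

from . import features as F
from .classify import train_ovr, score_matrix, upsample_training, augment_pseudo_docs
from .corpus import (
    DEFAULT_BIN_EDGES,
    LabeledCorpus,
    compute_rarity_bins,
    per_class_split,
)
from .kg import KnowledgeGraphStore, assemble_knowledge_features

__all__ = [
    "macro_f1",
    "mean_reciprocal_rank",
    "randomization_test",
    "run_experiment",
    "BinnedReport",
    "ReportRow",
    "METHODS",
    "RARE_BIN",
]

#: Synthetic bin key for the pooled rare classes (prevalence <= 0.1%).
RARE_BIN = "rare(<=0.1%)"


# ---------------------------------------------------------------------------
# Metrics

def _encode(labels: Iterable[str], index: Mapping[str, int]) -> np.ndarray:
    return np.array([index[l] for l in labels], dtype=np.intp)


def _macro_f1_encoded(
    preds: np.ndarray, truths: np.ndarray, subset: np.ndarray, n_labels: int
) -> float:
    tp = np.bincount(truths[preds == truths], minlength=n_labels)
    pred_counts = np.bincount(preds, minlength=n_labels)
    true_counts = np.bincount(truths, minlength=n_labels)
    fp = pred_counts - tp
    fn = true_counts - tp
    with np.errstate(divide="ignore", invalid="ignore"):
        f1 = 2.0 * tp / np.maximum(2.0 * tp + fp + fn, 1e-300)
    return float(f1[subset].mean())


def macro_f1(
    predictions: Sequence[str],
    truths: Sequence[str],
    class_subset: Iterable[str],
) -> float:
    """Unweighted mean of per-class F1 over ``class_subset``.

    Precision/recall come from the global confusion counts (predictions
    may fall on any trained class); a class with zero TP and zero
    FP+FN denominator contributes F1 = 0. Subset classes with no true
    test documents are excluded with a warning.
    """
    if len(predictions) != len(truths):
        raise ValueError("predictions and truths differ in length")
    subset = sorted(set(class_subset))
    if not subset:
        raise ValueError("class_subset must be non-empty")
    truth_set = set(truths)
    missing = [c for c in subset if c not in truth_set]
    if missing:
        warnings.warn(
            f"excluding {len(missing)} subset class(es) with no test documents",
            stacklevel=2,
        )
        subset = [c for c in subset if c in truth_set]
        if not subset:
            raise ValueError("no subset class has test documents")
    all_labels = sorted(set(predictions) | truth_set | set(subset))
    index = {l: i for i, l in enumerate(all_labels)}
    return _macro_f1_encoded(
        _encode(predictions, index),
        _encode(truths, index),
        _encode(subset, index),
        len(all_labels),
    )


def mean_reciprocal_rank(
    rankings: Sequence,
    truths: Sequence[str],
    class_subset: Iterable[str],
) -> float | None:
    """Mean of 1/rank of the true label, over test docs whose true class
    is in ``class_subset``. None when no document qualifies."""
    subset = frozenset(class_subset)
    rr = [
        1.0 / ranking.rank_of(truth)
        for ranking, truth in zip(rankings, truths, strict=True)
        if truth in subset
    ]
    return float(np.mean(rr)) if rr else None


def randomization_test(
    outcomes_a: Sequence,
    outcomes_b: Sequence,
    metric: Callable[[Sequence], float],
    rounds: int = 10000,
    seed: int = 0,
) -> float:
    """Paired (approximate) randomization test.

    Each round independently swaps each document's paired outcomes with
    probability 1/2 and recomputes the metric difference; the two-sided
    p-value is (#{|Δ_perm| >= |Δ_obs|} + 1) / (rounds + 1).
    """
    a = np.asarray(outcomes_a)
    b = np.asarray(outcomes_b)
    if a.shape != b.shape:
        raise ValueError("outcome sequences must be paired (equal length)")
    observed = metric(a) - metric(b)
    rng = np.random.default_rng(seed)
    hits = 0
    n = a.shape[0]
    for _ in range(rounds):
        mask = rng.random(n) < 0.5
        pa = np.where(mask, b, a)
        pb = np.where(mask, a, b)
        delta = metric(pa) - metric(pb)
        if abs(delta) >= abs(observed) - 1e-12:
            hits += 1
    return (hits + 1) / (rounds + 1)


# ---------------------------------------------------------------------------
# Single-run method execution

#: Canonical method names. ``pseudo_count`` / ``pseudo_doc`` / ``late_fusion``
#: are accepted as aliases of their _kg1 forms.
METHODS = (
    "bow",
    "upsample",
    "chi2",
    "bow_plus_chi2",
    "kg1",
    "kg12",
    "early_fusion_kg1",
    "early_fusion_kg12",
    "late_fusion_kg1",
    "pseudo_count_kg1",
    "pseudo_doc_kg1",
)

_ALIASES = {
    "pseudo_count": "pseudo_count_kg1",
    "pseudo_doc": "pseudo_doc_kg1",
    "late_fusion": "late_fusion_kg1",
}


def canonical_method(name: str) -> str:
    name = _ALIASES.get(name, name)
    if name not in METHODS:
        raise ValueError(f"unknown method {name!r}; choose from {METHODS}")
    return name


def _rank_matrix(S: np.ndarray) -> np.ndarray:
    """1-based rank of every class for every row; ties by class order
    (classes are sorted, so index order is lexicographic order)."""
    order = np.argsort(-S, axis=1, kind="stable")
    ranks = np.empty_like(order)
    np.put_along_axis(ranks, order, np.arange(1, S.shape[1] + 1)[None, :], axis=1)
    return ranks


def _predictions_from_scores(
    S: np.ndarray, classes: tuple[str, ...], truth_idx: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(predicted class index, 1-based rank of the true class) per row."""
    ranks = _rank_matrix(S)
    top = np.asarray(ranks == 1).argmax(axis=1)
    true_rank = ranks[np.arange(S.shape[0]), truth_idx]
    return top, true_rank


def _run_methods_once(
    train: LabeledCorpus,
    test: LabeledCorpus,
    store: KnowledgeGraphStore,
    methods: Sequence[str],
    *,
    medical_categories: Iterable[str],
    stopwords: Iterable[str],
    C: float,
    seed: int,
    top_n: int,
    specificity_fraction: float,
    pseudo_k: int,
) -> dict[str, tuple[np.ndarray, np.ndarray, tuple[str, ...]]]:
    """Train and evaluate each method on one split.

    Returns method -> (predicted label indices, true-label ranks,
    class list), all aligned with ``test.documents``.
    """
    _, kfs = assemble_knowledge_features(
        train,
        store,
        medical_categories,
        top_n=top_n,
        specificity_fraction=specificity_fraction,
        stopwords=stopwords,
    )
    train_docs = train.documents
    test_docs = test.documents
    y_train = [d.label for d in train_docs]
    classes = tuple(sorted(set(y_train)))
    class_index = {c: i for i, c in enumerate(classes)}
    truth_idx = np.array([class_index[d.label] for d in test_docs], dtype=np.intp)

    cache: dict[str, object] = {}

    def space(key: str) -> F.FeatureSpace:
        if "base" not in cache:
            cache["base"] = F.fit_feature_space(train, kfs.k)
        base: F.FeatureSpace = cache["base"]  # type: ignore[assignment]
        ck = f"space:{key}"
        if ck not in cache:
            K = {"k1": kfs.k1, "k12": kfs.k}[key]
            cache[ck] = base.restrict_vk(K)
        return cache[ck]  # type: ignore[return-value]

    def matrices(kind: str) -> tuple[sp.csr_matrix, sp.csr_matrix]:
        ck = f"X:{kind}"
        if ck in cache:
            return cache[ck]  # type: ignore[return-value]
        if kind == "bow":
            s = space("k1")
            pair = (F.bow_matrix(train_docs, s), F.bow_matrix(test_docs, s))
        elif kind in ("kg1", "kg12"):
            s = space("k1" if kind == "kg1" else "k12")
            pair = (
                F.segment_matrix(train_docs, s, s.vk),
                F.segment_matrix(test_docs, s, s.vk),
            )
        elif kind in ("early_fusion_kg1", "early_fusion_kg12"):
            s = space("k1" if kind.endswith("kg1") else "k12")
            pair = (F.fused_matrix(train_docs, s), F.fused_matrix(test_docs, s))
        elif kind == "pseudo_count_kg1":
            s = space("k1")
            pair = (
                F.pseudo_count_matrix(train_docs, s, pseudo_k),
                F.pseudo_count_matrix(test_docs, s, pseudo_k),
            )
        elif kind in ("chi2", "bow_plus_chi2"):
            s = space("k1")
            m = len(s.vk)
            if m == 0:
                raise ValueError("chi-square arm undefined: V ∩ K1 is empty")
            if "chi2_terms" not in cache:
                cache["chi2_terms"] = F.chi2_feature_selection(train, s, m)
            terms = cache["chi2_terms"]  # type: ignore[assignment]
            seg = (
                F.segment_matrix(train_docs, s, terms),
                F.segment_matrix(test_docs, s, terms),
            )
            if kind == "chi2":
                pair = seg
            else:
                bow = matrices("bow")
                pair = (
                    sp.hstack([bow[0], seg[0]], format="csr"),
                    sp.hstack([bow[1], seg[1]], format="csr"),
                )
        elif kind == "upsample":
            up = upsample_training(train, seed)
            s = F.fit_feature_space(up)
            pair = (F.bow_matrix(up.documents, s), F.bow_matrix(test_docs, s))
            cache["y:upsample"] = [d.label for d in up.documents]
        elif kind == "pseudo_doc_kg1":
            aug = augment_pseudo_docs(train, kfs.k1) if kfs.k1 else train
            s = F.fit_feature_space(aug)
            pair = (F.bow_matrix(aug.documents, s), F.bow_matrix(test_docs, s))
            cache["y:pseudo_doc_kg1"] = [d.label for d in aug.documents]
        else:  # pragma: no cover
            raise ValueError(kind)
        cache[ck] = pair
        return pair

    def scores(kind: str) -> np.ndarray:
        ck = f"S:{kind}"
        if ck not in cache:
            Xtr, Xte = matrices(kind)
            y = cache.get(f"y:{kind}", y_train)
            model = train_ovr(Xtr, y, C=C)
            cache[ck] = score_matrix(model, Xte)
        return cache[ck]  # type: ignore[return-value]

    results: dict[str, tuple[np.ndarray, np.ndarray, tuple[str, ...]]] = {}
    L = len(classes)
    for method in methods:
        if method == "late_fusion_kg1":
            ra = _rank_matrix(scores("bow"))
            rb = _rank_matrix(scores("kg1"))
            points = (L - ra) + (L - rb)
            # fused order: points desc, then bow rank asc, then class order
            fused_rank = _rank_matrix(points.astype(float) - ra * 1e-6)
            top = np.asarray(fused_rank == 1).argmax(axis=1)
            true_rank = fused_rank[np.arange(len(test_docs)), truth_idx]
            results[method] = (top, true_rank, classes)
        else:
            top, true_rank = _predictions_from_scores(
                scores(method), classes, truth_idx
            )
            results[method] = (top, true_rank, classes)
    return results


# ---------------------------------------------------------------------------
# Multi-run driver and report

@dataclass(frozen=True)
class ReportRow:
    """Mean binned metrics for one method in one prevalence bin.

    Metrics are on the conventional 0–100 scale. ``p_*`` are paired
    randomization p-values against the baseline method (None for the
    baseline itself or when the bin has no test documents).
    """

    method: str
    bin_name: str
    n_classes: int
    per_run_f1: tuple[float, ...]
    per_run_mrr: tuple[float, ...]
    mean_f1: float | None
    mean_mrr: float | None
    p_f1: float | None
    p_mrr: float | None


@dataclass(frozen=True)
class BinnedReport:
    rows: tuple[ReportRow, ...]
    runs: int
    base_seed: int
    baseline: str

    def row(self, method: str, bin_name: str) -> ReportRow:
        for r in self.rows:
            if r.method == method and r.bin_name == bin_name:
                return r
        raise KeyError((method, bin_name))

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "method": r.method,
                    "bin": r.bin_name,
                    "n_classes": r.n_classes,
                    "per_run_f1": ",".join(f"{v:.4f}" for v in r.per_run_f1),
                    "per_run_mrr": ",".join(f"{v:.4f}" for v in r.per_run_mrr),
                    "mean_f1": r.mean_f1,
                    "mean_mrr": r.mean_mrr,
                    "p_f1": r.p_f1,
                    "p_mrr": r.p_mrr,
                }
                for r in self.rows
            ]
        )

    def to_tsv(self) -> str:
        def fmt(v):
            return "" if v is None else f"{v:.6f}"

        lines = [
            "method\tbin\tn_classes\tper_run_f1\tper_run_mrr\t"
            "mean_f1\tmean_mrr\tp_f1\tp_mrr"
        ]
        for r in self.rows:
            lines.append(
                "\t".join(
                    [
                        r.method,
                        r.bin_name,
                        str(r.n_classes),
                        ",".join(f"{v:.6f}" for v in r.per_run_f1),
                        ",".join(f"{v:.6f}" for v in r.per_run_mrr),
                        fmt(r.mean_f1),
                        fmt(r.mean_mrr),
                        fmt(r.p_f1),
                        fmt(r.p_mrr),
                    ]
                )
            )
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        import json

        return json.dumps(
            {
                "runs": self.runs,
                "base_seed": self.base_seed,
                "baseline": self.baseline,
                "rows": [
                    {
                        "method": r.method,
                        "bin": r.bin_name,
                        "n_classes": r.n_classes,
                        "per_run_f1": [round(v, 6) for v in r.per_run_f1],
                        "per_run_mrr": [round(v, 6) for v in r.per_run_mrr],
                        "mean_f1": None if r.mean_f1 is None else round(r.mean_f1, 6),
                        "mean_mrr": None if r.mean_mrr is None else round(r.mean_mrr, 6),
                        "p_f1": None if r.p_f1 is None else round(r.p_f1, 6),
                        "p_mrr": None if r.p_mrr is None else round(r.p_mrr, 6),
                    }
                    for r in self.rows
                ],
            },
            indent=1,
        )


def run_experiment(
    corpus: LabeledCorpus,
    store: KnowledgeGraphStore,
    methods: Sequence[str],
    runs: int = 10,
    base_seed: int = 0,
    baseline: str = "bow",
    *,
    medical_categories: Iterable[str] = ("disease", "medicine", "symptom"),
    stopwords: Iterable[str] = (),
    C: float = 1.0,
    train_fraction: float = 0.8,
    bin_edges: Sequence[float] = DEFAULT_BIN_EDGES,
    rand_rounds: int = 2000,
    top_n: int = 20,
    specificity_fraction: float = 0.0001,
    pseudo_k: int = 1,
) -> BinnedReport:
    """Compare methods over several per-class train/test splits.

    For each run the corpus is re-split per class (seed = base_seed +
    run), knowledge features are re-assembled from that run's training
    split (K2 depends on the training documents), every method is
    trained on all classes and scored per rarity bin. Bins are computed
    once on the full corpus. A pooled rare-classes row (prevalence
    <= 0.1%) is reported in addition to the five bins. Significance per
    (method, bin, metric) is a paired randomization test against the
    baseline on the per-document outcomes pooled over runs
    (``rand_rounds=0`` skips significance testing entirely).
    """
    if runs < 1:
        raise ValueError("runs must be >= 1")
    methods = [canonical_method(m) for m in methods]
    baseline = canonical_method(baseline)
    if baseline not in methods:
        methods = [baseline] + methods
    binning = compute_rarity_bins(corpus, bin_edges)
    counts = corpus.class_counts
    # Bins of *testable* classes (>= 2 documents, so both split sides see them).
    bin_sets: dict[str, frozenset[str]] = {}
    for i in range(binning.n_bins):
        bin_sets[binning.bin_name(i)] = frozenset(
            l for l in binning.labels_in_bin(i) if counts[l] >= 2
        )
    bin_sets[RARE_BIN] = frozenset(
        l for l in binning.rare_labels() if counts[l] >= 2
    )

    # pooled per-document outcomes across runs, for significance testing
    pooled_preds: dict[str, list[np.ndarray]] = {m: [] for m in methods}
    pooled_rr: dict[str, list[np.ndarray]] = {m: [] for m in methods}
    pooled_truths: list[np.ndarray] = []
    per_run: dict[tuple[str, str], dict[str, list[float]]] = {
        (m, b): {"f1": [], "mrr": []} for m in methods for b in bin_sets
    }
    classes_ref: tuple[str, ...] | None = None

    for r in range(runs):
        split = per_class_split(corpus, train_fraction, base_seed + r)
        results = _run_methods_once(
            split.train,
            split.test,
            store,
            methods,
            medical_categories=medical_categories,
            stopwords=stopwords,
            C=C,
            seed=base_seed + r,
            top_n=top_n,
            specificity_fraction=specificity_fraction,
            pseudo_k=pseudo_k,
        )
        classes = next(iter(results.values()))[2]
        if classes_ref is None:
            classes_ref = classes
        class_index = {c: i for i, c in enumerate(classes)}
        truth_idx = np.array(
            [class_index[d.label] for d in split.test.documents], dtype=np.intp
        )
        pooled_truths.append(truth_idx)
        for m in methods:
            top, true_rank, _ = results[m]
            pooled_preds[m].append(top)
            pooled_rr[m].append(1.0 / true_rank)
            for bname, bset in bin_sets.items():
                if not bset:
                    continue
                subset_idx = np.array(
                    sorted(class_index[c] for c in bset), dtype=np.intp
                )
                f1 = _macro_f1_encoded(top, truth_idx, subset_idx, len(classes))
                in_bin = np.isin(truth_idx, subset_idx)
                mrr = float((1.0 / true_rank[in_bin]).mean()) if in_bin.any() else None
                per_run[(m, bname)]["f1"].append(100.0 * f1)
                if mrr is not None:
                    per_run[(m, bname)]["mrr"].append(100.0 * mrr)

    assert classes_ref is not None
    class_index = {c: i for i, c in enumerate(classes_ref)}
    truths_all = np.concatenate(pooled_truths)
    rows: list[ReportRow] = []
    bin_order = [binning.bin_name(i) for i in range(binning.n_bins)] + [RARE_BIN]
    for m in methods:
        preds_all = np.concatenate(pooled_preds[m])
        rr_all = np.concatenate(pooled_rr[m])
        for bname in bin_order:
            bset = bin_sets[bname]
            vals = per_run[(m, bname)]
            p_f1 = p_mrr = None
            if bset and m != baseline and rand_rounds > 0:
                subset_idx = np.array(
                    sorted(class_index[c] for c in bset), dtype=np.intp
                )
                base_preds = np.concatenate(pooled_preds[baseline])
                p_f1 = randomization_test(
                    preds_all,
                    base_preds,
                    lambda p: _macro_f1_encoded(
                        np.asarray(p), truths_all, subset_idx, len(classes_ref)
                    ),
                    rounds=rand_rounds,
                    seed=base_seed,
                )
                in_bin = np.isin(truths_all, subset_idx)
                if in_bin.any():
                    p_mrr = randomization_test(
                        rr_all[in_bin],
                        np.concatenate(pooled_rr[baseline])[in_bin],
                        lambda x: float(np.mean(x)),
                        rounds=rand_rounds,
                        seed=base_seed,
                    )
            rows.append(
                ReportRow(
                    method=m,
                    bin_name=bname,
                    n_classes=len(bset),
                    per_run_f1=tuple(vals["f1"]),
                    per_run_mrr=tuple(vals["mrr"]),
                    mean_f1=float(np.mean(vals["f1"])) if vals["f1"] else None,
                    mean_mrr=float(np.mean(vals["mrr"])) if vals["mrr"] else None,
                    p_f1=p_f1,
                    p_mrr=p_mrr,
                )
            )
    return BinnedReport(tuple(rows), runs, base_seed, baseline)
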