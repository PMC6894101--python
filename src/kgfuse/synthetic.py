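"""Seeded generator of Zipf-skewed corpora and companion knowledge graphs.

The real corpora this package targets — tens of thousands of short
symptom narratives over hundreds of diagnoses, with a handful of common
diagnoses and a long tail of rare ones — are proprietary. This module
generates an offline stand-in with the same statistical shape:

* class sizes follow a Zipf law (rank ``r`` gets mass ``r^-s``), so the
  default benchmark populates every prevalence bin including the three
  rare ones (<= 0.1%);
* each document is a short bag of tokens, a ``signal_rate`` fraction
  drawn from the class's private signal vocabulary and the rest from a
  shared background vocabulary;
* the companion knowledge graph is deliberately *imperfect*: only a
  ``kg_coverage`` fraction of classes gets an entity whose alias equals
  the class name, each such entity's attribute text contains only a
  ``kg_signal_recall`` fraction of the class's signal words plus
  ``kg_noise_words`` background distractors, uncovered classes get a
  "related condition" entity reachable only through the surrogate path,
  and one non-medical alias collision exercises the category filter.

Signal vocabularies are class-exclusive. Real symptom vocabulary
overlaps across diseases; exclusivity is a deliberate simplification
that makes ground truth unambiguous for recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .corpus import LabeledCorpus, preprocess_corpus, save_corpus_jsonl
from .kg import KGEntity, KnowledgeGraphStore, save_kg_json

__all__ = [
    "SyntheticSpec",
    "MEDICAL_CATEGORIES",
    "zipf_class_counts",
    "generate_corpus",
    "generate_kg",
    "generate_benchmark",
]

#: Category whitelist used by entity resolution on synthetic graphs.
MEDICAL_CATEGORIES = frozenset({"disease", "medicine", "symptom"})


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic benchmark.

    Defaults are the study conditions of the package's built-in
    benchmark: 60 classes over 8,000 short documents (mean 28 tokens,
    ±20% jitter), Zipf exponent 2.0 so that every prevalence bin holds
    at least three classes, 30% of tokens carrying class signal, and a
    knowledge graph covering ~90% of classes with 90% signal recall and
    5 distractor words per entity.
    """

    n_classes: int = 60
    zipf_exponent: float = 2.0
    n_docs: int = 8000
    signal_vocab_per_class: int = 10
    background_vocab: int = 2000
    doc_length: int = 28
    signal_rate: float = 0.3
    kg_coverage: float = 0.9
    kg_signal_recall: float = 0.9
    kg_noise_words: int = 5
    n_irrelevant_entities: int = 20
    seed: int = 0

    def __post_init__(self):
        for name in ("signal_rate", "kg_coverage", "kg_signal_recall"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.n_docs < self.n_classes:
            raise ValueError("n_docs must be >= n_classes")
        if self.zipf_exponent <= 0:
            raise ValueError("zipf_exponent must be positive")


def zipf_class_counts(n_classes: int, exponent: float, n_docs: int) -> np.ndarray:
    """Integer class sizes ∝ rank^-exponent, summing exactly to n_docs.

    Largest-remainder apportionment with a floor of one document per
    class; the result is sorted so counts are monotone non-increasing
    in rank.
    """
    if n_docs < n_classes:
        raise ValueError("n_docs must be >= n_classes")
    r = np.arange(1, n_classes + 1, dtype=float)
    w = r ** (-exponent)
    raw = n_docs * w / w.sum()
    counts = np.maximum(1, np.floor(raw)).astype(np.int64)
    remainder = raw - np.floor(raw)
    deficit = int(n_docs - counts.sum())
    order = np.lexsort((np.arange(n_classes), -remainder))
    i = 0
    while deficit > 0:
        counts[order[i % n_classes]] += 1
        deficit -= 1
        i += 1
    while deficit < 0:
        j = int(np.argmax(counts))
        counts[j] -= 1
        deficit += 1
    return np.sort(counts)[::-1]


def _labels(spec: SyntheticSpec) -> list[str]:
    return [f"disease_{r:03d}" for r in range(spec.n_classes)]


def _signal_vocab(spec: SyntheticSpec) -> dict[str, list[str]]:
    return {
        label: [
            f"sig{r:03d}w{j:02d}" for j in range(spec.signal_vocab_per_class)
        ]
        for r, label in enumerate(_labels(spec))
    }


def generate_corpus(
    spec: SyntheticSpec,
) -> tuple[LabeledCorpus, dict[str, frozenset[str]]]:
    """Generate the labeled corpus and the ground-truth signal words.

    Class ``r`` (0-based rank) receives a Zipf share of the documents;
    each document draws ``doc_length`` (±20%) tokens, each token coming
    from the class's signal vocabulary with probability ``signal_rate``
    and from the shared background vocabulary otherwise. Fully
    reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    labels = _labels(spec)
    signal = _signal_vocab(spec)
    background = [f"bg{j:04d}" for j in range(spec.background_vocab)]
    counts = zipf_class_counts(spec.n_classes, spec.zipf_exponent, spec.n_docs)
    records = []
    doc_no = 0
    for label, count in zip(labels, counts):
        sig = signal[label]
        for _ in range(int(count)):
            length = max(
                1, int(round(spec.doc_length * rng.uniform(0.8, 1.2)))
            )
            is_signal = rng.random(length) < spec.signal_rate
            tokens = [
                sig[rng.integers(len(sig))]
                if s
                else background[rng.integers(len(background))]
                for s in is_signal
            ]
            records.append((f"doc_{doc_no:05d}", " ".join(tokens), label))
            doc_no += 1
    corpus = preprocess_corpus(records)
    return corpus, {l: frozenset(signal[l]) for l in labels}


def generate_kg(
    spec: SyntheticSpec,
    ground_truth: dict[str, frozenset[str]],
    labels: list[str] | None = None,
) -> KnowledgeGraphStore:
    """Generate the imperfect companion knowledge graph.

    The first ``floor(kg_coverage * n_classes)`` classes by rank get a
    matched-name medical entity whose attributes hold a
    ``kg_signal_recall`` fraction of the class's signal words plus
    ``kg_noise_words`` background distractors. Every *uncovered* class
    gets a "related condition" entity with the same attribute recipe
    but a non-matching alias, so it is reachable only through the
    surrogate path. Irrelevant non-medical entities are added, one of
    which shares an alias with the most common class but lacks a
    medical category (the classic ambiguous-name case the category
    filter must reject).
    """
    labels = list(labels) if labels is not None else sorted(ground_truth)
    missing = set(labels) - set(ground_truth)
    if missing:
        raise ValueError(f"ground_truth missing labels: {sorted(missing)}")
    rng = np.random.default_rng(spec.seed + 1)
    background = [f"bg{j:04d}" for j in range(spec.background_vocab)]
    n_covered = int(np.floor(spec.kg_coverage * len(labels)))
    entities: list[KGEntity] = []

    def attribute_text(label: str) -> str:
        sig = sorted(ground_truth[label])
        k = int(round(spec.kg_signal_recall * len(sig)))
        kept = [sig[i] for i in sorted(rng.permutation(len(sig))[:k].tolist())]
        noise = [
            background[rng.integers(len(background))]
            for _ in range(spec.kg_noise_words)
        ]
        return " ".join(kept + noise)

    for r, label in enumerate(labels):
        if r < n_covered:
            entities.append(
                KGEntity(
                    entity_id=f"E{r:04d}",
                    canonical_name=label,
                    aliases=frozenset({label}),
                    categories=frozenset({"disease"}),
                    attributes={"overview": attribute_text(label)},
                    related_entities=frozenset(
                        {labels[(r + 1) % n_covered]} if n_covered > 1 else set()
                    ),
                )
            )
        else:
            # Reachable only by content overlap: alias differs from label.
            entities.append(
                KGEntity(
                    entity_id=f"S{r:04d}",
                    canonical_name=f"condition related to {label}",
                    aliases=frozenset({f"condition related to {label}"}),
                    categories=frozenset({"medicine"}),
                    attributes={"indication": attribute_text(label)},
                    related_entities=frozenset(),
                )
            )
    for j in range(spec.n_irrelevant_entities):
        words = " ".join(
            background[rng.integers(len(background))] for _ in range(8)
        )
        entities.append(
            KGEntity(
                entity_id=f"X{j:04d}",
                canonical_name=f"irrelevant_{j:03d}",
                aliases=frozenset({f"irrelevant_{j:03d}"}),
                categories=frozenset({"music", "geography"}),
                attributes={"text": words},
                related_entities=frozenset(),
            )
        )
    # Ambiguous alias: shares the most common class's name, not medical.
    entities.append(
        KGEntity(
            entity_id="X_collision",
            canonical_name=labels[0],
            aliases=frozenset({labels[0]}),
            categories=frozenset({"music"}),
            attributes={"text": "a popular song"},
            related_entities=frozenset(),
        )
    )
    return KnowledgeGraphStore(tuple(entities))


def generate_benchmark(
    spec: SyntheticSpec, out_dir: str | Path | None = None
) -> tuple[LabeledCorpus, KnowledgeGraphStore, dict[str, frozenset[str]]]:
    """Corpus + KG + ground truth from one seed; optionally write to disk.

    When ``out_dir`` is given, writes ``corpus.jsonl``, ``kg.json`` and
    ``manifest.json`` (the spec, so the benchmark can be regenerated
    bit-for-bit from the manifest alone).
    """
    corpus, ground_truth = generate_corpus(spec)
    store = generate_kg(spec, ground_truth, _labels(spec))
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        save_corpus_jsonl(corpus, out / "corpus.jsonl")
        save_kg_json(store, out / "kg.json")
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump({"synthetic_spec": asdict(spec)}, fh, indent=1)
    return corpus, store, ground_truth


def spec_from_manifest(path: str | Path) -> SyntheticSpec:
    """Reload a SyntheticSpec from a benchmark manifest."""
    with open(path, "r", encoding="utf-8") as fh:
        payload = json.load(fh)
    return SyntheticSpec(**payload["synthetic_spec"])
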