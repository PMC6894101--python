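"""Corpus ingestion, tokenization, rarity binning, and per-class splitting.

A corpus here is a set of short clinical narratives (one document per
patient record), each carrying exactly one class label (a diagnosis).
Class prevalence is typically extremely skewed: a handful of common
diagnoses account for most records while the long tail holds classes
with only a few documents each. Rarity binning stratifies the label set
by prevalence so that downstream metrics can be reported per rarity
level instead of being dominated by the majority classes.
"""

from __future__ import annotations

import bisect
import json
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

__all__ = [
    "TokenizedDocument",
    "LabeledCorpus",
    "RarityBinning",
    "SplitPair",
    "DEFAULT_BIN_EDGES",
    "default_tokenizer",
    "preprocess_corpus",
    "compute_rarity_bins",
    "per_class_split",
    "load_corpus_jsonl",
    "save_corpus_jsonl",
    "load_stopwords",
]

#: Prevalence bin edges as corpus fractions. The three lowest bins
#: (<=0.1%) are the "rare" classes; the two higher bins are reported
#: for comparison. Intervals are left-open right-closed.
DEFAULT_BIN_EDGES: tuple[float, ...] = (0.0002, 0.0005, 0.001, 0.005, 0.01)

#: Human-readable names for the default bins, in order.
DEFAULT_BIN_NAMES: tuple[str, ...] = (
    "(0, 0.02%]",
    "(0.02%, 0.05%]",
    "(0.05%, 0.1%]",
    "(0.1%, 0.5%]",
    "(0.5%, 1%]",
)

_TOKEN_RE = re.compile(r"[^\W_]+", re.UNICODE)


def default_tokenizer(text: str) -> list[str]:
    """Lowercase and split on punctuation/whitespace boundaries.

    Language-agnostic fallback. For languages without whitespace word
    boundaries (e.g. Chinese), inject a proper segmenter instead; every
    function in this package that tokenizes accepts a ``tokenizer``
    callable with this signature.
    """
    return _TOKEN_RE.findall(text.lower())


@dataclass(frozen=True)
class TokenizedDocument:
    """A single record: id, raw text, stop-word-free tokens, one label."""

    doc_id: str
    raw_text: str
    tokens: tuple[str, ...]
    label: str

    @property
    def token_set(self) -> frozenset[str]:
        return frozenset(self.tokens)


@dataclass(frozen=True)
class LabeledCorpus:
    """An immutable collection of labeled tokenized documents."""

    documents: tuple[TokenizedDocument, ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for doc in self.documents:
            if doc.doc_id in seen:
                raise ValueError(f"duplicate doc_id: {doc.doc_id!r}")
            seen.add(doc.doc_id)

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self):
        return iter(self.documents)

    @property
    def labels(self) -> frozenset[str]:
        return frozenset(d.label for d in self.documents)

    @property
    def class_counts(self) -> Counter:
        return Counter(d.label for d in self.documents)

    def documents_of(self, label: str) -> tuple[TokenizedDocument, ...]:
        return tuple(d for d in self.documents if d.label == label)

    def by_label(self) -> dict[str, list[TokenizedDocument]]:
        out: dict[str, list[TokenizedDocument]] = {}
        for d in self.documents:
            out.setdefault(d.label, []).append(d)
        return out


def preprocess_corpus(
    records: Iterable[tuple[str, str, str]],
    stopwords: Iterable[str] = (),
    tokenizer: Callable[[str], list[str]] = default_tokenizer,
) -> LabeledCorpus:
    """Tokenize raw ``(id, text, label)`` records into a LabeledCorpus.

    Stop words are removed after tokenization; token multiplicity is
    otherwise preserved (term frequencies are needed downstream, set
    semantics are applied only where membership is what matters).

    Raises ``ValueError`` on a duplicate id (naming it) or an empty label.
    """
    stop = frozenset(stopwords)
    docs: list[TokenizedDocument] = []
    seen: set[str] = set()
    for doc_id, text, label in records:
        if doc_id in seen:
            raise ValueError(f"duplicate doc_id: {doc_id!r}")
        seen.add(doc_id)
        if not label:
            raise ValueError(f"empty label for document {doc_id!r}")
        tokens = tuple(t for t in tokenizer(text) if t not in stop)
        docs.append(TokenizedDocument(doc_id, text, tokens, label))
    return LabeledCorpus(tuple(docs))


@dataclass(frozen=True)
class RarityBinning:
    """Assignment of each label to a prevalence bin.

    ``assignment[label]`` is a 0-based bin index, or ``None`` when the
    label's corpus fraction exceeds the last edge ("unbinned"). A label
    with fraction ``f`` falls in the first bin whose left-open
    right-closed interval ``(lo, hi]`` contains ``f``.
    """

    corpus_size: int
    bin_edges: tuple[float, ...]
    assignment: Mapping[str, int | None]

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges)

    def labels_in_bin(self, index: int) -> frozenset[str]:
        return frozenset(l for l, b in self.assignment.items() if b == index)

    def rare_labels(self, max_fraction: float = 0.001) -> frozenset[str]:
        """Labels in every bin whose upper edge is <= ``max_fraction``."""
        idx = {i for i, e in enumerate(self.bin_edges) if e <= max_fraction}
        return frozenset(
            l for l, b in self.assignment.items() if b is not None and b in idx
        )

    def bin_name(self, index: int) -> str:
        if self.bin_edges == DEFAULT_BIN_EDGES:
            return DEFAULT_BIN_NAMES[index]
        lo = 0.0 if index == 0 else self.bin_edges[index - 1]
        return f"({lo:g}, {self.bin_edges[index]:g}]"


def compute_rarity_bins(
    corpus: LabeledCorpus, edges: Sequence[float] = DEFAULT_BIN_EDGES
) -> RarityBinning:
    """Bin each label by its prevalence ``class_count / corpus_size``."""
    if len(corpus) == 0:
        raise ValueError("cannot bin an empty corpus")
    edges = tuple(edges)
    if any(not (0.0 < e < 1.0) for e in edges) or list(edges) != sorted(set(edges)):
        raise ValueError("bin edges must be strictly increasing fractions in (0, 1)")
    n = len(corpus)
    assignment: dict[str, int | None] = {}
    for label, count in corpus.class_counts.items():
        f = count / n
        idx = bisect.bisect_left(edges, f)
        assignment[label] = idx if idx < len(edges) else None
    return RarityBinning(n, edges, assignment)


@dataclass(frozen=True)
class SplitPair:
    """A per-class train/test split of a corpus.

    ``untestable`` lists singleton classes (one document) that were sent
    entirely to the train side; they are excluded from per-bin test
    metrics because no test document can exist for them.
    """

    train: LabeledCorpus
    test: LabeledCorpus
    seed: int
    untestable: frozenset[str] = field(default_factory=frozenset)


def per_class_split(
    corpus: LabeledCorpus, train_fraction: float = 0.8, seed: int = 0
) -> SplitPair:
    """Randomly split each class so both sides see every splittable class.

    Within a class of size ``n``, ``round(train_fraction * n)`` documents
    (round-half-up) go to train, clipped so that train >= 1 and test >= 1
    whenever ``n >= 2``. Classes with a single document go entirely to
    train and are flagged untestable. Deterministic for a fixed seed.
    """
    import numpy as np

    if len(corpus) == 0:
        raise ValueError("cannot split an empty corpus")
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train: list[TokenizedDocument] = []
    test: list[TokenizedDocument] = []
    untestable: set[str] = set()
    grouped = corpus.by_label()
    for label in sorted(grouped):
        docs = sorted(grouped[label], key=lambda d: d.doc_id)
        n = len(docs)
        if n == 1:
            train.extend(docs)
            untestable.add(label)
            continue
        n_train = int(np.floor(train_fraction * n + 0.5))
        n_train = min(max(n_train, 1), n - 1)
        perm = rng.permutation(n)
        chosen = set(perm[:n_train].tolist())
        for i, d in enumerate(docs):
            (train if i in chosen else test).append(d)
    return SplitPair(
        LabeledCorpus(tuple(train)), LabeledCorpus(tuple(test)), seed,
        frozenset(untestable),
    )


# ---------------------------------------------------------------------------
# File formats: JSON Lines corpus, plain-text stop-word list.

def load_corpus_jsonl(
    path,
    stopwords: Iterable[str] = (),
    tokenizer: Callable[[str], list[str]] = default_tokenizer,
) -> LabeledCorpus:
    """Read a JSONL corpus (keys: id, text, label) and preprocess it."""
    records = []
    with open(path, "r", encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            obj = json.loads(line)
            try:
                records.append((obj["id"], obj["text"], obj["label"]))
            except KeyError as exc:
                raise ValueError(
                    f"{path}:{line_no}: missing corpus key {exc}"
                ) from None
    return preprocess_corpus(records, stopwords, tokenizer)


def save_corpus_jsonl(corpus: LabeledCorpus, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for d in corpus.documents:
            fh.write(
                json.dumps(
                    {"id": d.doc_id, "text": d.raw_text, "label": d.label},
                    ensure_ascii=False,
                )
                + "\n"
            )


def load_stopwords(path) -> frozenset[str]:
    """Read a stop-word list: one token per line, UTF-8, blank lines ignored."""
    with open(path, "r", encoding="utf-8") as fh:
        return frozenset(w.strip() for w in fh if w.strip())
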