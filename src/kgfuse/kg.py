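"""Offline knowledge-graph store, entity resolution, and knowledge terms.

A knowledge graph snapshot is a flat list of entities, each with a
canonical name, surface-form aliases, categories, free-text attributes
and related-entity names. Disease classes are linked to entities in two
ways:

* **matched entity** — exact (case/width-normalized) alias lookup of the
  class name, disambiguated by requiring at least one whitelisted
  medical category (an ambiguous name like "insomnia" may also hit,
  say, a song entity; the category filter discards it);
* **surrogate entity** — when no alias matches, the entity with the
  highest content-word overlap with the class's profile of high-idf
  words, a deliberate fallback for incomplete graphs.

From the linked entities two word sets are harvested:

* ``K1`` — all attribute-text tokens and related-entity-name tokens of
  matched entities (trusted, may contain words outside the training
  vocabulary V);
* ``K2`` — for surrogate entities, only words that occur in a training
  document of the class AND occur in at most a small fraction of all KG
  entities (a specificity cap in the spirit of inverse document
  frequency — surrogate attributes are likely off-topic, so only
  class-co-occurring, KG-specific words survive). By construction
  K2 ⊆ V.

The union K = K1 ∪ K2 is the knowledge-term set consumed by the
featurizer.
"""

from __future__ import annotations

import json
import math
import unicodedata
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

from .corpus import LabeledCorpus, TokenizedDocument, default_tokenizer
from .features import document_frequencies

__all__ = [
    "KGEntity",
    "KnowledgeGraphStore",
    "DiseaseEntityMap",
    "KnowledgeFeatureSet",
    "normalize_surface",
    "resolve_matched_entity",
    "build_disease_profile",
    "select_surrogate_entity",
    "extract_k1",
    "extract_k2",
    "assemble_knowledge_features",
    "load_kg_json",
    "save_kg_json",
]


def normalize_surface(name: str) -> str:
    """Casefold + NFKC width normalization for alias lookup."""
    return unicodedata.normalize("NFKC", name).casefold().strip()


@dataclass(frozen=True)
class KGEntity:
    entity_id: str
    canonical_name: str
    aliases: frozenset[str]
    categories: frozenset[str]
    attributes: Mapping[str, str]
    related_entities: frozenset[str]

    def __post_init__(self):
        if self.canonical_name not in self.aliases:
            object.__setattr__(
                self, "aliases", self.aliases | {self.canonical_name}
            )


@dataclass
class KnowledgeGraphStore:
    """Indexed snapshot: alias lookup plus a word → entity-df index.

    ``word_entity_df[w]`` counts entities whose content (attribute
    texts, aliases, related-entity names — all tokenized with the
    corpus tokenizer, stop words removed) contains ``w``.
    """

    entities: tuple[KGEntity, ...]
    tokenizer: Callable[[str], list[str]] = default_tokenizer
    stopwords: frozenset[str] = frozenset()
    alias_index: dict[str, frozenset[str]] = field(init=False)
    word_entity_df: Counter = field(init=False)
    _by_id: dict[str, KGEntity] = field(init=False)
    _content_words: dict[str, frozenset[str]] = field(init=False)
    _knowledge_words: dict[str, frozenset[str]] = field(init=False)

    def __post_init__(self):
        self._by_id = {}
        for e in self.entities:
            if e.entity_id in self._by_id:
                raise ValueError(f"duplicate entity_id: {e.entity_id!r}")
            self._by_id[e.entity_id] = e
        alias_index: dict[str, set[str]] = {}
        for e in self.entities:
            for a in e.aliases:
                alias_index.setdefault(normalize_surface(a), set()).add(e.entity_id)
        self.alias_index = {k: frozenset(v) for k, v in alias_index.items()}
        self._content_words = {}
        self._knowledge_words = {}
        self.word_entity_df = Counter()
        for e in self.entities:
            attr = self._tokens(" ".join(e.attributes.values()))
            related = self._tokens(" ".join(sorted(e.related_entities)))
            aliases = self._tokens(" ".join(sorted(e.aliases)))
            self._knowledge_words[e.entity_id] = frozenset(attr | related)
            content = frozenset(attr | related | aliases)
            self._content_words[e.entity_id] = content
            self.word_entity_df.update(content)

    def _tokens(self, text: str) -> set[str]:
        return {t for t in self.tokenizer(text) if t not in self.stopwords}

    def __len__(self) -> int:
        return len(self.entities)

    def get(self, entity_id: str) -> KGEntity:
        try:
            return self._by_id[entity_id]
        except KeyError:
            raise KeyError(f"unknown entity_id: {entity_id!r}") from None

    def content_words(self, entity_id: str) -> frozenset[str]:
        """Words representing an entity for overlap scoring."""
        self.get(entity_id)
        return self._content_words[entity_id]

    def knowledge_words(self, entity_id: str) -> frozenset[str]:
        """Attribute-text and related-entity-name tokens (K1 source)."""
        self.get(entity_id)
        return self._knowledge_words[entity_id]


@dataclass(frozen=True)
class DiseaseEntityMap:
    """Per-label link: (entity_id or None, kind ∈ {matched, surrogate, none})."""

    mapping: Mapping[str, tuple[str | None, str]]

    def of_kind(self, kind: str) -> dict[str, str]:
        return {
            l: eid for l, (eid, k) in self.mapping.items() if k == kind and eid
        }


@dataclass(frozen=True)
class KnowledgeFeatureSet:
    """K1 (matched entities), K2 (surrogate entities), and K = K1 ∪ K2."""

    k1: frozenset[str]
    k2: frozenset[str]
    per_disease: Mapping[str, frozenset[str]]

    @property
    def k(self) -> frozenset[str]:
        return self.k1 | self.k2


def resolve_matched_entity(
    disease_name: str,
    store: KnowledgeGraphStore,
    medical_categories: Iterable[str],
) -> str | None:
    """Exact alias lookup filtered to medical entities.

    Candidates lacking any whitelisted category are discarded; among the
    survivors the entity with the most medical categories wins, ties
    broken by lexicographic entity_id. Returns None when nothing survives.
    """
    if not disease_name or not disease_name.strip():
        raise ValueError("disease name must be non-empty")
    medical = frozenset(medical_categories)
    candidates = store.alias_index.get(normalize_surface(disease_name), frozenset())
    survivors = [
        eid for eid in candidates if store.get(eid).categories & medical
    ]
    if not survivors:
        return None
    return min(
        survivors, key=lambda eid: (-len(store.get(eid).categories & medical), eid)
    )


def build_disease_profile(
    label: str,
    train_docs: Sequence[TokenizedDocument],
    idf: Mapping[str, float],
    top_n: int = 20,
) -> frozenset[str]:
    """The class's top-n distinct words by idf (its high-specificity profile).

    Ranking: idf descending, then total in-class count descending, then
    lexicographic. Words missing from ``idf`` are ignored.
    """
    if not train_docs:
        raise ValueError(f"class {label!r} has no training documents")
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    counts: Counter = Counter()
    for d in train_docs:
        counts.update(t for t in d.tokens if t in idf)
    ranked = sorted(counts, key=lambda w: (-idf[w], -counts[w], w))
    return frozenset(ranked[:top_n])


def select_surrogate_entity(
    profile: Iterable[str], store: KnowledgeGraphStore
) -> str | None:
    """Entity with the largest content-word overlap with the profile.

    Ties broken by lexicographic entity_id; None when the store is empty.
    """
    profile = frozenset(profile)
    if not profile:
        raise ValueError("profile must be non-empty")
    if len(store) == 0:
        return None
    return min(
        (e.entity_id for e in store.entities),
        key=lambda eid: (-len(profile & store.content_words(eid)), eid),
    )


def extract_k1(
    matched: Mapping[str, str],
    store: KnowledgeGraphStore,
    stopwords: Iterable[str] = (),
) -> tuple[frozenset[str], dict[str, frozenset[str]]]:
    """Union of attribute-text and related-entity-name tokens over matched
    entities; returns (K1, per-disease contributions)."""
    stop = frozenset(stopwords)
    per_disease: dict[str, frozenset[str]] = {}
    k1: set[str] = set()
    for label in sorted(matched):
        eid = matched[label]
        if eid not in store._by_id:
            raise KeyError(f"dangling entity_id {eid!r} for class {label!r}")
        words = frozenset(w for w in store.knowledge_words(eid) if w not in stop)
        per_disease[label] = words
        k1 |= words
    return frozenset(k1), per_disease


def specificity_cap(store_size: int, specificity_fraction: float) -> int:
    """Max entity-df for a word to count as KG-specific: max(1, ⌊f·|E|⌋)."""
    return max(1, math.floor(specificity_fraction * store_size))


def extract_k2(
    label: str,
    surrogate: str,
    train_docs: Sequence[TokenizedDocument],
    store: KnowledgeGraphStore,
    specificity_fraction: float = 0.0001,
) -> frozenset[str]:
    """Surrogate-entity words that are both class-attested and KG-specific.

    A word survives iff it (i) is a content word of the surrogate entity,
    (ii) occurs in at least one training document of the class, and
    (iii) occurs in at most ``max(1, floor(specificity_fraction·|E|))``
    KG entities. (ii) guarantees K2 ⊆ V.
    """
    if not train_docs:
        raise ValueError(f"class {label!r} has no training documents")
    cap = specificity_cap(len(store), specificity_fraction)
    class_words = set()
    for d in train_docs:
        class_words |= d.token_set
    return frozenset(
        w
        for w in store.content_words(surrogate)
        if w in class_words and store.word_entity_df[w] <= cap
    )


def assemble_knowledge_features(
    train: LabeledCorpus,
    store: KnowledgeGraphStore,
    medical_categories: Iterable[str],
    top_n: int = 20,
    specificity_fraction: float = 0.0001,
    stopwords: Iterable[str] = (),
) -> tuple[DiseaseEntityMap, KnowledgeFeatureSet]:
    """Link every training class to a KG entity and harvest K1/K2.

    For each label: try a matched entity; otherwise build the class's
    high-idf profile and pick a surrogate by content overlap (kind
    ``none`` only when the store has no candidates at all). K1 is
    accumulated over matched classes, K2 over surrogate classes.
    """
    if len(train) == 0:
        raise ValueError("empty training corpus")
    n = len(train)
    df = document_frequencies(train)
    idf = {t: math.log(n / c) + 1.0 for t, c in df.items()}
    grouped = train.by_label()
    mapping: dict[str, tuple[str | None, str]] = {}
    for label in sorted(grouped):
        try:
            eid = resolve_matched_entity(label, store, medical_categories)
            if eid is not None:
                mapping[label] = (eid, "matched")
                continue
            profile = build_disease_profile(label, grouped[label], idf, top_n)
            sid = select_surrogate_entity(profile, store)
            mapping[label] = (sid, "surrogate") if sid else (None, "none")
        except (ValueError, KeyError) as exc:
            raise type(exc)(f"class {label!r}: {exc}") from exc

    entity_map = DiseaseEntityMap(mapping)
    k1, per_disease = extract_k1(entity_map.of_kind("matched"), store, stopwords)
    k2: set[str] = set()
    for label, sid in sorted(entity_map.of_kind("surrogate").items()):
        words = extract_k2(
            label, sid, grouped[label], store, specificity_fraction
        )
        per_disease[label] = words
        k2 |= words
    for label, (eid, kind) in mapping.items():
        per_disease.setdefault(label, frozenset())
    return entity_map, KnowledgeFeatureSet(k1, frozenset(k2), per_disease)


# ---------------------------------------------------------------------------
# Snapshot format: JSON array of
# {id, name, aliases: [...], categories: [...], attributes: {name: text},
#  related: [...]}.

def load_kg_json(
    path,
    tokenizer: Callable[[str], list[str]] = default_tokenizer,
    stopwords: Iterable[str] = (),
) -> KnowledgeGraphStore:
    with open(path, "r", encoding="utf-8") as fh:
        raw = json.load(fh)
    if not isinstance(raw, list):
        raise ValueError("KG snapshot must be a JSON array of entity objects")
    entities = []
    for i, obj in enumerate(raw):
        missing = {"id", "name"} - obj.keys()
        if missing:
            raise ValueError(f"entity #{i}: missing keys {sorted(missing)}")
        entities.append(
            KGEntity(
                entity_id=obj["id"],
                canonical_name=obj["name"],
                aliases=frozenset(obj.get("aliases", [])),
                categories=frozenset(obj.get("categories", [])),
                attributes=dict(obj.get("attributes", {})),
                related_entities=frozenset(obj.get("related", [])),
            )
        )
    return KnowledgeGraphStore(
        tuple(entities), tokenizer=tokenizer, stopwords=frozenset(stopwords)
    )


def save_kg_json(store: KnowledgeGraphStore, path) -> None:
    payload = [
        {
            "id": e.entity_id,
            "name": e.canonical_name,
            "aliases": sorted(e.aliases),
            "categories": sorted(e.categories),
            "attributes": dict(sorted(e.attributes.items())),
            "related": sorted(e.related_entities),
        }
        for e in store.entities
    ]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, ensure_ascii=False, indent=1)
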