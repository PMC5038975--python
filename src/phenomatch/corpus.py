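"""Annotation corpora and the frequency / co-occurrence weighting scheme.

An :class:`AnnotationCorpus` holds the entity→term annotations of one entity
class (drugs with their side effects, or genes with their phenotypic traits)
together with the inverted term→entity index.  From it derive the two weights
that downweight frequent and co-occurring terms in the similarity score:

* frequency weight  f = -ln(k / n)  for a term annotated to k of n entities,
* co-occurrence weight  c = -ln J(A, B)  with J the Jaccard index of the two
  terms' entity sets within this corpus.

J = 0 would make c infinite; never-co-occurring pairs are instead capped at
c = -ln(1 / (|A ∪ B| + 1)), i.e. maximally-but-finitely informative, growing
only logarithmically with corpus support.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .ontology import Ontology

__all__ = [
    "AnnotationCorpus",
    "PairWeighting",
    "CorpusError",
    "UndefinedWeightError",
    "load_corpus",
]


class CorpusError(ValueError):
    """Malformed or inconsistent annotation corpus."""


class UndefinedWeightError(KeyError):
    """A weight was requested for a term not annotated in this corpus."""


@dataclass(frozen=True)
class PairWeighting:
    """Frequency and co-occurrence weight of a focal term vs. a partner."""

    f: float
    c: float

    @property
    def product(self) -> float:
        return self.f * self.c


class AnnotationCorpus:
    """Bidirectional entity↔term index for one entity class."""

    def __init__(
        self,
        annotations: Mapping[str, Iterable[str]],
        entity_class: str = "entity",
    ):
        if entity_class not in ("drug", "gene", "entity"):
            raise ValueError(f"unknown entity class: {entity_class!r}")
        self.entity_class = entity_class
        self._annotations: dict[str, frozenset[str]] = {}
        inverted: dict[str, set[str]] = {}
        for entity, terms in annotations.items():
            terms = frozenset(terms)
            if not terms:
                raise CorpusError(f"entity {entity!r} has no annotations")
            self._annotations[str(entity)] = terms
            for t in terms:
                inverted.setdefault(t, set()).add(str(entity))
        if not self._annotations:
            raise CorpusError("empty corpus")
        self._inverted: dict[str, frozenset[str]] = {
            t: frozenset(es) for t, es in inverted.items()
        }
        self._freq_cache: dict[str, float] = {}

    # -- structure ---------------------------------------------------------

    @property
    def n_entities(self) -> int:
        return len(self._annotations)

    @property
    def entities(self) -> Sequence[str]:
        return sorted(self._annotations)

    @property
    def terms(self) -> frozenset[str]:
        return frozenset(self._inverted)

    @property
    def annotations(self) -> Mapping[str, frozenset[str]]:
        return self._annotations

    def profile(self, entity_id: str) -> frozenset[str]:
        try:
            return self._annotations[entity_id]
        except KeyError:
            raise CorpusError(f"unknown entity: {entity_id!r}") from None

    def entities_with(self, term_id: str) -> frozenset[str]:
        """Entities annotated with a term (empty set if the term is unused)."""
        return self._inverted.get(term_id, frozenset())

    # -- weights -----------------------------------------------------------

    def frequency_weight(self, term_id: str) -> float:
        """f = -ln(k / n); 0 when the term annotates every entity."""
        if term_id in self._freq_cache:
            return self._freq_cache[term_id]
        k = len(self.entities_with(term_id))
        if k == 0:
            raise UndefinedWeightError(
                f"term {term_id!r} annotates no {self.entity_class} in this corpus"
            )
        f = -math.log(k / self.n_entities)
        self._freq_cache[term_id] = f
        return f

    def jaccard(self, term_a: str, term_b: str) -> float:
        a = self.entities_with(term_a)
        b = self.entities_with(term_b)
        union = len(a | b)
        if union == 0:
            return 0.0
        return len(a & b) / union

    def cooccurrence_weight(self, term_a: str, term_b: str) -> float:
        """c = -ln J(A, B), capped at -ln(1/(|A ∪ B| + 1)) when J = 0.

        ``term_a`` must be annotated here; ``term_b`` may be absent (its
        entity set is then empty, so J = 0 and the cap applies).
        """
        a = self.entities_with(term_a)
        if not a:
            raise UndefinedWeightError(
                f"term {term_a!r} annotates no {self.entity_class} in this corpus"
            )
        if term_a == term_b:
            return 0.0
        b = self.entities_with(term_b)
        union = a | b
        inter = a & b
        if inter:
            return -math.log(len(inter) / len(union))
        return -math.log(1.0 / (len(union) + 1))

    def pair_weight(self, focal: str, other: str) -> PairWeighting:
        """Frequency weight of ``focal`` times its co-occurrence with ``other``."""
        return PairWeighting(
            f=self.frequency_weight(focal),
            c=self.cooccurrence_weight(focal, other),
        )

    # -- descriptives ------------------------------------------------------

    def annotation_counts(self) -> dict[str, int]:
        return {e: len(ts) for e, ts in self._annotations.items()}

    def summary(self, quantiles: Sequence[float] = (0.25, 0.5, 0.75)) -> dict:
        """Sorted per-entity annotation counts plus requested quantiles.

        Quantiles use linear interpolation (the numpy default), matching the
        rule used for the drug burden tertiles.
        """
        counts = np.array(sorted(self.annotation_counts().values()))
        out: dict = {"counts": counts.tolist(), "n_entities": self.n_entities}
        if len(quantiles):
            qs = np.quantile(counts, list(quantiles), method="linear")
            out["quantiles"] = dict(zip([float(q) for q in quantiles], qs.tolist()))
        return out


def load_corpus(
    records: Iterable[tuple[str, str] | Mapping[str, str]],
    ontology: Ontology,
    entity_class: str = "entity",
    strict: bool = True,
) -> AnnotationCorpus:
    """Build a corpus from (entity_id, term_id) records, validated against an ontology.

    Duplicate rows are deduplicated.  Terms absent from the ontology raise a
    reference error in strict mode (default) or are dropped (a count of
    dropped rows is attached as ``corpus.n_dropped``).
    """
    annotations: dict[str, set[str]] = {}
    unknown: set[str] = set()
    n_dropped = 0
    for rec in records:
        if isinstance(rec, Mapping):
            entity, term = str(rec["entity_id"]), str(rec["term_id"])
        else:
            entity, term = str(rec[0]), str(rec[1])
        if term not in ontology:
            unknown.add(term)
            n_dropped += 1
            continue
        annotations.setdefault(entity, set()).add(term)
    if unknown and strict:
        raise CorpusError(
            "unknown ontology terms in annotations: " + ", ".join(sorted(unknown))
        )
    corpus = AnnotationCorpus(annotations, entity_class=entity_class)
    corpus.n_dropped = n_dropped  # type: ignore[attr-defined]
    return corpus
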