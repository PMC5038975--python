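"""Multi-parent phenotype ontology with intrinsic information content.

The similarity method operates on an adapted four-level, multi-parent DAG of
phenotype terms (a MedDRA-like hierarchy; cross-hierarchy SMQ-style groupings
enter simply as extra parent links).  Term specificity is measured by an
*intrinsic* information content computed from the ontology structure alone —
not from annotation frequency — so that annotation bias does not leak into
term similarity:

    IC(t) = 1 - ln(child(t) + 1) / ln(N)

where ``child(t)`` is the number of descendant terms (transitive by default)
and ``N`` the total number of terms.  A term with fewer descendants is more
specific: IC is 1 at every leaf and 0 at a root that dominates all other
terms.  The similarity of two terms is anchored at their Most Informative
Common Ancestor (MICA), the shared ancestor with maximal IC; ancestor sets
are self-inclusive so MICA(t, t) = t.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping

import networkx as nx

__all__ = [
    "TermNode",
    "MicaResult",
    "Ontology",
    "OntologyError",
    "CycleError",
    "UnknownTermError",
    "load_ontology",
]


class OntologyError(ValueError):
    """Structural problem in an ontology definition."""


class CycleError(OntologyError):
    """The parent-link graph contains a cycle."""


class UnknownTermError(KeyError):
    """A term id does not exist in the ontology."""


@dataclass(frozen=True)
class TermNode:
    """One ontology term: id, human-readable label, optional level, parents."""

    term_id: str
    label: str = ""
    level: int | None = None
    parent_ids: frozenset[str] = frozenset()


@dataclass(frozen=True)
class MicaResult:
    """Most informative common ancestor of a term pair.

    ``term_id`` is ``None`` (and ``found`` False) when the two terms share no
    ancestor, which can only happen in a forest without a common root; the
    sentinel carries ``ic_value`` 0 so downstream scores vanish.
    """

    term_id: str | None
    ic_value: float
    found: bool = True


class Ontology:
    """A validated multi-parent term DAG with cached counts and IC.

    Parameters
    ----------
    terms:
        Iterable of :class:`TermNode`.  Every parent reference must resolve
        and the parent-link graph must be acyclic.
    descendant_mode:
        ``"transitive"`` (default) counts all distinct descendants of a term;
        ``"direct"`` counts only immediate children.  The mode feeds the
        ``child(term)`` quantity inside the IC formula.
    """

    def __init__(self, terms: Iterable[TermNode], descendant_mode: str = "transitive"):
        if descendant_mode not in ("transitive", "direct"):
            raise ValueError(f"unknown descendant mode: {descendant_mode!r}")
        self.descendant_mode = descendant_mode
        self._nodes: dict[str, TermNode] = {}
        for node in terms:
            if node.term_id in self._nodes:
                raise OntologyError(f"duplicate term id: {node.term_id!r}")
            self._nodes[node.term_id] = node
        if not self._nodes:
            raise OntologyError("an ontology needs at least one term")

        # edges run child -> parent
        g = nx.DiGraph()
        g.add_nodes_from(self._nodes)
        for node in self._nodes.values():
            for pid in node.parent_ids:
                if pid not in self._nodes:
                    raise OntologyError(
                        f"term {node.term_id!r} references unknown parent {pid!r}"
                    )
                g.add_edge(node.term_id, pid)
        if not nx.is_directed_acyclic_graph(g):
            edge = nx.find_cycle(g)[0]
            raise CycleError(
                f"cycle in parent links (e.g. {edge[0]!r} -> {edge[1]!r})"
            )
        self._g = g

        self._descendants: dict[str, frozenset[str]] = {
            t: frozenset(nx.ancestors(g, t)) for t in g  # reach t via parent links
        }
        self._ancestors: dict[str, frozenset[str]] = {
            t: frozenset(nx.descendants(g, t)) | {t} for t in g  # self-inclusive
        }
        self._ic = {t: self._compute_ic(t) for t in g}
        self._check_monotone()

    # -- basic structure ---------------------------------------------------

    def __contains__(self, term_id: str) -> bool:
        return term_id in self._nodes

    def __len__(self) -> int:
        return len(self._nodes)

    @property
    def n_terms(self) -> int:
        return len(self._nodes)

    @property
    def terms(self) -> Mapping[str, TermNode]:
        return self._nodes

    @property
    def roots(self) -> frozenset[str]:
        return frozenset(t for t in self._g if self._g.out_degree(t) == 0)

    @property
    def leaves(self) -> frozenset[str]:
        return frozenset(t for t in self._g if self._g.in_degree(t) == 0)

    def _require(self, term_id: str) -> None:
        if term_id not in self._nodes:
            raise UnknownTermError(term_id)

    def parents(self, term_id: str) -> frozenset[str]:
        self._require(term_id)
        return frozenset(self._g.successors(term_id))

    def children(self, term_id: str) -> frozenset[str]:
        self._require(term_id)
        return frozenset(self._g.predecessors(term_id))

    def ancestors(self, term_id: str) -> frozenset[str]:
        """Self-inclusive ancestor set of a term."""
        self._require(term_id)
        return self._ancestors[term_id]

    def descendant_count(self, term_id: str, mode: str | None = None) -> int:
        """Number of descendants of a term (excluding the term itself)."""
        self._require(term_id)
        mode = mode or self.descendant_mode
        if mode == "transitive":
            return len(self._descendants[term_id])
        if mode == "direct":
            return self._g.in_degree(term_id)
        raise ValueError(f"unknown descendant mode: {mode!r}")

    # -- information content ----------------------------------------------

    def _compute_ic(self, term_id: str) -> float:
        n = len(self._nodes)
        if n == 1:
            warnings.warn(
                "single-term ontology: information content is degenerate, "
                "defining IC = 1",
                stacklevel=2,
            )
            return 1.0
        child = self.descendant_count(term_id)
        return 1.0 - math.log(child + 1) / math.log(n)

    def _check_monotone(self) -> None:
        for child, parent in self._g.edges:
            # descendants of the parent always include those of the child,
            # so this can only fire on an internal bookkeeping bug
            assert self._ic[child] >= self._ic[parent] - 1e-12

    def ic(self, term_id: str) -> float:
        """Intrinsic information content, in [0, 1]."""
        self._require(term_id)
        return self._ic[term_id]

    @lru_cache(maxsize=None)
    def _mica_cached(self, a: str, b: str) -> MicaResult:
        common = self._ancestors[a] & self._ancestors[b]
        if not common:
            return MicaResult(term_id=None, ic_value=0.0, found=False)
        # max IC; ties broken by lexicographically smallest term id
        best = min(common, key=lambda t: (-self._ic[t], t))
        return MicaResult(term_id=best, ic_value=self._ic[best])

    def mica(self, a: str, b: str) -> MicaResult:
        """Most informative common ancestor of two terms (self-inclusive)."""
        self._require(a)
        self._require(b)
        if a > b:
            a, b = b, a
        return self._mica_cached(a, b)


def load_ontology(
    term_records: Iterable[Mapping[str, object]],
    descendant_mode: str = "transitive",
) -> Ontology:
    """Build an :class:`Ontology` from tabular term records.

    Each record must carry ``term_id`` and may carry ``label``, ``level`` and
    ``parent_ids`` (an iterable of term ids, or a single pipe-separated
    string).  Extra grouping ancestors (SMQ-like cross-links) are ordinary
    parents.
    """
    nodes = []
    for rec in term_records:
        raw_parents = rec.get("parent_ids", ())
        if isinstance(raw_parents, str):
            raw_parents = [p for p in raw_parents.split("|") if p]
        raw_level = rec.get("level")
        level = int(raw_level) if raw_level not in (None, "") else None
        nodes.append(
            TermNode(
                term_id=str(rec["term_id"]),
                label=str(rec.get("label", "") or ""),
                level=level,
                parent_ids=frozenset(str(p) for p in raw_parents),
            )
        )
    return Ontology(nodes, descendant_mode=descendant_mode)
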