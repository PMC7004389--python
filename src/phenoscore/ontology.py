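"""Ontology parsing and hierarchy queries.

Phenotype ontologies (Mammalian Phenotype, Human Phenotype, ...) are rooted
directed acyclic graphs whose ``is_a`` links define a subsumption hierarchy.
This module wraps :mod:`obonet` parsing in a validated :class:`OntologyGraph`
that answers the ancestor/descendant queries every other module relies on.

Only ``is_a`` edges are interpreted; ``part_of`` and other relation types are
ignored because prior estimation, upward propagation and the false-positive
ancestral search are all phrased purely on the subsumption hierarchy.
"""

from __future__ import annotations

from collections import deque
from typing import Iterable, Mapping

import networkx as nx
import obonet

from .errors import OntologyError, UnknownTermError

__all__ = ["OntologyGraph", "parse_obo"]


class OntologyGraph:
    """An is_a DAG of phenotype terms with deterministic hierarchy queries.

    Parameters
    ----------
    parents
        Map term -> set of direct is_a parents. Every referenced parent must
        itself appear as a key.
    aliases
        Map alternate id -> canonical id (``alt_id`` entries).
    obsolete
        Terms flagged obsolete. They are kept out of the hierarchy unless the
        graph was parsed with ``keep_obsolete``.
    names
        Optional human-readable term names.
    """

    def __init__(
        self,
        parents: Mapping[str, Iterable[str]],
        aliases: Mapping[str, str] | None = None,
        obsolete: Iterable[str] | None = None,
        names: Mapping[str, str] | None = None,
    ) -> None:
        self.parents: dict[str, frozenset[str]] = {
            t: frozenset(ps) for t, ps in parents.items()
        }
        self.aliases: dict[str, str] = dict(aliases or {})
        self.obsolete: frozenset[str] = frozenset(obsolete or ())
        self.names: dict[str, str] = dict(names or {})
        self._validate()
        self.children: dict[str, frozenset[str]] = self._invert()
        self.roots: frozenset[str] = frozenset(
            t for t, ps in self.parents.items() if not ps
        )
        self._ancestor_cache: dict[str, tuple[str, ...]] = {}

    # -- construction helpers -------------------------------------------------

    def _validate(self) -> None:
        if not self.parents:
            raise OntologyError("ontology has no terms")
        terms = set(self.parents)
        for t, ps in self.parents.items():
            missing = ps - terms
            if missing:
                raise OntologyError(
                    f"dangling is_a target(s) {sorted(missing)} referenced by {t}"
                )
        g = nx.DiGraph(
            (child, parent) for child, ps in self.parents.items() for parent in ps
        )
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            return
        path = " -> ".join(edge[0] for edge in cycle) + f" -> {cycle[0][0]}"
        raise OntologyError(f"cyclic is_a structure: {path}")

    def _invert(self) -> dict[str, frozenset[str]]:
        children: dict[str, set[str]] = {t: set() for t in self.parents}
        for t, ps in self.parents.items():
            for p in ps:
                children[p].add(t)
        return {t: frozenset(cs) for t, cs in children.items()}

    # -- queries --------------------------------------------------------------

    @property
    def terms(self) -> frozenset[str]:
        return frozenset(self.parents)

    def __len__(self) -> int:
        return len(self.parents)

    def __contains__(self, term: str) -> bool:
        return term in self.parents or term in self.aliases

    def resolve(self, term: str) -> str:
        """Resolve an id or alias to its canonical term id."""
        if term in self.parents:
            return term
        if term in self.aliases:
            return self.aliases[term]
        if term in self.obsolete:
            raise UnknownTermError(f"term {term!r} is obsolete")
        raise UnknownTermError(f"unknown term {term!r}")

    def ancestors(self, term: str) -> tuple[str, ...]:
        """Transitive is_a closure of ``term``, excluding ``term`` itself.

        The order is deterministic: breadth-first by edge distance with
        lexicographic tie-breaks, which makes the nearest-ancestor search in
        the scoring engine reproducible.
        """
        term = self.resolve(term)
        cached = self._ancestor_cache.get(term)
        if cached is not None:
            return cached
        seen: dict[str, int] = {}
        queue: deque[tuple[str, int]] = deque([(term, 0)])
        while queue:
            node, dist = queue.popleft()
            for parent in self.parents[node]:
                if parent not in seen or dist + 1 < seen[parent]:
                    seen[parent] = dist + 1
                    queue.append((parent, dist + 1))
        ordered = tuple(sorted(seen, key=lambda t: (seen[t], t)))
        self._ancestor_cache[term] = ordered
        return ordered

    def descendants(self, term: str) -> frozenset[str]:
        """All terms whose ancestor closure contains ``term``."""
        term = self.resolve(term)
        out: set[str] = set()
        queue = deque([term])
        while queue:
            node = queue.popleft()
            for child in self.children[node]:
                if child not in out:
                    out.add(child)
                    queue.append(child)
        return frozenset(out)

    def topological_order(self) -> tuple[str, ...]:
        """Terms ordered children-before-parents (deterministic)."""
        g = nx.DiGraph()
        g.add_nodes_from(self.parents)
        g.add_edges_from(
            (child, parent) for child, ps in self.parents.items() for parent in ps
        )
        return tuple(nx.lexicographical_topological_sort(g))


def parse_obo(path, keep_obsolete: bool = False) -> OntologyGraph:
    """Parse an OBO flat file into a validated :class:`OntologyGraph`.

    Only ``[Term]`` stanzas and ``is_a`` relations are interpreted. ``alt_id``
    entries are recorded as aliases resolving silently to the canonical id.
    Obsolete terms are excluded from the hierarchy unless ``keep_obsolete``.

    Raises
    ------
    OntologyError
        For an empty file, a cyclic is_a structure (one cycle is named), or a
        dangling is_a target (missing ids are listed).
    """
    try:
        raw = obonet.read_obo(path, ignore_obsolete=False)
    except ValueError as exc:
        raise OntologyError(f"unreadable OBO file {path!r}: {exc}") from exc
    # obonet materialises dangling is_a targets as attribute-less nodes
    stanza_nodes = {n for n, d in raw.nodes(data=True) if d}
    dangling = sorted(set(raw.nodes) - stanza_nodes)
    if dangling:
        raise OntologyError(f"dangling is_a target(s): {dangling}")
    if not stanza_nodes:
        raise OntologyError(f"no [Term] stanzas found in {path!r}")

    obsolete = {
        n
        for n, d in raw.nodes(data=True)
        if str(d.get("is_obsolete", "")).lower() == "true"
    }
    keep = stanza_nodes if keep_obsolete else stanza_nodes - obsolete
    parents: dict[str, set[str]] = {t: set() for t in keep}
    for child, parent, key in raw.edges(keys=True):
        if key != "is_a" or child not in keep:
            continue
        if parent not in keep:
            if parent in obsolete:
                continue  # edge into an excluded obsolete term
            raise OntologyError(f"is_a target {parent!r} of {child!r} is not a term")
        parents[child].add(parent)

    aliases: dict[str, str] = {}
    names: dict[str, str] = {}
    for n, d in raw.nodes(data=True):
        if n not in keep:
            continue
        if "name" in d:
            names[n] = d["name"]
        for alt in d.get("alt_id", []):
            aliases[alt] = n
    return OntologyGraph(parents, aliases=aliases, obsolete=obsolete, names=names)
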