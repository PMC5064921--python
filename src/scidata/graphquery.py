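"""In-memory quad store with basic-graph-pattern matching.

Supports exactly what cross-document search over SciData RDF needs: a
conjunction of triple patterns (with an optional named-graph slot)
joined on shared variables, plus equality filters.  Variables are
strings starting with ``?``.  No SPARQL text parsing — patterns are
built in code or loaded from a YAML/JSON config.

The join is evaluated smallest-candidate-set first against SPO/POS/OSP
indexes, and solutions come back in a deterministic order (sorted by
binding values).
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import QueryError
from .rdfizer import RdfLiteral, Triple
from .vocabulary import default_vocabulary


def is_var(slot) -> bool:
    return isinstance(slot, str) and slot.startswith("?")


@dataclass(frozen=True)
class Pattern:
    """One triple pattern; slots are constants or ``?name`` variables.

    At least one of subject/predicate/object must be a constant —
    a fully unconstrained scan is rejected as a query error.
    """

    subject: object
    predicate: object
    object: object
    graph: object = None  # None = any graph; constant or variable otherwise

    def __post_init__(self):
        if all(is_var(s) for s in (self.subject, self.predicate, self.object)):
            raise QueryError("pattern needs at least one constant slot")

    def variables(self) -> set[str]:
        return {s for s in (self.subject, self.predicate, self.object, self.graph)
                if is_var(s)}


class QuadStore:
    """Indexed quad set with set-semantics ingestion."""

    def __init__(self):
        self.quads: set[tuple] = set()
        self._spo: dict = {}
        self._pos: dict = {}
        self._osp: dict = {}
        self.graphs: dict[str | None, set] = {}

    def __len__(self):
        return len(self.quads)

    def add(self, triple: Triple) -> None:
        q = (triple.subject, triple.predicate, triple.object, triple.graph)
        if q in self.quads:
            return
        self.quads.add(q)
        s, p, o, g = q
        self._spo.setdefault(s, {}).setdefault(p, set()).add(q)
        self._pos.setdefault(p, {}).setdefault(o, set()).add(q)
        self._osp.setdefault(o, {}).setdefault(s, set()).add(q)
        self.graphs.setdefault(g, set()).add(q)

    def candidates(self, pattern: Pattern) -> list[tuple]:
        """Smallest index slice consistent with the pattern's constants."""
        s, p, o = pattern.subject, pattern.predicate, pattern.object
        if not is_var(s) and not is_var(p):
            quads = self._spo.get(s, {}).get(p, set())
        elif not is_var(p) and not is_var(o):
            quads = self._pos.get(p, {}).get(o, set())
        elif not is_var(o) and not is_var(s):
            quads = self._osp.get(o, {}).get(s, set())
        elif not is_var(s):
            quads = set().union(*self._spo.get(s, {}).values()) if s in self._spo else set()
        elif not is_var(p):
            quads = set().union(*self._pos.get(p, {}).values()) if p in self._pos else set()
        else:
            quads = set().union(*self._osp.get(o, {}).values()) if o in self._osp else set()
        if pattern.graph is not None and not is_var(pattern.graph):
            quads = {q for q in quads if q[3] == pattern.graph}
        return list(quads)


def ingest(store: QuadStore, triples) -> QuadStore:
    """Add triples/quads to the store; re-ingestion is a no-op."""
    for t in triples:
        store.add(t)
    return store


def _unify(pattern: Pattern, quad: tuple, binding: dict) -> dict | None:
    out = dict(binding)
    slots = (pattern.subject, pattern.predicate, pattern.object, pattern.graph)
    for slot, value in zip(slots, quad):
        if slot is None:
            continue
        if is_var(slot):
            if slot in out and out[slot] != value:
                return None
            out[slot] = value
        elif slot != value:
            return None
    return out


def _binding_sort_key(binding: dict):
    return tuple(str(binding[k]) for k in sorted(binding))


def match(store: QuadStore, patterns: list[Pattern], filters=None) -> list[dict]:
    """Solutions of the conjunctive pattern join, deterministically ordered.

    ``filters`` is a list of equality constraints: ``(var, constant)``
    or ``(var, var)`` pairs.  Every filtered variable must occur in some
    pattern.
    """
    if not patterns:
        raise QueryError("match requires at least one pattern")
    filters = list(filters or [])
    pattern_vars = set().union(*(p.variables() for p in patterns))
    for a, b in filters:
        for side in (a, b):
            if is_var(side) and side not in pattern_vars:
                raise QueryError(f"filter variable {side!r} is not used in any pattern")

    ordered = sorted(patterns, key=lambda p: (len(store.candidates(p)), repr(p)))
    solutions: list[dict] = [{}]
    for pattern in ordered:
        cands = store.candidates(pattern)
        nxt = []
        for binding in solutions:
            for quad in cands:
                unified = _unify(pattern, quad, binding)
                if unified is not None:
                    nxt.append(unified)
        solutions = nxt
        if not solutions:
            break

    def passes(binding):
        for a, b in filters:
            av = binding[a] if is_var(a) else a
            bv = binding[b] if is_var(b) else b
            if av != bv:
                return False
        return True

    solutions = [b for b in solutions if passes(b)]
    # deduplicate (identical bindings reachable along multiple quad orders)
    unique = {tuple(sorted((k, str(v)) for k, v in b.items())): b for b in solutions}
    return sorted(unique.values(), key=_binding_sort_key)


def brute_force_match(store: QuadStore, patterns: list[Pattern], filters=None) -> list[dict]:
    """Index-free nested-loop join over the raw quad set (test oracle)."""
    if not patterns:
        raise QueryError("match requires at least one pattern")
    solutions: list[dict] = [{}]
    for pattern in patterns:
        solutions = [u for b in solutions for q in store.quads
                     if (u := _unify(pattern, q, b)) is not None]
    for a, b in list(filters or []):
        solutions = [s for s in solutions
                     if (s[a] if is_var(a) else a) == (s[b] if is_var(b) else b)]
    unique = {tuple(sorted((k, str(v)) for k, v in s.items())): s for s in solutions}
    return sorted(unique.values(), key=_binding_sort_key)


def toc_scope(store: QuadStore, kinds, sdmo_namespace: str | None = None) -> set[str]:
    """Documents whose table of contents covers all requested kinds.

    ``kinds`` are bare kind names ("datapoint", "measurement"); they are
    looked up as toc IRIs under the SDMO namespace.
    """
    kinds = list(kinds)
    if not kinds:
        raise QueryError("toc_scope requires at least one kind")
    ns = sdmo_namespace or default_vocabulary().sdmo_namespace
    toc_pred = ns + "toc"
    result: set[str] | None = None
    for kind in kinds:
        docs = {q[0] for q in store._pos.get(toc_pred, {}).get(ns + kind, set())}
        result = docs if result is None else result & docs
        if not result:
            return set()
    return result


def load_query_config(config: dict, sdmo_namespace: str | None = None):
    """Build (patterns, filters) from a YAML/JSON-style mapping.

    Shape::

        prefixes: {sci: "...", dcterms: "..."}   # optional
        patterns:
          - {s: "?doc", p: "sci:property", o: {literal: "refractive index"}}
          - {s: "?doc", p: "sci:discipline", o: {literal: chemistry}, g: "?g"}
        filters:
          - ["?g", "https://example.org/doc/"]

    IRIs may use the declared prefixes; ``o`` accepts a plain string
    (IRI or variable) or ``{literal: ..., datatype: ..., language: ...}``.
    """
    prefixes = dict(config.get("prefixes", {}))
    prefixes.setdefault("sci", sdmo_namespace or default_vocabulary().sdmo_namespace)

    def iri(v):
        if not isinstance(v, str) or is_var(v):
            return v
        head, _, tail = v.partition(":")
        if head in prefixes:
            return prefixes[head] + tail
        return v

    def obj(v):
        if isinstance(v, dict):
            return RdfLiteral(str(v["literal"]), datatype=iri(v.get("datatype")),
                              language=v.get("language"))
        return iri(v)

    patterns = [Pattern(iri(p["s"]), iri(p["p"]), obj(p["o"]), iri(p.get("g")))
                for p in config.get("patterns", [])]
    filters = [(iri(a), obj(b)) for a, b in config.get("filters", [])]
    return patterns, filters
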