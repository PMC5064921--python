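"""Deterministic RDF-ization of SciData documents.

``to_triples`` serializes a document to JSON-LD, expands it, and walks
the expanded form emitting subject–predicate–object triples.  Objects
carrying ``@id`` become IRI nodes; anonymous objects become blank nodes
labeled in depth-first order (``_:b0``, ``_:b1``, …) so that identical
documents always yield byte-identical N-Quads.

The produced graph is, up to blank-node relabeling, the same graph any
conformant JSON-LD processor derives from the serialized document —
the test suite checks graph isomorphism against rdflib.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import jsonld_codec as codec
from . import model as m
from .errors import ParseError

XSD_STRING = codec.XSD + "string"
XSD_INTEGER = codec.XSD + "integer"
XSD_BOOLEAN = codec.XSD + "boolean"
XSD_DOUBLE = codec.XSD + "double"


@dataclass(frozen=True)
class RdfLiteral:
    """An RDF literal; plain strings carry no datatype (RDF 1.1 collapses
    ``xsd:string``), language-tagged strings carry no datatype either."""

    value: str
    datatype: str | None = None
    language: str | None = None

    def __post_init__(self):
        if self.datatype == XSD_STRING and self.language is None:
            object.__setattr__(self, "datatype", None)


@dataclass(frozen=True)
class Triple:
    """Subject/predicate/object (+ optional named graph).

    Subjects and objects that are strings are IRIs, or blank-node
    labels when prefixed ``_:``; literal objects are RdfLiteral.
    """

    subject: str
    predicate: str
    object: "str | RdfLiteral"
    graph: str | None = None


def _literal_from_value_object(vo: dict) -> RdfLiteral:
    v = vo["@value"]
    if "@language" in vo:
        return RdfLiteral(str(v), language=vo["@language"])
    if "@type" in vo:
        return RdfLiteral(str(v), datatype=vo["@type"])
    if isinstance(v, bool):
        return RdfLiteral("true" if v else "false", datatype=XSD_BOOLEAN)
    if isinstance(v, int):
        return RdfLiteral(str(v), datatype=XSD_INTEGER)
    if isinstance(v, float):
        # canonical xsd:double lexical form, as JSON-LD deserialization of
        # native JSON numbers prescribes
        mantissa, _, exp = f"{v:E}".partition("E")
        mantissa = mantissa.rstrip("0").rstrip(".")
        if "." not in mantissa:
            mantissa += ".0"
        return RdfLiteral(f"{mantissa}E{int(exp)}", datatype=XSD_DOUBLE)
    return RdfLiteral(str(v))


def expanded_to_triples(nodes: list, graph: str | None = None) -> list[Triple]:
    """Walk expanded JSON-LD node objects, emitting triples."""
    triples: list[Triple] = []
    counter = [0]

    def node_subject(node: dict) -> str:
        if "@id" in node:
            return node["@id"]
        label = f"_:b{counter[0]}"
        counter[0] += 1
        return label

    def walk(node: dict, subject: str):
        for t in node.get("@type", []):
            triples.append(Triple(subject, codec.RDF_TYPE, t, graph))
        for pred, values in node.items():
            if pred.startswith("@"):
                continue
            for v in values:
                if "@value" in v:
                    triples.append(Triple(subject, pred, _literal_from_value_object(v), graph))
                elif set(v) == {"@id"}:
                    triples.append(Triple(subject, pred, v["@id"], graph))
                else:
                    obj = node_subject(v)
                    triples.append(Triple(subject, pred, obj, graph))
                    walk(v, obj)

    for node in nodes:
        walk(node, node_subject(node))
    # set semantics with deterministic (first-appearance) order
    seen, out = set(), []
    for t in triples:
        if t not in seen:
            seen.add(t)
            out.append(t)
    return out


def to_triples(doc: m.SciDataDocument, strict: bool = True,
               graph: str | None = "document") -> list[Triple]:
    """Convert a document to RDF triples.

    The named graph defaults to the document IRI (pass ``graph=None``
    for plain triples, or any IRI to override).  Strict-mode
    serialization failures propagate.
    """
    text = codec.serialize(doc, strict=strict)
    if graph == "document":
        graph = doc.doc_id
    return expanded_to_triples(codec.expand(text), graph=graph)


# --------------------------------------------------------------------------
# N-Quads I/O

_ESCAPES = {"\\": "\\\\", '"': '\\"', "\n": "\\n", "\r": "\\r", "\t": "\\t"}


def _escape(s: str) -> str:
    return "".join(_ESCAPES.get(c, c) for c in s)


def _fmt_node(node) -> str:
    if isinstance(node, RdfLiteral):
        out = f'"{_escape(node.value)}"'
        if node.language:
            out += f"@{node.language}"
        elif node.datatype:
            out += f"^^<{node.datatype}>"
        return out
    if node.startswith("_:"):
        return node
    return f"<{node}>"


def write_nquads(triples, graph_iri: str | None = None) -> str:
    """Serialize triples as canonically sorted N-Quads text.

    ``graph_iri`` stamps every quad with that named graph, overriding
    per-triple graphs; otherwise each triple's own graph (if any) is
    written.
    """
    lines = []
    for t in triples:
        g = graph_iri if graph_iri is not None else t.graph
        parts = [_fmt_node(t.subject), _fmt_node(t.predicate), _fmt_node(t.object)]
        if g:
            parts.append(_fmt_node(g))
        lines.append(" ".join(parts) + " .")
    return "\n".join(sorted(lines)) + ("\n" if lines else "")


_IRI_RE = r"<([^<>\"{}|^`\\\x00-\x20]*)>"
_BNODE_RE = r"(_:[A-Za-z0-9][A-Za-z0-9._-]*)"
_LIT_RE = r'"((?:[^"\\]|\\.)*)"(?:\^\^' + _IRI_RE + r"|@([a-zA-Z][a-zA-Z0-9-]*))?"
import re as _re

_QUAD_LINE = _re.compile(
    rf"^\s*(?:{_IRI_RE}|{_BNODE_RE})"          # subject: groups 1 (iri) / 2 (bnode)
    rf"\s+{_IRI_RE}"                           # predicate: group 3
    rf"\s+(?:{_IRI_RE}|{_BNODE_RE}|{_LIT_RE})"  # object: groups 4/5 or 6 (lex) 7 (dt) 8 (lang)
    rf"(?:\s+(?:{_IRI_RE}|{_BNODE_RE}))?"      # graph: groups 9/10
    r"\s*\.\s*$")

_UNESCAPES = {"\\": "\\", '"': '"', "n": "\n", "r": "\r", "t": "\t",
              "b": "\b", "f": "\f", "'": "'"}


def _unescape(s: str) -> str:
    def sub(mo):
        c = mo.group(1)
        if c[0] in "uU":
            return chr(int(c[1:], 16))
        return _UNESCAPES.get(c, c)
    return _re.sub(r"\\(u[0-9A-Fa-f]{4}|U[0-9A-Fa-f]{8}|.)", sub, s)


def read_nquads(text: str) -> list[Triple]:
    """Parse N-Quads text into triples, preserving blank-node labels.

    Hand-rolled line parser: the write/read contract requires the exact
    blank-node labels back, which general RDF parsers rename on input.
    Syntax errors carry the 1-based line number.
    """
    out = []
    for lineno, line in enumerate(text.splitlines(), 1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        mo = _QUAD_LINE.match(line)
        if mo is None:
            raise ParseError("malformed N-Quads line", line=lineno)
        g = mo.group(1), mo.group(2), mo.group(3), mo.group(4), mo.group(5), \
            mo.group(6), mo.group(7), mo.group(8), mo.group(9), mo.group(10)
        subject = g[0] if g[0] is not None else g[1]
        predicate = g[2]
        if g[5] is not None:
            obj: str | RdfLiteral = RdfLiteral(_unescape(g[5]), datatype=g[6], language=g[7])
        else:
            obj = g[3] if g[3] is not None else g[4]
        graph = g[8] if g[8] is not None else g[9]
        out.append(Triple(subject, predicate, obj, graph))
    return out


def to_rdflib_graph(triples):
    """Materialize triples (graph component ignored) as an rdflib Graph."""
    from rdflib import BNode, Graph
    from rdflib import Literal as RLiteral
    from rdflib import URIRef

    g = Graph()
    bnodes: dict[str, object] = {}

    def conv(n, as_object=False):
        if isinstance(n, RdfLiteral):
            return RLiteral(n.value, datatype=n.datatype, lang=n.language)
        if n.startswith("_:"):
            return bnodes.setdefault(n, BNode())
        return URIRef(n)

    for t in triples:
        g.add((conv(t.subject), conv(t.predicate), conv(t.object, True)))
    return g
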