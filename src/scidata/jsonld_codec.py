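"""JSON-LD serialization of SciData documents.

The codec covers the JSON-LD 1.0 feature subset the data model needs:
term definitions, namespace prefixes, ``@vocab``, ``@base``, ``@id``,
``@type`` and typed values.  Contexts can be inlined or externalized to
standalone files; external contexts are resolved through a local
:class:`ContextRegistry`, never the network.

Numbers are emitted as typed value objects carrying their printed
lexical form (``{"@value": "3.50", "@type": "xsd:decimal"}``) so that
significant figures survive the round trip and the RDF literal produced
by any conformant processor is identical to ours.

Output key order is canonical — JSON-LD keywords first, then
alphabetical — so serialized files diff stably.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from decimal import Decimal
from urllib.parse import urljoin

from . import model as m
from .errors import ContextError, ParseError, SerializationError
from .quantity import NumericValue, Parameter, TextValue, Unit, UnitSpec, expansion_str, parse_expansion
from .vocabulary import EXTERNAL_NAMESPACES, Vocabulary, default_vocabulary

XSD = "http://www.w3.org/2001/XMLSchema#"
RDF_TYPE = "http://www.w3.org/1999/02/22-rdf-syntax-ns#type"

KEYWORD_ORDER = ("@context", "@base", "@vocab", "@id", "@type", "@value", "@language")

#: model terms whose string values are IRIs, not literals
REF_TERMS = frozenset({"toc", "source", "scope", "unitref", "valuerefs"})

_XSD_BY_NUMERIC_TYPE = {
    "decimal": XSD + "decimal",
    "integer": XSD + "integer",
    "float": XSD + "float",
    "exponential": XSD + "double",
}
_NUMERIC_TYPE_BY_XSD = {v: k for k, v in _XSD_BY_NUMERIC_TYPE.items()}


@dataclass
class TermDefinition:
    alias: str
    iri: str
    value_type: str | None = None  # "@id" or a datatype IRI
    container_hint: str | None = None

    def to_jsonld(self):
        if self.value_type is None:
            return {"@id": self.iri}
        return {"@id": self.iri, "@type": self.value_type}


@dataclass
class Context:
    prefixes: dict[str, str] = field(default_factory=dict)
    vocab: str | None = None
    base: str | None = None
    terms: list[TermDefinition] = field(default_factory=list)
    #: keys seen in the document with no term definition (kept, flagged)
    unannotated: list[str] = field(default_factory=list, compare=False)

    def __post_init__(self):
        aliases = [t.alias for t in self.terms]
        collisions = set(aliases) & (set(self.prefixes) | {k for k in aliases if k.startswith("@")})
        if len(set(aliases)) != len(aliases):
            dupes = sorted({a for a in aliases if aliases.count(a) > 1})
            raise ContextError(f"duplicate term aliases: {dupes}")
        if collisions:
            raise ContextError(f"term aliases collide with prefixes/keywords: {sorted(collisions)}")

    def to_jsonld(self, include_base: bool = True) -> dict:
        out: dict = {}
        if include_base and self.base:
            out["@base"] = self.base
        if self.vocab:
            out["@vocab"] = self.vocab
        for alias in sorted(self.prefixes):
            out[alias] = self.prefixes[alias]
        for term in sorted(self.terms, key=lambda t: t.alias):
            out[term.alias] = term.to_jsonld()
        return out


class ContextRegistry:
    """Offline IRI → context-payload map for external-context resolution."""

    def __init__(self):
        self._contexts: dict[str, dict] = {}

    def add(self, iri: str, payload: dict) -> None:
        ctx = payload.get("@context", payload)
        self._contexts[iri] = ctx

    def lookup(self, iri: str) -> dict:
        try:
            return self._contexts[iri]
        except KeyError:
            raise ContextError(f"unknown external context IRI {iri!r}") from None

    @classmethod
    def from_directory(cls, path) -> "ContextRegistry":
        """Load from a directory holding ``registry.yaml`` (IRI → filename)."""
        import pathlib

        import yaml

        path = pathlib.Path(path)
        reg = cls()
        mapping = yaml.safe_load((path / "registry.yaml").read_text()) or {}
        for iri, fname in mapping.items():
            reg.add(iri, json.loads((path / fname).read_text()))
        return reg


# --------------------------------------------------------------------------
# id assignment

def assign_ids(doc: m.SciDataDocument, base_iri: str | None = None) -> m.SciDataDocument:
    """Mint per-object identifiers.

    Element ids are minted at add time; this fills in the structural ids
    of parameters (``datapoint/1/parameter/1/``).  Values and in-place
    units take their ids from the owning parameter at serialization
    (``.../value/``, ``.../unit/``), so a parameter and its value always
    get distinct IRIs.  Idempotent: ids are recomputed structurally.
    """
    if base_iri is not None:
        m.build_document({}, base_iri)  # reuse the base checks
        doc.base_iri = base_iri
        doc.doc_id = base_iri
    for rid, el in m.iter_elements(doc):
        if isinstance(el, m.Datapoint):
            for i, p in enumerate(el.parameters, 1):
                p.param_id = f"{rid}parameter/{i}/"
        elif isinstance(el, m.Dataseries):
            el.parameter.param_id = f"{rid}parameter/1/"
        elif isinstance(el, m.Datagroup):
            for i, p in enumerate(el.attributes, 1):
                p.param_id = f"{rid}attribute/{i}/"
        elif isinstance(el, (m.Aspect, m.Facet)):
            i = 0
            for v in el.metadata.values():
                if isinstance(v, Parameter):
                    i += 1
                    v.param_id = f"{rid}parameter/{i}/"
    return doc


# --------------------------------------------------------------------------
# body construction (model -> plain JSON-LD dict, no context)

def _decimal_value(lexical: str, xsd_type: str = XSD + "decimal") -> dict:
    return {"@value": lexical, "@type": "xsd:" + xsd_type[len(XSD):]}


def _render_numeric(nv: NumericValue, node_id: str | None) -> dict:
    out: dict = {}
    if node_id:
        out["@id"] = node_id
    out["@type"] = "sci:value"
    out["number"] = _decimal_value(nv.lexical, _XSD_BY_NUMERIC_TYPE[nv.numeric_type])
    out["numbertype"] = nv.numeric_type
    if nv.sigfigs is not None:
        out["sigfigs"] = nv.sigfigs
    if nv.error is not None:
        out["error"] = _decimal_value(str(nv.error))
    if nv.exact:
        out["exact"] = True
    return out


def _render_text(tv: TextValue, node_id: str | None) -> dict:
    out: dict = {}
    if node_id:
        out["@id"] = node_id
    out["@type"] = "sci:textstring"
    if tv.language:
        out["text"] = {"@value": tv.text, "@language": tv.language}
    else:
        out["text"] = tv.text
    out["texttype"] = tv.text_type
    return out


def _render_unit(unit: Unit, node_id: str) -> dict:
    out = {"@id": node_id, "@type": "sci:unit", "symbol": unit.symbol}
    if unit.quantity_kind:
        out["quantitykind"] = unit.quantity_kind
    if unit.si_base_expansion:
        out["dimensions"] = expansion_str(unit.si_base_expansion)
    out["multiplier"] = _decimal_value(str(unit.multiplier_to_si))
    if unit.offset_to_si != 0:
        out["offset"] = _decimal_value(str(unit.offset_to_si))
    if unit.prefix:
        out["prefix"] = unit.prefix
    return out


def _render_parameter(p: Parameter) -> dict:
    out: dict = {}
    if p.param_id:
        out["@id"] = p.param_id
    out["@type"] = "sci:parameter"
    out["property"] = p.property
    if p.quantity:
        out["quantity"] = p.quantity
    pid = p.param_id or ""
    if isinstance(p.value, NumericValue):
        out["value"] = _render_numeric(p.value, pid + "value/" if pid else None)
    elif isinstance(p.value, TextValue):
        out["textstring"] = _render_text(p.value, pid + "textstring/" if pid else None)
    else:  # array of values
        out["values"] = [
            _render_numeric(v, None) if isinstance(v, NumericValue) else _render_text(v, None)
            for v in p.value
        ]
    spec = p.unit_spec
    if isinstance(spec, UnitSpec):
        if spec.form == "unitstr":
            out["unitstr"] = spec.unitstr
        elif spec.form == "unitref":
            out["unitref"] = spec.unitref
        else:
            out["unit"] = _render_unit(spec.unit, pid + "unit/" if pid else None)
    return out


def _render_series_value(v):
    if isinstance(v, bool):
        raise SerializationError("boolean series values are not supported")
    if isinstance(v, int):
        return v
    if isinstance(v, Decimal):
        return _decimal_value(str(v))
    if isinstance(v, float):
        return _decimal_value(str(v))
    if isinstance(v, str):
        return v
    raise SerializationError(f"unsupported series value type {type(v).__name__}")


def _render_metadata_value(v):
    if isinstance(v, Parameter):
        return _render_parameter(v)
    if isinstance(v, Decimal):
        return _decimal_value(str(v))
    if isinstance(v, float):
        return _decimal_value(str(v))
    if isinstance(v, list):
        return [_render_metadata_value(x) for x in v]
    if isinstance(v, dict):
        return {k: _render_metadata_value(x) for k, x in v.items()}
    return v


def _maybe_single(values: list):
    return values[0] if len(values) == 1 else values


def _render_datapoint(dp: m.Datapoint) -> dict:
    out = {"@id": dp.point_id, "@type": "sci:datapoint",
           "parameter": _maybe_single([_render_parameter(p) for p in dp.parameters])}
    if dp.source_refs:
        out["source"] = _maybe_single(list(dp.source_refs))
    if dp.scope_refs:
        out["scope"] = _maybe_single(list(dp.scope_refs))
    return out


def _render_dataseries(ds: m.Dataseries) -> dict:
    out = {"@id": ds.series_id, "@type": "sci:dataseries"}
    if ds.label:
        out["label"] = ds.label
    out["parameter"] = _render_parameter(ds.parameter)
    if ds.values_are_refs:
        out["valuerefs"] = _maybe_single(list(ds.values))
    else:
        out["values"] = _maybe_single([_render_series_value(v) for v in ds.values])
    return out


def _render_datagroup(dg: m.Datagroup) -> dict:
    out = {"@id": dg.group_id, "@type": "sci:datagroup", "kind": dg.kind}
    if dg.attributes:
        out["attributes"] = _maybe_single([_render_parameter(p) for p in dg.attributes])
    if dg.source_refs:
        out["source"] = _maybe_single(list(dg.source_refs))
    if dg.scope_refs:
        out["scope"] = _maybe_single(list(dg.scope_refs))
    if dg.members:
        rendered = []
        for member in dg.members:
            if isinstance(member, str):
                rendered.append({"@id": member})
            elif isinstance(member, m.Datagroup):
                rendered.append(_render_datagroup(member))
            elif isinstance(member, m.Dataseries):
                rendered.append(_render_dataseries(member))
            else:
                rendered.append(_render_datapoint(member))
        out["members"] = _maybe_single(rendered)
    return out


def build_body(doc: m.SciDataDocument) -> dict:
    """The document as a context-free JSON-LD node object."""
    out: dict = {"@id": doc.doc_id}
    for k, v in doc.root_metadata.items():
        out[k] = _render_metadata_value(v)
    if doc.toc:
        out["toc"] = _maybe_single(["sci:" + k for k in sorted(doc.toc)])
    sd = doc.scidata
    container: dict = {"@id": "scidata/", "@type": "sci:scientificData"}
    if sd.discipline:
        container["discipline"] = sd.discipline
    if sd.subdiscipline:
        container["subdiscipline"] = sd.subdiscipline
    if sd.property_list:
        container["properties"] = _maybe_single(list(sd.property_list))
    if sd.methodology is not None:
        meth: dict = {"@id": "methodology/", "@type": "sci:methodology"}
        if sd.methodology.evaluation:
            meth["evaluation"] = sd.methodology.evaluation
        if sd.methodology.aspects:
            meth["aspects"] = _maybe_single([
                {"@id": a.aspect_id, "@type": "sci:" + a.kind,
                 **{k: _render_metadata_value(v) for k, v in a.metadata.items()}}
                for a in sd.methodology.aspects
            ])
        container["methodology"] = meth
    if sd.system is not None:
        system: dict = {"@id": "system/", "@type": "sci:system"}
        if sd.system.facets:
            system["facets"] = _maybe_single([
                {"@id": f.facet_id, "@type": "sci:" + f.kind,
                 **{k: _render_metadata_value(v) for k, v in f.metadata.items()}}
                for f in sd.system.facets
            ])
        container["system"] = system
    if sd.dataset is not None:
        ds = sd.dataset
        dataset: dict = {"@id": "dataset/", "@type": "sci:dataset"}
        if ds.source_refs:
            dataset["source"] = _maybe_single(list(ds.source_refs))
        if ds.scope_refs:
            dataset["scope"] = _maybe_single(list(ds.scope_refs))
        if ds.datapoints:
            dataset["datapoint"] = _maybe_single([_render_datapoint(p) for p in ds.datapoints])
        if ds.dataseries:
            dataset["dataseries"] = _maybe_single([_render_dataseries(s) for s in ds.dataseries])
        if ds.datagroups:
            dataset["datagroup"] = _maybe_single([_render_datagroup(g) for g in ds.datagroups])
        container["dataset"] = dataset
    out["scidata"] = container
    return out


# --------------------------------------------------------------------------
# context building

def _collect_keys(node, keys: set[str]):
    if isinstance(node, dict):
        for k, v in node.items():
            if not k.startswith("@"):
                keys.add(k)
            _collect_keys(v, keys)
    elif isinstance(node, list):
        for v in node:
            _collect_keys(v, keys)


def build_context(doc: m.SciDataDocument, vocabulary: Vocabulary | None = None,
                  strict: bool = False) -> Context:
    """Derive a context covering every key the document serializes.

    Each used key gets one term definition from the vocabulary registry,
    with absolute IRIs (see :func:`compact_context` for the prefixed
    form).  Keys with no registry entry are flagged in
    ``Context.unannotated`` — or rejected when ``strict`` is set.
    """
    vocab = vocabulary or default_vocabulary()
    keys: set[str] = set()
    _collect_keys(build_body(doc), keys)
    prefixes = {"sci": vocab.sdmo_namespace, "xsd": XSD}
    terms, unannotated = [], []
    for key in sorted(keys):
        if key in vocab:
            term = vocab.lookup(key)
            for alias, ns in EXTERNAL_NAMESPACES.items():
                if term.term_iri.startswith(ns):
                    prefixes[alias] = ns
            terms.append(TermDefinition(
                alias=key, iri=term.term_iri,
                value_type="@id" if key in REF_TERMS else None))
        else:
            unannotated.append(key)
    if strict and unannotated:
        raise ContextError(f"no term definition for keys: {unannotated}")
    return Context(prefixes=prefixes, vocab=vocab.sdmo_namespace, base=doc.base_iri,
                   terms=terms, unannotated=unannotated)


def compact_context(ctx: Context) -> Context:
    """Rewrite absolute term IRIs into prefix:suffix form.

    Longest-namespace match wins; ties break alphabetically on the
    prefix.  Idempotent, and semantics-preserving: expansion of the
    output context equals expansion of the input.
    """
    ranked = sorted(ctx.prefixes.items(), key=lambda kv: (-len(kv[1]), kv[0]))

    def shorten(iri: str) -> str:
        if ":" in iri and not iri.startswith(("http://", "https://")):
            return iri  # already compact
        for alias, ns in ranked:
            if iri.startswith(ns) and len(iri) > len(ns):
                return f"{alias}:{iri[len(ns):]}"
        return iri

    terms = [TermDefinition(t.alias, shorten(t.iri),
                            t.value_type if t.value_type in (None, "@id") else shorten(t.value_type),
                            t.container_hint)
             for t in ctx.terms]
    return Context(prefixes=dict(ctx.prefixes), vocab=ctx.vocab, base=ctx.base,
                   terms=terms, unannotated=list(ctx.unannotated))


def externalize_context(doc: m.SciDataDocument, ctx: Context, file_iri: str):
    """Split a document into a context-referencing form plus a standalone context.

    Returns ``(document_dict, context_payload)``: the document's
    ``@context`` becomes ``[file_iri, {"@base": ...}]`` and the payload
    holds everything else.  Re-inlining reproduces the inline document.
    """
    payload = {"@context": ctx.to_jsonld(include_base=False)}
    body = build_body(doc)
    document = {"@context": [file_iri, {"@base": ctx.base or doc.base_iri}], **body}
    return canonical_order(document), canonical_order(payload)


# --------------------------------------------------------------------------
# canonical key ordering

def canonical_order(node):
    """Keywords first (fixed order), then alphabetical — recursively."""
    if isinstance(node, dict):
        ordered = {}
        for kw in KEYWORD_ORDER:
            if kw in node:
                ordered[kw] = canonical_order(node[kw])
        for k in sorted(k for k in node if k not in KEYWORD_ORDER):
            ordered[k] = canonical_order(node[k])
        return ordered
    if isinstance(node, list):
        return [canonical_order(v) for v in node]
    return node


# --------------------------------------------------------------------------
# serialize / deserialize

def serialize(doc: m.SciDataDocument, strict: bool = True,
              external_context: str | None = None,
              vocabulary: Vocabulary | None = None) -> str:
    """Serialize to JSON-LD text (UTF-8, canonical key order).

    In strict mode the document must validate with no errors and every
    emitted key must have a term definition.  ``external_context``
    switches from an inline context to a reference on that IRI (register
    the returned payload of :func:`externalize_context` to deserialize).
    As a side effect, parameter ids are assigned and ``context_ref`` is
    updated to reflect the serialization mode.
    """
    if strict:
        problems = [i for i in m.validate(doc) if i.severity == "error"]
        if problems:
            detail = "; ".join(f"{i.path}: {i.message}" for i in problems)
            raise SerializationError(f"document does not validate: {detail}")
    assign_ids(doc)
    ctx = compact_context(build_context(doc, vocabulary=vocabulary, strict=strict))
    if external_context:
        doc.context_ref = external_context
        document, _payload = externalize_context(doc, ctx, external_context)
    else:
        doc.context_ref = None
        document = canonical_order({"@context": ctx.to_jsonld(), **build_body(doc)})
    return json.dumps(document, indent=2, ensure_ascii=False)


def _as_list(v) -> list:
    if v is None:
        return []
    return v if isinstance(v, list) else [v]


class _CtxState:
    """Parsed context: term/prefix map, @vocab, @base."""

    def __init__(self):
        self.terms: dict[str, str] = {}      # alias -> IRI
        self.types: dict[str, str] = {}      # alias -> "@id" | datatype IRI (compact ok)
        self.vocab: str | None = None
        self.base: str | None = None
        self.external_refs: list[str] = []

    def expand_iri(self, value: str, vocab: bool = False,
                   document_relative: bool = False) -> str | None:
        if not isinstance(value, str) or value.startswith("@"):
            return value
        if value in self.terms:
            return self.terms[value]
        if ":" in value:
            prefix, suffix = value.split(":", 1)
            if suffix.startswith("//") or prefix == "_":
                return value
            if prefix in self.terms:
                return self.terms[prefix] + suffix
            return value  # absolute IRI with an undeclared scheme-like prefix
        if vocab and self.vocab:
            return self.vocab + value
        if document_relative and self.base:
            return urljoin(self.base, value)
        return None

    def term_type(self, alias: str) -> str | None:
        t = self.types.get(alias)
        if t and t != "@id":
            return self.expand_iri(t, vocab=True)
        return t


def parse_context(raw, registry: ContextRegistry | None = None) -> _CtxState:
    """Parse an ``@context`` value (dict, IRI string, or list of both)."""
    state = _CtxState()
    for part in _as_list(raw):
        if isinstance(part, str):
            if registry is None:
                raise ContextError(
                    f"external context {part!r} cannot be resolved: no registry supplied")
            state.external_refs.append(part)
            part = registry.lookup(part)
        if not isinstance(part, dict):
            raise ContextError(f"unsupported @context entry: {part!r}")
        for k, v in part.items():
            if k == "@base":
                state.base = v
            elif k == "@vocab":
                state.vocab = v
            elif k.startswith("@"):
                raise ContextError(f"unsupported context keyword {k!r}")
            elif isinstance(v, str):
                state.terms[k] = v
            elif isinstance(v, dict):
                if "@id" not in v:
                    raise ContextError(f"term {k!r} definition lacks @id")
                state.terms[k] = v["@id"]
                if "@type" in v:
                    state.types[k] = v["@type"]
            else:
                raise ContextError(f"unsupported term definition for {k!r}")
    # compact IRIs in term definitions resolve against the same context
    for alias, iri in list(state.terms.items()):
        if ":" in iri:
            prefix, suffix = iri.split(":", 1)
            if not suffix.startswith("//") and prefix in state.terms and prefix != alias:
                state.terms[alias] = state.terms[prefix] + suffix
    return state


# --------------------------------------------------------------------------
# expansion / compaction (JSON-LD 1.0 subset)

def expand(doc_or_text, registry: ContextRegistry | None = None) -> list:
    """Expand a JSON-LD document per the 1.0 expansion algorithm (subset).

    Returns the expanded form: a list of node objects with absolute IRI
    keys and explicit value objects.
    """
    obj = _load_json(doc_or_text)
    if not isinstance(obj, dict):
        raise ParseError("top-level JSON-LD value must be an object")
    ctx = parse_context(obj.get("@context"), registry)
    expanded = _expand_node(obj, ctx)
    return [expanded] if expanded else []


def _expand_node(node: dict, ctx: _CtxState) -> dict:
    out: dict = {}
    for key, value in node.items():
        if key == "@context":
            continue
        if key == "@id":
            iri = ctx.expand_iri(value, vocab=False, document_relative=True)
            if iri is not None:
                out["@id"] = iri
            continue
        if key == "@type":
            out["@type"] = [ctx.expand_iri(t, vocab=True, document_relative=True)
                            for t in _as_list(value)]
            continue
        if key.startswith("@"):
            raise ContextError(f"unsupported keyword {key!r} in node object")
        iri = ctx.expand_iri(key, vocab=True)
        if iri is None:
            continue  # key has no definition and no @vocab: dropped
        out.setdefault(iri, [])
        for v in _as_list(value):
            out[iri].append(_expand_value(v, key, ctx))
    return out


def _expand_value(v, term: str, ctx: _CtxState):
    if isinstance(v, dict):
        if "@value" in v:
            vo = {"@value": v["@value"]}
            if "@type" in v:
                vo["@type"] = ctx.expand_iri(v["@type"], vocab=True)
            if "@language" in v:
                vo["@language"] = v["@language"]
            return vo
        if set(v) == {"@id"}:
            return {"@id": ctx.expand_iri(v["@id"], vocab=False, document_relative=True)}
        return _expand_node(v, ctx)
    ttype = ctx.term_type(term)
    if isinstance(v, str):
        if ttype == "@id":
            return {"@id": ctx.expand_iri(v, vocab=False, document_relative=True)}
        if ttype:
            return {"@value": v, "@type": ttype}
        return {"@value": v}
    return {"@value": v}


def compact(expanded, ctx: Context | dict, registry: ContextRegistry | None = None) -> dict:
    """Compact an expanded document with the given context (inverse of expand)."""
    if isinstance(ctx, Context):
        raw = ctx.to_jsonld()
    else:
        raw = ctx
    state = parse_context(raw, registry)
    nodes = expanded if isinstance(expanded, list) else [expanded]
    if not nodes:
        return {"@context": raw}
    body = _compact_node(nodes[0], state)
    return canonical_order({"@context": raw, **body})


def _inverse_terms(state: _CtxState):
    inv: dict[str, list[str]] = {}
    for alias in sorted(state.terms):
        iri = state.expand_iri(state.terms[alias], vocab=True) or state.terms[alias]
        inv.setdefault(iri, []).append(alias)
    return inv


def _compact_iri(iri: str, state: _CtxState, relative: bool = True) -> str:
    if relative and state.base and iri != state.base and iri.startswith(state.base):
        return iri[len(state.base):]
    candidates = []
    for alias, ns_or_iri in state.terms.items():
        ns = state.expand_iri(ns_or_iri, vocab=True) or ns_or_iri
        if not ns.endswith(("#", "/", ":")):
            continue  # only namespace-shaped terms act as prefixes
        if iri.startswith(ns) and len(iri) > len(ns):
            # longest namespace wins; ties break on the alphabetically first alias
            candidates.append((-len(ns), alias, f"{alias}:{iri[len(ns):]}"))
    if candidates:
        return min(candidates)[2]
    return iri


def _compact_node(node: dict, state: _CtxState) -> dict:
    inv = _inverse_terms(state)
    out: dict = {}
    for key, values in node.items():
        if key == "@id":
            out["@id"] = _compact_iri(values, state)
            continue
        if key == "@type":
            types = [_compact_iri(t, state, relative=False) for t in values]
            out["@type"] = types[0] if len(types) == 1 else types
            continue
        aliases = inv.get(key)
        alias = _pick_alias(aliases, values, state) if aliases else _compact_iri(
            key, state, relative=False)
        compacted = [_compact_value(v, alias, state) for v in values]
        out[alias] = compacted[0] if len(compacted) == 1 else compacted
    return out


def _pick_alias(aliases: list[str], values: list, state: _CtxState) -> str:
    all_refs = values and all(isinstance(v, dict) and set(v) == {"@id"} for v in values)
    for alias in aliases:
        if (state.types.get(alias) == "@id") == bool(all_refs):
            return alias
    return aliases[0]


def _compact_value(v, alias: str, state: _CtxState):
    if isinstance(v, dict) and "@value" in v:
        ttype = state.term_type(alias)
        if "@type" in v:
            if ttype and v["@type"] == ttype:
                return v["@value"]
            return {"@value": v["@value"], "@type": _compact_iri(v["@type"], state, relative=False)}
        if "@language" in v:
            return {"@value": v["@value"], "@language": v["@language"]}
        return v["@value"]
    if isinstance(v, dict) and set(v) == {"@id"}:
        if state.types.get(alias) == "@id":
            return _compact_iri(v["@id"], state)
        return {"@id": _compact_iri(v["@id"], state)}
    if isinstance(v, dict):
        return _compact_node(v, state)
    return v


# --------------------------------------------------------------------------
# deserialization (JSON-LD -> model)

def _load_json(doc_or_text):
    if isinstance(doc_or_text, dict):
        return doc_or_text
    try:
        return json.loads(doc_or_text)
    except json.JSONDecodeError as e:
        raise ParseError(f"malformed JSON: {e.msg}", line=e.lineno) from None


def deserialize(text, registry: ContextRegistry | None = None) -> m.SciDataDocument:
    """Rebuild a :class:`SciDataDocument` from JSON-LD text.

    Accepts inline contexts and external context references (resolved
    through ``registry``).  ``deserialize(serialize(doc))`` is
    model-equal to ``doc``.
    """
    obj = _load_json(text)
    if "@context" not in obj:
        raise ParseError("document has no @context")
    ctx = parse_context(obj["@context"], registry)
    if not ctx.base:
        raise ParseError("document context declares no @base")
    vocab_ns = ctx.terms.get("sci") or ctx.vocab or ""

    def strip_sci(value: str) -> str:
        iri = ctx.expand_iri(value, vocab=True) or value
        return iri[len(vocab_ns):] if vocab_ns and iri.startswith(vocab_ns) else iri

    doc = m.SciDataDocument(base_iri=ctx.base, doc_id=obj.get("@id", ctx.base))
    doc.context_ref = ctx.external_refs[0] if ctx.external_refs else None

    for key, value in obj.items():
        if key.startswith("@") or key in ("toc", "scidata"):
            continue
        doc.root_metadata[key] = _parse_metadata_value(value)
    doc.toc = {strip_sci(t) for t in _as_list(obj.get("toc"))}

    sd = obj.get("scidata", {})
    container = doc.scidata
    container.discipline = sd.get("discipline")
    container.subdiscipline = sd.get("subdiscipline")
    container.property_list = [str(p) for p in _as_list(sd.get("properties"))]
    if "methodology" in sd:
        meth = sd["methodology"]
        container.methodology = m.Methodology(evaluation=meth.get("evaluation"))
        for a in _as_list(meth.get("aspects")):
            aspect = m.Aspect(aspect_id=a.get("@id", ""), kind=strip_sci(a.get("@type", "")),
                              metadata=_parse_metadata_map(a))
            container.methodology.aspects.append(aspect)
            doc.note_id(aspect.aspect_id)
    if "system" in sd:
        container.system = m.System()
        for f in _as_list(sd["system"].get("facets")):
            facet = m.Facet(facet_id=f.get("@id", ""), kind=strip_sci(f.get("@type", "")),
                            metadata=_parse_metadata_map(f))
            container.system.facets.append(facet)
            doc.note_id(facet.facet_id)
    if "dataset" in sd:
        ds = sd["dataset"]
        container.dataset = m.Dataset(
            source_refs=_as_list(ds.get("source")), scope_refs=_as_list(ds.get("scope")))
        for p in _as_list(ds.get("datapoint")):
            container.dataset.datapoints.append(_parse_datapoint(p, doc))
        for s in _as_list(ds.get("dataseries")):
            container.dataset.dataseries.append(_parse_dataseries(s, doc))
        for g in _as_list(ds.get("datagroup")):
            container.dataset.datagroups.append(_parse_datagroup(g, doc, strip_sci))
    return doc


def _is_parameter_obj(v) -> bool:
    return isinstance(v, dict) and any(
        t.endswith("parameter") or t == "sci:parameter" for t in _as_list(v.get("@type")))


def _parse_metadata_map(node: dict) -> dict:
    return {k: _parse_metadata_value(v) for k, v in node.items() if not k.startswith("@")}


def _parse_metadata_value(v):
    if _is_parameter_obj(v):
        return _parse_parameter(v)
    if isinstance(v, dict) and "@value" in v:
        if str(v.get("@type", "")).endswith("decimal"):
            return Decimal(v["@value"])
        return v["@value"]
    if isinstance(v, dict):
        return {k: _parse_metadata_value(x) for k, x in v.items() if not k.startswith("@")}
    if isinstance(v, list):
        return [_parse_metadata_value(x) for x in v]
    return v


def _parse_numeric(node: dict) -> NumericValue:
    num = node["number"]
    lexical = str(num["@value"]) if isinstance(num, dict) else str(num)
    ntype = node.get("numbertype")
    if ntype is None and isinstance(num, dict):
        ntype = _NUMERIC_TYPE_BY_XSD.get(num.get("@type", ""), "decimal")
    err = node.get("error")
    return NumericValue(
        number=lexical, numeric_type=ntype or "decimal",
        sigfigs=node.get("sigfigs"),
        error=Decimal(err["@value"]) if isinstance(err, dict) else (
            Decimal(str(err)) if err is not None else None),
        exact=bool(node.get("exact", False)),
    )


def _parse_text(node: dict) -> TextValue:
    t = node["text"]
    if isinstance(t, dict):
        return TextValue(text=t["@value"], text_type=node.get("texttype", "plain"),
                         language=t.get("@language"))
    return TextValue(text=t, text_type=node.get("texttype", "plain"))


def _parse_unit(node: dict) -> Unit:
    mult = node.get("multiplier", "1")
    off = node.get("offset", "0")
    return Unit(
        symbol=node.get("symbol", ""),
        quantity_kind=node.get("quantitykind", ""),
        si_base_expansion=parse_expansion(node.get("dimensions", "")),
        multiplier_to_si=Decimal(mult["@value"]) if isinstance(mult, dict) else Decimal(str(mult)),
        offset_to_si=Decimal(off["@value"]) if isinstance(off, dict) else Decimal(str(off)),
        prefix=node.get("prefix"),
    )


def _parse_parameter(node: dict) -> Parameter:
    if "value" in node:
        value = _parse_numeric(node["value"])
    elif "textstring" in node:
        value = _parse_text(node["textstring"])
    else:
        value = [_parse_numeric(v) if "number" in v else _parse_text(v)
                 for v in _as_list(node.get("values"))]
    spec = None
    if "unitstr" in node:
        spec = UnitSpec.from_str(node["unitstr"])
    elif "unitref" in node:
        spec = UnitSpec.from_ref(node["unitref"])
    elif "unit" in node:
        spec = UnitSpec.from_unit(_parse_unit(node["unit"]))
    return Parameter(property=node.get("property", ""), value=value,
                     quantity=node.get("quantity"), unit_spec=spec,
                     param_id=node.get("@id"))


def _parse_series_value(v):
    if isinstance(v, dict) and "@value" in v:
        return Decimal(v["@value"]) if str(v.get("@type", "")).endswith(
            ("decimal", "double", "float")) else v["@value"]
    return v


def _parse_datapoint(node: dict, doc: m.SciDataDocument) -> m.Datapoint:
    dp = m.Datapoint(
        point_id=node.get("@id", ""),
        parameters=[_parse_parameter(p) for p in _as_list(node.get("parameter"))],
        source_refs=_as_list(node.get("source")), scope_refs=_as_list(node.get("scope")))
    doc.note_id(dp.point_id)
    return dp


def _parse_dataseries(node: dict, doc: m.SciDataDocument) -> m.Dataseries:
    refs = _as_list(node.get("valuerefs"))
    series = m.Dataseries(
        series_id=node.get("@id", ""),
        parameter=_parse_parameter(node["parameter"]),
        values=refs if refs else [_parse_series_value(v) for v in _as_list(node.get("values"))],
        label=node.get("label", ""),
        values_are_refs=bool(refs))
    doc.note_id(series.series_id)
    return series


def _parse_datagroup(node: dict, doc: m.SciDataDocument, strip_sci) -> m.Datagroup:
    members = []
    for mem in _as_list(node.get("members")):
        if set(mem) == {"@id"}:
            members.append(mem["@id"])
        else:
            kind = strip_sci(_as_list(mem.get("@type"))[0]) if mem.get("@type") else ""
            if kind == "datagroup":
                members.append(_parse_datagroup(mem, doc, strip_sci))
            elif kind == "dataseries":
                members.append(_parse_dataseries(mem, doc))
            else:
                members.append(_parse_datapoint(mem, doc))
    group = m.Datagroup(
        group_id=node.get("@id", ""), kind=node.get("kind", ""),
        members=members,
        attributes=[_parse_parameter(p) for p in _as_list(node.get("attributes"))],
        source_refs=_as_list(node.get("source")), scope_refs=_as_list(node.get("scope")))
    doc.note_id(group.group_id)
    return group
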