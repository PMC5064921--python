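"""Domain model for SciData documents.

A :class:`SciDataDocument` packages provenance metadata, a table of
contents, and a ``scidata`` container holding the three sections that
describe a piece of research: how it was done (methodology *aspects*),
what it was done on (system *facets*), and what was found (the
*dataset*, organized as datapoints, dataseries and nestable
datagroups).  Dataset elements link back to aspects via ``source`` and
to facets via ``scope`` references.

Identifiers are minted per element kind as 1-based ordinals with a
trailing slash (``measurement/1/``, ``datapoint/2/``) and resolve
against the document base IRI.  Construction is permissive — dangling
references are allowed while a document is being assembled — and
:func:`validate` is the single enforcement point for the model
invariants.
"""

from __future__ import annotations

import difflib
import re
from dataclasses import dataclass, field
from urllib.parse import urlsplit

from .errors import CycleError, ModelError, NotFoundError
from .quantity import NumericValue, Parameter, TextValue, UnitSpec
from .vocabulary import Vocabulary, default_vocabulary

DATASET_ELEMENT_KINDS = ("datapoint", "dataseries", "datagroup")


@dataclass
class Aspect:
    """One methodology component: how the data was obtained."""

    aspect_id: str
    kind: str
    metadata: dict = field(default_factory=dict)


@dataclass
class Facet:
    """One system component: what the data is about."""

    facet_id: str
    kind: str
    metadata: dict = field(default_factory=dict)


@dataclass
class Methodology:
    evaluation: str | None = None
    aspects: list[Aspect] = field(default_factory=list)


@dataclass
class System:
    facets: list[Facet] = field(default_factory=list)


@dataclass
class Datapoint:
    """An individual value report; order among datapoints carries no meaning."""

    point_id: str
    parameters: list[Parameter]
    source_refs: list[str] = field(default_factory=list)
    scope_refs: list[str] = field(default_factory=list)


@dataclass
class Dataseries:
    """An ordered, correlated array of values for one quantity.

    ``values`` is either an inline array of numbers/texts or, when
    ``values_are_refs`` is set, an array of IRIs pointing at datapoints.
    """

    series_id: str
    parameter: Parameter
    values: list
    label: str = ""
    values_are_refs: bool = False


@dataclass
class Datagroup:
    """A nestable aggregate of dataset elements."""

    group_id: str
    kind: str
    members: list = field(default_factory=list)  # Datagroup | Dataseries | Datapoint | str IRI
    attributes: list[Parameter] = field(default_factory=list)
    source_refs: list[str] = field(default_factory=list)
    scope_refs: list[str] = field(default_factory=list)


@dataclass
class Dataset:
    datagroups: list[Datagroup] = field(default_factory=list)
    dataseries: list[Dataseries] = field(default_factory=list)
    datapoints: list[Datapoint] = field(default_factory=list)
    source_refs: list[str] = field(default_factory=list)
    scope_refs: list[str] = field(default_factory=list)


@dataclass
class ScidataContainer:
    discipline: str | None = None
    subdiscipline: str | None = None
    methodology: Methodology | None = None
    system: System | None = None
    dataset: Dataset | None = None
    property_list: list[str] = field(default_factory=list)


@dataclass
class SciDataDocument:
    base_iri: str
    doc_id: str
    root_metadata: dict = field(default_factory=dict)
    toc: set[str] = field(default_factory=set)
    scidata: ScidataContainer = field(default_factory=ScidataContainer)
    #: None → inline context; IRI string → external context reference
    context_ref: str | None = None
    _counters: dict = field(default_factory=dict, compare=False, repr=False)

    def mint_id(self, kind: str) -> str:
        n = self._counters.get(kind, 0) + 1
        self._counters[kind] = n
        return f"{kind}/{n}/"

    def note_id(self, element_id: str) -> None:
        """Advance counters past an externally supplied id (deserialization)."""
        m = re.fullmatch(r"(.+?)/(\d+)/", element_id)
        if m:
            kind, n = m.group(1), int(m.group(2))
            self._counters[kind] = max(self._counters.get(kind, 0), n)


@dataclass
class ValidationIssue:
    severity: str  # "error" | "warning"
    path: str
    message: str


# --------------------------------------------------------------------------
# builders

def build_document(root_metadata: dict, base_iri: str) -> SciDataDocument:
    """Create an empty document rooted at an absolute base IRI.

    The base must be an absolute http(s) IRI ending in a path delimiter;
    the document id is minted as the base itself.
    """
    parts = urlsplit(base_iri)
    if parts.scheme not in ("http", "https") or not parts.netloc:
        raise ModelError(f"base IRI must be absolute http(s), got {base_iri!r}")
    if not base_iri.endswith("/"):
        raise ModelError(f"base IRI must end with a path delimiter: {base_iri!r}")
    if re.search(r"\s", base_iri):
        raise ModelError(f"base IRI must not contain whitespace: {base_iri!r}")
    return SciDataDocument(base_iri=base_iri, doc_id=base_iri,
                           root_metadata=dict(root_metadata))


def add_aspect(doc: SciDataDocument, kind: str, metadata: dict | None = None) -> Aspect:
    """Append a methodology aspect; ids are per-kind ordinals."""
    if not kind:
        raise ModelError("aspect kind must be non-empty")
    if doc.scidata.methodology is None:
        doc.scidata.methodology = Methodology()
    aspect = Aspect(aspect_id=doc.mint_id(kind), kind=kind, metadata=dict(metadata or {}))
    doc.scidata.methodology.aspects.append(aspect)
    return aspect


def add_facet(doc: SciDataDocument, kind: str, metadata: dict | None = None) -> Facet:
    """Append a system facet; ids are per-kind ordinals."""
    if not kind:
        raise ModelError("facet kind must be non-empty")
    if doc.scidata.system is None:
        doc.scidata.system = System()
    facet = Facet(facet_id=doc.mint_id(kind), kind=kind, metadata=dict(metadata or {}))
    doc.scidata.system.facets.append(facet)
    return facet


def _ensure_dataset(doc: SciDataDocument) -> Dataset:
    if doc.scidata.dataset is None:
        doc.scidata.dataset = Dataset()
    return doc.scidata.dataset


def add_datapoint(doc: SciDataDocument, parameters: list[Parameter],
                  source_refs=(), scope_refs=()) -> Datapoint:
    """Append a datapoint.  References may be dangling until validate."""
    if not parameters:
        raise ModelError("a datapoint requires at least one parameter")
    point = Datapoint(point_id=doc.mint_id("datapoint"), parameters=list(parameters),
                      source_refs=list(source_refs), scope_refs=list(scope_refs))
    _ensure_dataset(doc).datapoints.append(point)
    return point


def add_dataseries(doc: SciDataDocument, parameter: Parameter, values: list,
                   label: str = "", values_are_refs: bool = False,
                   into: Datagroup | None = None) -> Dataseries:
    """Append a dataseries, directly under the dataset or into a datagroup."""
    if not values:
        raise ModelError("a dataseries requires non-empty values")
    series = Dataseries(series_id=doc.mint_id("dataseries"), parameter=parameter,
                        values=list(values), label=label, values_are_refs=values_are_refs)
    if into is not None:
        into.members.append(series)
    else:
        _ensure_dataset(doc).dataseries.append(series)
    return series


def add_datagroup(doc: SciDataDocument, kind: str, members=(), attributes=(),
                  source_refs=(), scope_refs=(),
                  into: Datagroup | None = None) -> Datagroup:
    """Append a datagroup; nesting must stay a finite tree (no cycles)."""
    if not kind:
        raise ModelError("datagroup kind must be non-empty")
    group = Datagroup(group_id=doc.mint_id("datagroup"), kind=kind,
                      members=[], attributes=list(attributes),
                      source_refs=list(source_refs), scope_refs=list(scope_refs))
    target = group  # members are added through add_to_group for cycle checking
    for m in members:
        add_to_group(target, m)
    if into is not None:
        add_to_group(into, group)
    else:
        _ensure_dataset(doc).datagroups.append(group)
    return group


def add_to_group(group: Datagroup, member) -> None:
    """Add a member to a datagroup, refusing reference cycles."""
    if isinstance(member, Datagroup):
        if member is group or _contains_group(member, group):
            raise CycleError(
                f"adding {member.group_id!r} to {group.group_id!r} would create a cycle")
    group.members.append(member)


def _contains_group(group: Datagroup, target: Datagroup) -> bool:
    for m in group.members:
        if isinstance(m, Datagroup) and (m is target or _contains_group(m, target)):
            return True
    return False


# --------------------------------------------------------------------------
# traversal

def iter_groups(dataset: Dataset):
    stack = list(dataset.datagroups)
    while stack:
        g = stack.pop(0)
        yield g
        stack.extend(m for m in g.members if isinstance(m, Datagroup))


def iter_elements(doc: SciDataDocument):
    """Yield (relative_id, element) for every addressable element."""
    sd = doc.scidata
    if sd.methodology:
        for a in sd.methodology.aspects:
            yield a.aspect_id, a
    if sd.system:
        for f in sd.system.facets:
            yield f.facet_id, f
    if sd.dataset:
        seen_series, seen_points = [], []
        for g in iter_groups(sd.dataset):
            yield g.group_id, g
            for m in g.members:
                if isinstance(m, Dataseries):
                    seen_series.append(m)
                elif isinstance(m, Datapoint):
                    seen_points.append(m)
        for s in sd.dataset.dataseries + seen_series:
            yield s.series_id, s
        for p in sd.dataset.datapoints + seen_points:
            yield p.point_id, p


def iter_parameters(doc: SciDataDocument):
    """Yield every Parameter reachable in the document."""
    for _rid, el in iter_elements(doc):
        if isinstance(el, Datapoint):
            yield from el.parameters
        elif isinstance(el, Dataseries):
            yield el.parameter
        elif isinstance(el, Datagroup):
            yield from el.attributes
        elif isinstance(el, (Aspect, Facet)):
            for v in el.metadata.values():
                if isinstance(v, Parameter):
                    yield v


# --------------------------------------------------------------------------
# toc, resolution, validation

def _toc_kinds(doc: SciDataDocument) -> set[str]:
    kinds: set[str] = set()
    sd = doc.scidata
    if sd.methodology:
        kinds.update(a.kind for a in sd.methodology.aspects)
    if sd.system:
        kinds.update(f.kind for f in sd.system.facets)
    if sd.dataset:
        ids = [rid for rid, el in iter_elements(doc)
               if isinstance(el, (Datapoint, Dataseries, Datagroup))]
        for rid in ids:
            kinds.add(rid.split("/", 1)[0])
    return kinds


def compute_toc(doc: SciDataDocument) -> list[str]:
    """Derive the table of contents and update the document in place.

    Returns the sorted, deduplicated set of element kinds: each distinct
    aspect kind, facet kind, and dataset element kind present.
    """
    kinds = _toc_kinds(doc)
    doc.toc = set(kinds)
    return sorted(kinds)


def resolve_ref(doc: SciDataDocument, iri: str):
    """Return the element whose minted IRI equals ``iri``.

    Accepts absolute IRIs under the document base as well as
    base-relative fragments (``substance/1/``).
    """
    rel = iri[len(doc.base_iri):] if iri.startswith(doc.base_iri) else iri
    index = dict(iter_elements(doc))
    if rel in index:
        return index[rel]
    raise NotFoundError(f"no element with IRI {iri!r}",
                        candidates=difflib.get_close_matches(rel, index, n=3))


def validate(doc: SciDataDocument, vocabulary: Vocabulary | None = None) -> list[ValidationIssue]:
    """Check every model invariant; returns issues instead of raising.

    The list is empty exactly when all references resolve, ids are
    unique, the toc matches the content, parameters are well-formed and
    units are well-formed.  Severity "warning" marks recoverable
    problems (a stale toc); everything else is "error".
    """
    issues: list[ValidationIssue] = []
    err = lambda path, msg: issues.append(ValidationIssue("error", path, msg))
    warn = lambda path, msg: issues.append(ValidationIssue("warning", path, msg))

    elements = list(iter_elements(doc))
    index: dict[str, object] = {}
    for rid, el in elements:
        if rid in index and index[rid] is not el:
            err(rid, f"duplicate element id {rid!r}")
        index[rid] = el

    def check_refs(owner: str, refs: list[str], label: str):
        for ref in refs:
            rel = ref[len(doc.base_iri):] if ref.startswith(doc.base_iri) else ref
            if rel not in index:
                err(owner, f"{label} reference {ref!r} does not resolve")

    sd = doc.scidata
    if sd.methodology and sd.methodology.aspects and not sd.methodology.evaluation:
        err("methodology", "evaluation must be present when aspects are non-empty")
    if sd.dataset:
        check_refs("dataset", sd.dataset.source_refs, "source")
        check_refs("dataset", sd.dataset.scope_refs, "scope")
    for rid, el in elements:
        if isinstance(el, (Datapoint, Datagroup)):
            check_refs(rid, el.source_refs, "source")
            check_refs(rid, el.scope_refs, "scope")
        if isinstance(el, Datapoint) and not el.parameters:
            err(rid, "datapoint has no parameters")
        if isinstance(el, Dataseries):
            if not el.values:
                err(rid, "dataseries has empty values")
            if el.values_are_refs:
                for ref in el.values:
                    rel = ref[len(doc.base_iri):] if ref.startswith(doc.base_iri) else ref
                    target = index.get(rel)
                    if target is None:
                        err(rid, f"series value reference {ref!r} does not resolve")
                    elif not isinstance(target, Datapoint):
                        err(rid, f"series value reference {ref!r} is not a datapoint")
        if isinstance(el, Datagroup):
            for m in el.members:
                if isinstance(m, str):
                    rel = m[len(doc.base_iri):] if m.startswith(doc.base_iri) else m
                    if rel not in index:
                        err(rid, f"member reference {m!r} does not resolve")

    # cycle check over datagroup nesting
    if sd.dataset:
        on_path: set[int] = set()

        def walk(g: Datagroup):
            if id(g) in on_path:
                err(g.group_id, "datagroup nesting contains a cycle")
                return
            on_path.add(id(g))
            for m in g.members:
                if isinstance(m, Datagroup):
                    walk(m)
            on_path.discard(id(g))

        for g in sd.dataset.datagroups:
            walk(g)

    # parameter and unit well-formedness (beyond constructor checks)
    for param in iter_parameters(doc):
        path = param.param_id or param.property
        if not param.property:
            err(path, "parameter property is empty")
        if not isinstance(param.value, (NumericValue, TextValue, list)):
            err(path, f"parameter value has unsupported type {type(param.value).__name__}")
        spec = param.unit_spec
        if isinstance(spec, UnitSpec) and spec.form == "unitref":
            ref = spec.unitref
            is_external = not ref.startswith(doc.base_iri) and re.match(
                r"^[a-zA-Z][a-zA-Z0-9+.-]*:", ref)
            if not is_external:
                from .quantity import document_units
                rel = ref[len(doc.base_iri):] if ref.startswith(doc.base_iri) else ref
                if rel not in document_units(doc):
                    err(path, f"internal unit reference {ref!r} does not resolve")

    # toc consistency
    actual = _toc_kinds(doc)
    for stale in sorted(doc.toc - actual):
        warn("toc", f"stale toc entry {stale!r}")
    for missing in sorted(actual - doc.toc):
        warn("toc", f"toc is missing entry {missing!r}")

    return issues


def unannotated_keys(doc: SciDataDocument, vocabulary: Vocabulary | None = None) -> list[str]:
    """Metadata keys with no vocabulary term: retained but unannotated."""
    vocab = vocabulary or default_vocabulary()
    keys: set[str] = set(doc.root_metadata)
    for _rid, el in iter_elements(doc):
        if isinstance(el, (Aspect, Facet)):
            keys.update(el.metadata)
    return sorted(k for k in keys if k not in vocab)
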