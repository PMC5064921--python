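"""Bundled vocabulary registry for the scientific data model ontology (SDMO).

Every structural term the model serializes — the framework terms — is
registered here, grouped into the ontology's six classes: metadata,
context, dataset, methodology, scientific data, and unit of measure.
Alongside the framework terms the registry reproduces the handful of
external terms the model leans on (Dublin Core document metadata,
CHEMINF substance identifiers); these are tracked separately so counts
of framework-specific terms stay honest.

The SDMO namespace IRI is configurable; compact ``sci:`` IRIs in the
bundled table expand against it lazily.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass
from importlib import resources

from .errors import ModelError, NotFoundError

CLASS_GROUPS = (
    "metadata", "context", "dataset", "methodology", "scientific data", "unit of measure",
)

#: Default SDMO namespace, after the model's project site; override per registry.
DEFAULT_SDMO_NAMESPACE = "http://stuchalk.github.io/scidata/ontology/scidata.owl#"

EXTERNAL_NAMESPACES = {
    "dcterms": "http://purl.org/dc/terms/",
    "cheminf": "http://semanticscience.org/resource/",
}


@dataclass
class VocabularyTerm:
    term_name: str
    class_group: str
    term_iri: str
    definition: str = ""
    source_vocab: str = "sdmo"

    def __post_init__(self):
        if self.class_group not in CLASS_GROUPS:
            raise ModelError(f"unknown class group {self.class_group!r}")


class Vocabulary:
    """Exact-name term registry with a configurable SDMO namespace."""

    def __init__(self, sdmo_namespace: str = DEFAULT_SDMO_NAMESPACE):
        self.sdmo_namespace = sdmo_namespace
        self._terms: dict[str, VocabularyTerm] = {}
        self._load_bundled()

    def _load_bundled(self):
        text = resources.files("scidata").joinpath("data/vocabulary.tsv").read_text()
        for line in text.strip().splitlines()[1:]:
            name, group, iri, definition, source = line.split("\t")
            if iri.startswith("sci:"):
                iri = self.sdmo_namespace + iri[len("sci:"):]
            self.register(VocabularyTerm(name, group, iri, definition, source))

    def register(self, term: VocabularyTerm) -> VocabularyTerm:
        if term.term_name in self._terms:
            raise ModelError(f"term {term.term_name!r} already registered")
        self._terms[term.term_name] = term
        return term

    def terms(self) -> list[VocabularyTerm]:
        return list(self._terms.values())

    def lookup(self, name: str) -> VocabularyTerm:
        try:
            return self._terms[name]
        except KeyError:
            raise NotFoundError(
                f"no vocabulary term named {name!r}",
                candidates=difflib.get_close_matches(name, self._terms, n=3),
            ) from None

    def __contains__(self, name: str) -> bool:
        return name in self._terms

    def sdmo_terms(self) -> list[VocabularyTerm]:
        """Framework-specific terms only (external reproductions excluded)."""
        return [t for t in self._terms.values() if t.source_vocab == "sdmo"]

    def export_tsv(self) -> str:
        """Term table as TSV: name, class_group, IRI, definition."""
        lines = ["name\tclass_group\tiri\tdefinition"]
        for t in self._terms.values():
            lines.append(f"{t.term_name}\t{t.class_group}\t{t.term_iri}\t{t.definition}")
        return "\n".join(lines) + "\n"


_DEFAULT: Vocabulary | None = None


def default_vocabulary() -> Vocabulary:
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = Vocabulary()
    return _DEFAULT


def vocabulary_terms() -> list[VocabularyTerm]:
    """All registered terms in the default registry."""
    return default_vocabulary().terms()


def term_lookup(name: str) -> VocabularyTerm:
    """Exact-match lookup in the default registry; NotFoundError otherwise."""
    return default_vocabulary().lookup(name)
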