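# scidata

A Python implementation of the **SciData scientific data model**: a
generic, discipline-agnostic framework for packaging scientific data
*together with the context that gives it meaning* — how it was obtained
(methodology), what it is about (system), and the data itself
(dataset) — serialized as JSON-LD so that it converts losslessly to RDF
and becomes searchable across heterogeneous collections.

It is aimed at people building data pipelines around laboratory,
literature-extracted or computed results — electronic-notebook
developers, cheminformatics engineers, data curators — who need their
records to be both human-readable files and machine-queryable graphs.

## The model

A document is a "data packet":

```
@context            term definitions, namespace prefixes, @vocab, @base
@id                 document IRI (minted from a base IRI)
title / authors / … provenance metadata (Dublin Core terms)
toc                 kinds of content present, for search scoping
scidata
├── discipline, subdiscipline
├── methodology     evaluation (experimental | computational | theoretical)
│   └── aspects     measurement, procedure, calculation, basisset, software, …
├── system
│   └── facets      substance, condition, organism, material, …
└── dataset
    ├── datapoint   unrelated single values
    ├── dataseries  ordered correlated arrays
    └── datagroup   nestable aggregates
```

Dataset elements link back to aspects (`source`) and facets (`scope`).
The recurring unit of reporting is the **parameter** — a property name,
optional quantity, a numeric or textual value, and a unit given as an
opaque string (`unitstr`), an in-place definition (`unit`: quantity
kind, SI base-dimension exponents, affine factor to SI), or a reference
(`unitref`). Numeric values carry their printed form, significant
figures, uncertainty and exactness. Every framework term is defined in
a bundled vocabulary registry (72 terms in six classes), so each JSON
key resolves to an ontology IRI and documents RDF-ize deterministically
into subject–predicate–object triples.

Around the core model the package provides: a JSON-LD codec
(expand/compact, inline or external contexts), an N-Quads writer/reader
with deterministic blank-node labels, an in-memory quad store with
basic-graph-pattern matching, a JCAMP-DX reader that converts spectra
into the model, and generators for the four canonical example documents
(pH, refractive index, NMR spectrum, SCF calculation).

## Worked example

```python
import scidata as sd
from scidata import rdfizer, graphquery as gq
from scidata.rdfizer import RdfLiteral
from scidata.vocabulary import default_vocabulary

doc = sd.build_document(
    {"title": "pH of a buffer solution", "authors": ["A. Chemist", "B. Chemist"]},
    "https://lab.example.org/notebook/42/")
doc.scidata.discipline = "chemistry"
doc.scidata.methodology = sd.Methodology(evaluation="experimental")
aspect = sd.add_aspect(doc, "measurement", {"technique": "potentiometry"})
facet = sd.add_facet(doc, "substance", {"name": "phosphate buffer"})
sd.add_datapoint(
    doc,
    [sd.make_parameter("pH", sd.NumericValue("7.41", sigfigs=3), quantity="pH")],
    source_refs=[aspect.aspect_id], scope_refs=[facet.facet_id])

print(sd.compute_toc(doc))       # ['datapoint', 'measurement', 'substance']
print(sd.validate(doc))          # []  — every reference resolves, ids unique

triples = rdfizer.to_triples(doc)
print(len(triples))              # 35

store = gq.ingest(gq.QuadStore(), triples)
ns = default_vocabulary().sdmo_namespace
print(gq.match(store, [gq.Pattern("?p", ns + "property", RdfLiteral("pH"), "?doc")]))
# [{'?p': 'https://lab.example.org/notebook/42/datapoint/1/parameter/1/',
#   '?doc': 'https://lab.example.org/notebook/42/'}]
```

The toc says what kinds of content the packet holds; `validate` returns
an empty issue list for a well-formed document; RDF-izing the packet
yields 35 triples in a named graph (the document IRI), and a one-pattern
graph query finds the pH parameter and the document reporting it.
Sibling utilities behave the same way:
`sd.format_sigfigs(0.0123454, 4)` → `"0.01235"`, and converting
25.0 °C to kelvin gives `298.15` with its 3 significant figures intact.

The same operations are scriptable from the shell:

```sh
scidata fixture ph --out ph.jsonld      # one of the bundled examples
scidata validate ph.jsonld              # exit 0, issues as JSON on stderr
scidata triples ph.jsonld --out ph.nq   # canonical N-Quads
scidata convert spectrum.jdx --out spectrum.jsonld   # JCAMP-DX import
scidata query ph.nq --query query.yaml  # BGP query from a YAML config
```

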