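# Methods

This note records how the package interprets the scientific data model,
the conventions it fixes where the model leaves choices open, and what
its tests do and do not demonstrate.

## The data model and its invariants

A document is a tree: provenance metadata and a `toc` at the root, and
a `scidata` container with three optional sections. *Methodology* holds
an `evaluation` flag (experimental / computational / theoretical — free
text, those three conventional) and an ordered list of *aspects*, each
an open metadata map of a given kind (`measurement`, `procedure`,
`calculation`, `basisset`, `software`, …). *System* holds *facets* of
the same shape (`substance`, `condition`, `material`, `organism`, …).
*Dataset* holds `datapoint`s (independent value reports), `dataseries`
(ordered correlated arrays, inline or as IRI links to datapoints) and
`datagroup`s (nestable aggregates). Dataset elements carry `source`
links into aspects and `scope` links into facets; the structural terms
deliberately carry no scientific semantics of their own — meaning comes
from the linked context and from the vocabulary annotations.

Invariants enforced: ids unique per document, all internal references
resolvable, series values non-empty, datagroup nesting acyclic, an
`evaluation` present whenever aspects exist, and a `toc` equal to the
derivable set of kinds. Construction is deliberately permissive —
references may dangle while a document is being assembled — and
`validate()` is the single enforcement point, returning machine-readable
issues (severity, path, message) rather than raising. A stale `toc` is a
warning; everything else is an error. Metadata keys without a vocabulary
entry are *not* validation issues: they are legal ("annotated or not" is
a feature of the model), surfaced by `unannotated_keys()` and by context
building, and rejected only by strict-mode serialization.

**Identifier minting.** Elements get `<kind>/<ordinal>/` ids with
1-based per-kind counters and a trailing slash (`measurement/1/`,
`datapoint/2/`), resolved against the document base IRI. They are
stable under append and human-readable. Parameters get structural ids
at serialization time (`datapoint/1/parameter/1/`), and a parameter's
value and in-place unit hang off it (`…/value/`, `…/unit/`), so a
parameter and its value are always separately addressable IRIs.
`assign_ids` recomputes these structurally and is idempotent.

**toc.** Entries are bare kind names in the model (aspect kinds, facet
kinds, and the dataset element classes present); the codec maps them to
vocabulary IRIs (`sci:datapoint`) on output. This keeps the model layer
format-free while making toc triples queryable for search scoping.

## Parameters, numbers, units

Numbers are carried as a decimal lexical form plus a `Decimal` value:
significant figures are metadata the model records, and "3.50" must
still read "3.50" after any number of round trips. Values may carry
`sigfigs` (≥ 1), a non-negative `error`, and an `exact` flag (exclusive
with `error`); integer-typed values must be integral.

`format_sigfigs` rounds half-even on decimal digits. Scientific
notation (`1.2e4`) is used when the magnitude exponent reaches 4, or
whenever a positional rendering would be ambiguous (trailing zeros left
of the decimal point, e.g. 2 significant figures of 120 → `1.2e2`).
A positional integer whose last significant digit sits in the ones
place (`10` from 9.99 @ 2 s.f.) is rendered positionally and read here
as all-digits-significant. The threshold (4) is a documented convention,
configurable via `quantity.SCI_NOTATION_THRESHOLD`.

Units are defined by quantity kind, an SI base-dimension exponent map,
and an affine map to coherent SI (`x_si = x·multiplier + offset`), the
shape QUDT uses for conversion factors. The bundled table
(`data/units.tsv`) ships the SI base and derived units plus ~20 common
chemistry units (L, atm, bar, mmHg, Torr, cal, eV, Da, Å, M, 1/cm, ppm,
%, °C, …), combinable with all SI prefixes; prefixing an affine unit is
rejected. Conversion requires identical quantity kind *and* dimension
map, runs at 40 decimal digits of precision, scales `error` linearly
(a single-value affine transform has no quadrature to do), and keeps
`exact` only when the decimal arithmetic itself was exact (so cm → m
preserves it, atm → mmHg does not). External `unitref` IRIs resolve to
offline stubs (`resolved=False`); this library never fetches anything.

## JSON-LD encoding

The codec implements the JSON-LD 1.0 feature subset the model needs —
term definitions, prefixes, `@vocab`, `@base`, `@id`, `@type`, typed
values — for both directions, and the test suite holds its RDF output
graph-isomorphic to rdflib's independent JSON-LD processor on every
fixture and on randomized documents.

Conventions fixed here:

- **Context.** One term definition per used key; `sci:` prefixes the
  model ontology namespace (the project site's ontology IRI by default;
  a `Vocabulary(sdmo_namespace=…)` overrides it), `dcterms:`/`cheminf:`
  cover the reproduced external terms, `@vocab` is the model namespace,
  `@base` the document base. IRI-valued terms (`toc`, `source`,
  `scope`, `unitref`, `valuerefs`) are typed `@id`. `build_context`
  emits absolute IRIs; `compact_context` rewrites them to prefix form
  (longest namespace wins, alphabetical alias on ties) and is
  idempotent.
- **Numbers** serialize as typed value objects with their lexical form
  (`{"@value": "3.28", "@type": "xsd:decimal"}`), the numeric type
  mapping to `xsd:decimal` / `integer` / `float` / `double`. Counts and
  flags use native JSON integers and booleans. Native JSON floats are
  avoided entirely, which sidesteps processor-dependent
  double-canonicalization.
- **Key order** is canonical (keywords first, then alphabetical) so
  files diff stably.
- **Singleton arrays** are written as scalars, per JSON-LD's set
  semantics, and re-wrapped by structure-aware deserialization; values
  inside open metadata maps therefore normalize singleton lists to
  scalars across a round trip, so the bundled fixtures use either
  scalars or ≥2-element lists there.
- **External contexts** resolve through a local `ContextRegistry`
  (IRI → payload, loadable from a directory with a `registry.yaml`
  map); an unknown IRI is an error naming that IRI. Offline by design.

Strict-mode serialization requires a clean `validate()` and a term
definition for every emitted key; non-strict keeps unannotated keys
(they expand under `@vocab`) and flags them on the context.

## RDF-ization and querying

`to_triples` = serialize → expand → walk: `@id`-bearing objects become
IRI nodes, anonymous objects become blank nodes labeled in depth-first
order, literals are typed per the value objects (plain strings collapse
to untagged literals, as RDF 1.1 prescribes). The named graph defaults
to the document IRI, giving per-document provenance in a quad store.
Identical documents yield byte-identical N-Quads because blank-node
labels are deterministic and lines are sorted. The N-Quads *reader* is
a small hand-written line parser: the read∘write identity contract
requires blank-node labels to survive, and general RDF parsers rename
them on input; a test cross-checks the reader against rdflib up to
relabeling.

The quad store keeps SPO/POS/OSP indexes with set semantics. Queries
are conjunctive basic graph patterns (constants or `?variables` in
subject/predicate/object and optionally the graph slot) plus equality
filters — exactly enough to express the canonical cross-document
search (find documents reporting a given property, about a substance
with a given InChIKey, in a given discipline) without a SPARQL grammar.
Patterns are evaluated smallest-candidate-first; solutions are sorted
by binding values, so pattern order never changes results. A
brute-force nested-loop join over the raw quad set serves as the
test oracle.

## JCAMP-DX

The reader handles single-block files: LDR splitting (label
normalization ignores case, spaces, dashes, underscores — the
dialect-tolerant comparison form), continuation lines, `$$` comments
(stripped, retained per record). Data tables decode in `(X++(Y..Y))`
form (x rebuilt from FIRSTX plus DELTAX or the FIRSTX/LASTX/NPOINTS
grid; ordinates scaled by YFACTOR) and `(XY..XY)` form (pairs scaled by
both factors). AFFN and PAC tokenizations are handled by one numeric
scanner; any alphabetic pseudo-digit — the SQZ/DIF/DUP compression
alphabets, and also exponent `E`, which is lexically ambiguous with the
SQZ digit for +5 — raises `UnsupportedEncodingError` rather than risk
silent corruption. A declared NPOINTS that disagrees with the decoded
count is an integrity error.

Conversion places the spectrum in a `spectrum` datagroup holding the x
and y dataseries (each series' parameter names the axis and records its
extent; the axis unit strings land as `unitstr`), sourced to a
`measurement` aspect and scoped to a `substance` facet. The
LDR-to-model mapping ships as editable YAML
(`data/jcamp_map.yaml`); unmapped LDRs land verbatim in the measurement
aspect under their lowercased label (serializable in non-strict mode).
NTUPLES/multi-block files and JCAMP writing are out of scope.

## Fixtures and what passing tests show

The four named fixtures mirror the model's canonical applications:
single datapoints with an observation (pH), a literature-extracted
value with its citation (refractive index), a two-series spectrum group
(NMR), and two-level nested groups (SCF calculation). Their numeric
values are structural placeholders in realistic ranges — the fixtures
assert model mechanics, not chemistry — and the substance identifiers
(InChIKeys) are opaque configuration strings. The randomized generator
samples documents over all builder paths (aspect/facet kinds, numeric /
text / array parameters, the three unit forms, series by value and by
reference, nested groups) with about 16 points per series and nesting
depth ≤ 2 by default: enough to exercise every serialization branch at
interactive speed. Synthetic JCAMP files draw 1–1024 points with
grid-exact DELTAX and y values that are exact multiples of YFACTOR, so
decoded values are compared at 1e-9 relative tolerance.

Passing tests therefore demonstrate structural and semantic fidelity of
the machinery — round-trip identity, processor-equivalent RDF, query
correctness — on documents of desk scale. They do not demonstrate
coverage of real-world JCAMP dialect quirks (compressed tables,
NTUPLES), nor performance beyond a few thousand quads, nor the
chemical correctness of any value.

## Problem sizes and numerical choices

Checks run at: 4 fixtures + 100 random documents for processor
agreement, 500 random documents for round trips, 200 random stores of
≤ 500 quads for query-oracle agreement, 100 JCAMP files of 1–1024
points, 150 random documents for toc agreement. Unit arithmetic uses
40-digit decimal precision; JCAMP decoding uses binary floats with a
1e-9 relative acceptance band; ties in significant-figure rounding go
half-even; degenerate inputs (empty documents, single-point spectra,
metadata-only JCAMP files) are exercised explicitly.

## Known limitations

- JSON-LD 1.1 features (containers, framing, `@nest`) are out of scope;
  documents produced by other tools parse only if they stay within the
  1.0 subset and the serialization shape described above.
- The compactor prefers prefixed forms over `@vocab`-bare forms, so
  unannotated keys compact to `sci:<key>` rather than `<key>`.
- Unit conversion covers the bundled table and SI prefixes; it is not a
  general QUDT ingester, and uncertainty propagation is linear scaling
  only.
- The query engine is an in-memory desk-scale tool: no persistence, no
  OPTIONAL/UNION/property paths, no HTTP endpoint.
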