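"""JSON-LD serialization: contexts, ids, round trips, processor agreement."""

import json

import pytest
from hypothesis import given, settings, strategies as st

from scidata import fixtures, model as m
from scidata import jsonld_codec as codec
from scidata.errors import ContextError, ParseError, SerializationError
from scidata.quantity import NumericValue, make_parameter


def _parameter_doc():
    doc = m.build_document({"title": "one parameter"}, "https://example.org/param/")
    doc.scidata.methodology = m.Methodology(evaluation="computational")
    m.add_aspect(doc, "calculation", {"method": "model calculation"})
    m.add_datapoint(doc, [make_parameter(
        "magnetic flux density", NumericValue("7.05", sigfigs=3),
        quantity="magnetic field strength")],
        source_refs=["calculation/1/"])
    m.compute_toc(doc)
    return doc


class TestBuildContext:
    def test_quantity_term_defined(self):
        ctx = codec.build_context(_parameter_doc())
        aliases = {t.alias: t for t in ctx.terms}
        assert "quantity" in aliases
        assert aliases["quantity"].iri.endswith("quantity")

    def test_empty_doc_prefixes_only(self):
        doc = m.build_document({}, "https://example.org/empty/")
        ctx = codec.build_context(doc)
        assert "sci" in ctx.prefixes and "xsd" in ctx.prefixes

    def test_every_emitted_key_defined_or_flagged(self, fixture_doc):
        ctx = codec.build_context(fixture_doc)
        defined = {t.alias for t in ctx.terms}
        emitted = set()
        codec._collect_keys(codec.build_body(fixture_doc), emitted)
        assert emitted == defined | set(ctx.unannotated)
        assert ctx.unannotated == []

    def test_strict_mode_rejects_unknown_keys(self):
        doc = m.build_document({"mystery": 1}, "https://example.org/x/")
        with pytest.raises(ContextError):
            codec.build_context(doc, strict=True)
        assert codec.build_context(doc).unannotated == ["mystery"]


class TestCompactContext:
    def test_absolute_sdmo_iris_become_sci_forms(self, ph_doc):
        compacted = codec.compact_context(codec.build_context(ph_doc))
        sci_terms = [t for t in compacted.terms if t.iri.startswith("sci:")]
        assert sci_terms, "expected sci:-prefixed terms"
        assert all(":" in t.iri for t in compacted.terms)

    def test_idempotent(self, ph_doc):
        once = codec.compact_context(codec.build_context(ph_doc))
        assert codec.compact_context(once) == once

    def test_shared_namespace_tie_break_deterministic(self):
        ctx = codec.Context(
            prefixes={"beta": "https://ns.example/v#", "alpha": "https://ns.example/v#"},
            terms=[codec.TermDefinition("thing", "https://ns.example/v#thing")])
        out = codec.compact_context(ctx)
        assert out.terms[0].iri == "alpha:thing"


class TestAssignIds:
    def test_parameter_and_value_distinct_iris(self):
        doc = _parameter_doc()
        codec.assign_ids(doc)
        param = doc.scidata.dataset.datapoints[0].parameters[0]
        assert param.param_id == "datapoint/1/parameter/1/"
        body = codec.build_body(doc)
        point = body["scidata"]["dataset"]["datapoint"]
        assert point["parameter"]["@id"] != point["parameter"]["value"]["@id"]

    def test_empty_doc_only_root_id(self):
        doc = m.build_document({}, "https://example.org/empty/")
        codec.assign_ids(doc)
        body = codec.build_body(doc)
        assert body["@id"] == "https://example.org/empty/"

    def test_idempotent(self, fixture_doc):
        codec.assign_ids(fixture_doc)
        first = codec.build_body(fixture_doc)
        codec.assign_ids(fixture_doc)
        assert codec.build_body(fixture_doc) == first


class TestSerializeDeserialize:
    def test_fixture_round_trip(self, fixture_doc):
        text = codec.serialize(fixture_doc)
        assert codec.deserialize(text) == fixture_doc

    @settings(max_examples=40, deadline=None)
    @given(st.integers(min_value=0, max_value=100_000))
    def test_random_document_round_trip(self, seed):
        doc = fixtures.make_fixture("random", seed=seed)
        assert codec.deserialize(codec.serialize(doc)) == doc

    def test_truncated_file_parse_error_with_line(self):
        text = codec.serialize(fixtures.make_fixture("ph"))
        with pytest.raises(ParseError) as exc:
            codec.deserialize(text[: len(text) // 2])
        assert exc.value.line is not None

    def test_unknown_external_context_named_in_error(self):
        bad = json.dumps({"@context": ["https://nowhere.example/ctx.jsonld",
                                       {"@base": "https://example.org/x/"}]})
        with pytest.raises(ContextError) as exc:
            codec.deserialize(bad, registry=codec.ContextRegistry())
        assert "https://nowhere.example/ctx.jsonld" in str(exc.value)

    def test_strict_serialize_requires_clean_validate(self):
        doc = m.build_document({}, "https://example.org/broken/")
        doc.scidata.methodology = m.Methodology(evaluation="experimental")
        m.add_datapoint(doc, [make_parameter("pH", NumericValue("3"))],
                        source_refs=["measurement/1/"])
        with pytest.raises(SerializationError):
            codec.serialize(doc, strict=True)
        assert codec.serialize(doc, strict=False)

    def test_output_key_order_is_canonical(self, ph_doc):
        obj = json.loads(codec.serialize(ph_doc))
        keys = list(obj)
        assert keys[0] == "@context" and keys[1] == "@id"
        rest = [k for k in keys if not k.startswith("@")]
        assert rest == sorted(rest)


class TestExternalizeContext:
    FILE_IRI = "https://example.org/contexts/scidata.jsonld"

    def test_document_references_file_iri(self, ph_doc):
        ctx = codec.compact_context(codec.build_context(ph_doc))
        codec.assign_ids(ph_doc)
        document, payload = codec.externalize_context(ph_doc, ctx, self.FILE_IRI)
        assert document["@context"][0] == self.FILE_IRI
        assert document["@context"][1] == {"@base": ph_doc.base_iri}
        assert "@context" in payload and "@base" not in payload["@context"]

    def test_externalize_then_reinline_round_trip(self, fixture_doc):
        inline_text = codec.serialize(fixture_doc)
        ctx = codec.compact_context(codec.build_context(fixture_doc))
        document, payload = codec.externalize_context(fixture_doc, ctx, self.FILE_IRI)
        registry = codec.ContextRegistry()
        registry.add(self.FILE_IRI, payload)
        roundtripped = codec.deserialize(json.dumps(document), registry=registry)
        roundtripped.context_ref = None
        assert codec.serialize(roundtripped) == inline_text

    def test_external_and_inline_expansion_agree(self, ph_doc):
        ctx = codec.compact_context(codec.build_context(ph_doc))
        codec.assign_ids(ph_doc)
        inline = {"@context": ctx.to_jsonld(), **codec.build_body(ph_doc)}
        document, payload = codec.externalize_context(ph_doc, ctx, self.FILE_IRI)
        registry = codec.ContextRegistry()
        registry.add(self.FILE_IRI, payload)
        assert codec.expand(inline) == codec.expand(document, registry=registry)

    def test_empty_doc_consistent_pair(self):
        doc = m.build_document({}, "https://example.org/empty/")
        ctx = codec.build_context(doc)
        document, payload = codec.externalize_context(doc, ctx, self.FILE_IRI)
        assert document["@id"] == doc.doc_id
        assert payload["@context"]["sci"]


class TestExpandCompact:
    def test_compact_of_expand_is_identity(self, fixture_doc):
        text = codec.serialize(fixture_doc)
        obj = json.loads(text)
        compacted = codec.compact(codec.expand(text), obj["@context"])
        assert json.dumps(compacted, sort_keys=True) == json.dumps(obj, sort_keys=True)

    def test_expand_drops_undefined_keys_without_vocab(self):
        doc = {"@context": {"@base": "https://example.org/x/"},
               "@id": "https://example.org/x/", "unmapped": "gone"}
        expanded = codec.expand(doc)
        assert expanded == [{"@id": "https://example.org/x/"}]

    def test_expand_keeps_keys_under_vocab(self):
        doc = {"@context": {"@vocab": "https://v.example/"},
               "@id": "https://example.org/x/", "kept": "here"}
        assert codec.expand(doc) == [{
            "@id": "https://example.org/x/",
            "https://v.example/kept": [{"@value": "here"}]}]

    def test_expand_empty_document(self):
        assert codec.expand({}) == []

    def test_expansion_matches_rdflib_graph(self, fixture_doc):
        """Reference-processor agreement at the RDF level."""
        from rdflib import Graph
        from rdflib.compare import isomorphic

        from scidata.rdfizer import expanded_to_triples, to_rdflib_graph
        text = codec.serialize(fixture_doc)
        mine = to_rdflib_graph(expanded_to_triples(codec.expand(text)))
        ref = Graph()
        ref.parse(data=text, format="json-ld")
        assert isomorphic(mine, ref)
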