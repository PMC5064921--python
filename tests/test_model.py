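"""Model construction, id minting, toc derivation, validation, vocabulary."""

import pytest
from hypothesis import given, settings, strategies as st

from scidata import model as m
from scidata.errors import CycleError, ModelError, NotFoundError
from scidata.quantity import NumericValue, make_parameter
from scidata.vocabulary import CLASS_GROUPS, default_vocabulary, term_lookup, vocabulary_terms


def _doc(base="https://example.org/doc/"):
    d = m.build_document({"title": "t"}, base)
    d.scidata.methodology = m.Methodology(evaluation="experimental")
    return d


def _param(prop="pH", value="3.5"):
    return make_parameter(prop, NumericValue(value))


class TestBuildDocument:
    def test_identity_of_base(self):
        doc = m.build_document({"title": "x"}, "https://example.org/doc1/")
        assert doc.doc_id == "https://example.org/doc1/"
        assert doc.base_iri == "https://example.org/doc1/"
        assert doc.toc == set()

    @pytest.mark.parametrize("bad", [
        "not a uri", "ftp://example.org/x/", "https://example.org/doc",
        "relative/path/", "https:///nopath/",
    ])
    def test_malformed_base_rejected(self, bad):
        with pytest.raises(ModelError):
            m.build_document({}, bad)

    def test_root_metadata_matches_ph_fixture(self, ph_doc):
        rebuilt = m.build_document(ph_doc.root_metadata, ph_doc.base_iri)
        assert rebuilt.root_metadata == ph_doc.root_metadata
        assert rebuilt.doc_id == ph_doc.doc_id


class TestIdMinting:
    def test_ordinal_ids_per_kind(self):
        doc = _doc()
        a1 = m.add_aspect(doc, "measurement", {"technique": "pH"})
        a2 = m.add_aspect(doc, "measurement")
        f1 = m.add_facet(doc, "substance", {"name": "hydrochloric acid"})
        assert a1.aspect_id == "measurement/1/"
        assert a2.aspect_id == "measurement/2/"
        assert f1.facet_id == "substance/1/"

    def test_empty_kind_rejected(self):
        doc = _doc()
        with pytest.raises(ModelError):
            m.add_aspect(doc, "")
        with pytest.raises(ModelError):
            m.add_facet(doc, "")

    def test_facet_holds_parameter(self):
        doc = _doc()
        facet = m.add_facet(doc, "condition", {"conditions": _param("temperature", "25.0")})
        assert facet.metadata["conditions"].property == "temperature"

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.sampled_from(["measurement", "procedure", "substance", "condition"]),
                    min_size=1, max_size=12))
    def test_minted_ids_injective(self, kinds):
        """No two elements in one document ever share a minted IRI."""
        doc = _doc()
        for k in kinds:
            if k in ("measurement", "procedure"):
                m.add_aspect(doc, k)
            else:
                m.add_facet(doc, k)
            m.add_datapoint(doc, [_param()])
        ids = [rid for rid, _ in m.iter_elements(doc)]
        assert len(ids) == len(set(ids))


class TestDatasetBuilders:
    def test_datapoint_requires_parameters(self):
        with pytest.raises(ModelError):
            m.add_datapoint(_doc(), [])

    def test_datapoint_with_numeric_and_text(self, ph_doc):
        point = ph_doc.scidata.dataset.datapoints[0]
        assert len(point.parameters) == 2
        props = {p.property for p in point.parameters}
        assert props == {"pH", "observation"}

    def test_deferred_reference_flagged_later(self):
        doc = _doc()
        m.add_datapoint(doc, [_param()], source_refs=["measurement/1/"])
        errors = [i for i in m.validate(doc) if i.severity == "error"]
        assert any("measurement/1/" in i.message for i in errors)
        m.add_aspect(doc, "measurement")
        m.compute_toc(doc)
        assert m.validate(doc) == []

    def test_series_requires_values(self):
        with pytest.raises(ModelError):
            m.add_dataseries(_doc(), _param(), values=[])

    def test_group_of_two_series(self):
        doc = _doc()
        group = m.add_datagroup(doc, "spectrum")
        m.add_dataseries(doc, _param("chemical shift"), values=[1, 2, 3], into=group)
        m.add_dataseries(doc, _param("intensity"), values=[4, 5, 6], into=group)
        assert len(group.members) == 2
        assert m.compute_toc(doc) == ["datagroup", "dataseries"]

    def test_self_nesting_rejected(self):
        doc = _doc()
        g = m.add_datagroup(doc, "outer")
        with pytest.raises(CycleError):
            m.add_to_group(g, g)

    def test_descendant_nesting_rejected(self):
        doc = _doc()
        outer = m.add_datagroup(doc, "outer")
        inner = m.add_datagroup(doc, "inner", into=outer)
        with pytest.raises(CycleError):
            m.add_to_group(inner, outer)

    def test_nested_groups_round(self):
        doc = _doc()
        outer = m.add_datagroup(doc, "results")
        mid = m.add_datagroup(doc, "orbitals", into=outer)
        m.add_dataseries(doc, _param("orbital energy"), values=[1, 2], into=mid)
        ids = [rid for rid, _ in m.iter_elements(doc)]
        assert {"datagroup/1/", "datagroup/2/", "dataseries/1/"} <= set(ids)


class TestComputeToc:
    def test_empty_document(self):
        doc = m.build_document({}, "https://example.org/empty/")
        assert m.compute_toc(doc) == []
        assert doc.toc == set()

    def test_ph_fixture_kinds(self, ph_doc):
        assert m.compute_toc(ph_doc) == ["condition", "datapoint", "measurement", "substance"]

    def test_nmr_fixture_contains_group_kinds(self):
        from scidata.fixtures import make_fixture
        toc = set(m.compute_toc(make_fixture("nmr_limonene")))
        assert {"datagroup", "dataseries"} <= toc

    def test_idempotent(self, fixture_doc):
        first = m.compute_toc(fixture_doc)
        assert m.compute_toc(fixture_doc) == first

    @settings(max_examples=25, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_brute_force_enumeration(self, seed):
        from scidata.fixtures import make_fixture
        doc = make_fixture("random", seed=seed)
        expected = set()
        sd = doc.scidata
        if sd.methodology:
            expected |= {a.kind for a in sd.methodology.aspects}
        if sd.system:
            expected |= {f.kind for f in sd.system.facets}
        if sd.dataset:
            for rid, el in m.iter_elements(doc):
                if isinstance(el, m.Datapoint):
                    expected.add("datapoint")
                elif isinstance(el, m.Dataseries):
                    expected.add("dataseries")
                elif isinstance(el, m.Datagroup):
                    expected.add("datagroup")
        assert set(m.compute_toc(doc)) == expected


class TestResolveRef:
    def test_absolute_and_relative_agree(self):
        doc = _doc()
        facet = m.add_facet(doc, "substance", {"name": "water"})
        rel = m.resolve_ref(doc, "substance/1/")
        abso = m.resolve_ref(doc, doc.base_iri + "substance/1/")
        assert rel is facet and abso is facet

    def test_unknown_iri_lists_near_misses(self):
        doc = _doc()
        m.add_aspect(doc, "measurement")
        with pytest.raises(NotFoundError) as exc:
            m.resolve_ref(doc, "measurement/2/")
        assert "measurement/1/" in str(exc.value)


class TestValidate:
    def test_fixture_documents_are_clean(self, fixture_doc):
        assert m.validate(fixture_doc) == []

    def test_broken_series_reference(self):
        doc = _doc()
        point = m.add_datapoint(doc, [_param()])
        m.add_dataseries(doc, _param(), values=[point.point_id], values_are_refs=True)
        doc.scidata.dataset.datapoints.clear()
        m.compute_toc(doc)
        errors = [i for i in m.validate(doc) if i.severity == "error"]
        assert len(errors) == 1 and "datapoint/1/" in errors[0].message

    def test_stale_toc_is_single_warning(self, ph_doc):
        ph_doc.toc.add("spectrum")
        issues = m.validate(ph_doc)
        assert [i.severity for i in issues] == ["warning"]
        assert "stale" in issues[0].message

    def test_missing_evaluation_is_error(self):
        doc = m.build_document({}, "https://example.org/d/")
        m.add_aspect(doc, "measurement")
        m.compute_toc(doc)
        assert any("evaluation" in i.message for i in m.validate(doc)
                   if i.severity == "error")

    @settings(max_examples=20, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_referential_closure(self, seed):
        """A clean validate implies every internal reference resolves."""
        from scidata.fixtures import make_fixture
        doc = make_fixture("random", seed=seed)
        assert m.validate(doc) == []
        for rid, el in m.iter_elements(doc):
            refs = list(getattr(el, "source_refs", [])) + list(getattr(el, "scope_refs", []))
            if isinstance(el, m.Dataseries) and el.values_are_refs:
                refs += el.values
            for ref in refs:
                assert m.resolve_ref(doc, ref) is not None


class TestVocabulary:
    def test_dataseries_in_dataset_group(self):
        term = term_lookup("dataseries")
        assert term.class_group == "dataset"
        assert term.term_iri.endswith("dataseries")

    def test_framework_term_count_over_sixty(self):
        assert len(default_vocabulary().sdmo_terms()) >= 60

    def test_unknown_term_not_found(self):
        with pytest.raises(NotFoundError):
            term_lookup("nonexistent")

    def test_all_terms_in_known_class_groups(self):
        assert {t.class_group for t in vocabulary_terms()} <= set(CLASS_GROUPS)

    def test_every_serialized_key_registered_for_fixtures(self, fixture_doc):
        """Vocabulary closure: strict context building succeeds on fixtures."""
        from scidata.jsonld_codec import build_context
        ctx = build_context(fixture_doc, strict=True)
        assert ctx.unannotated == []

    def test_export_tsv_shape(self):
        lines = default_vocabulary().export_tsv().strip().splitlines()
        assert lines[0] == "name\tclass_group\tiri\tdefinition"
        assert all(len(line.split("\t")) == 4 for line in lines[1:])

    def test_unannotated_keys_reported(self):
        doc = _doc()
        m.add_aspect(doc, "measurement", {"mystery_knob": 3})
        assert m.unannotated_keys(doc) == ["mystery_knob"]
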