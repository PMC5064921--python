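"""Parameter construction, significant-figure formatting, unit conversion."""

from decimal import Decimal

import pytest
from hypothesis import given, settings, strategies as st

from scidata import model as m
from scidata.errors import IncompatibleUnitsError, ModelError, NotFoundError, UnitError
from scidata.jsonld_codec import assign_ids
from scidata.quantity import (
    NumericValue, TextValue, Unit, UnitSpec, UnitStub, convert, format_sigfigs,
    get_unit, iter_unit_pairs, make_parameter, resolve_unitref, unit_table,
)


class TestMakeParameter:
    def test_quantity_is_plain_string_field(self):
        p = make_parameter("magnetic flux density", NumericValue("7.05"),
                           quantity="magnetic field strength")
        assert p.quantity == "magnetic field strength"
        assert isinstance(p.value, NumericValue)

    def test_dimensionless_without_unit(self):
        p = make_parameter("pH", NumericValue("3.5"))
        assert p.unit_spec is None

    def test_conflicting_value_kinds_rejected(self):
        with pytest.raises(ModelError):
            NumericValue("abc")
        with pytest.raises(ModelError):
            make_parameter("x", object())

    def test_coercions(self):
        assert isinstance(make_parameter("n", 3).value, NumericValue)
        assert make_parameter("n", 3).value.numeric_type == "integer"
        assert isinstance(make_parameter("s", "note").value, TextValue)
        assert isinstance(make_parameter("a", [1, 2]).value, list)

    def test_empty_property_rejected(self):
        with pytest.raises(ModelError):
            make_parameter("", NumericValue("1"))

    def test_numeric_invariants(self):
        with pytest.raises(ModelError):
            NumericValue("1.5", numeric_type="integer")
        with pytest.raises(ModelError):
            NumericValue("1", exact=True, error="0.1")
        with pytest.raises(ModelError):
            NumericValue("1", sigfigs=0)


def _oracle_sigfigs(number: float, sigfigs: int) -> tuple[str, int]:
    """Independent (digits, exponent) oracle: pure integer arithmetic over
    the number's shortest decimal representation, half-even on ties."""
    import re

    s = repr(float(number))
    mo = re.fullmatch(r"-?(\d+)(?:\.(\d+))?(?:e([+-]?\d+))?", s)
    intpart, frac, exp = mo.group(1), mo.group(2) or "", int(mo.group(3) or 0)
    raw = intpart + frac
    digits = raw.lstrip("0")
    if not digits:
        return "0" * sigfigs, 0
    exp10 = len(intpart) + exp - (len(raw) - len(digits)) - 1
    if len(digits) <= sigfigs:
        return digits.ljust(sigfigs, "0"), exp10
    head, tail = int(digits[:sigfigs]), digits[sigfigs:]
    half = "5" + "0" * (len(tail) - 1)
    if tail > half or (tail == half and head % 2 == 1):
        head += 1
    rounded = str(head)
    if len(rounded) > sigfigs:
        rounded, exp10 = rounded[:sigfigs], exp10 + 1
    return rounded, exp10


def _parse_rendered(rendered: str) -> tuple[str, int]:
    """Recover (digits, exponent) from a format_sigfigs rendering."""
    neg = rendered.startswith("-")
    body = rendered.lstrip("-")
    if "e" in body:
        mantissa, exp = body.split("e")
        return mantissa.replace(".", ""), int(exp)
    raw = body.replace(".", "")
    digits = raw.lstrip("0")
    if not digits:
        return raw, 0
    point = body.find(".")
    intlen = len(body) if point < 0 else point
    return digits, intlen - (len(raw) - len(digits)) - 1


class TestFormatSigfigs:
    @pytest.mark.parametrize("number,sigfigs,expected", [
        (1.0, 2, "1.0"),
        (0.0123454, 4, "0.01235"),
        (12345, 2, "1.2e4"),
        (123.4, 4, "123.4"),
        (-3.14159, 3, "-3.14"),
        (0, 3, "0.00"),
        (9.99, 2, "10"),
        (120, 2, "1.2e2"),
        (0.0001234, 2, "1.2e-4"),
    ])
    def test_reference_renderings(self, number, sigfigs, expected):
        assert format_sigfigs(number, sigfigs) == expected

    def test_sigfigs_below_one_rejected(self):
        with pytest.raises(ModelError):
            format_sigfigs(1.0, 0)

    @settings(max_examples=200, deadline=None)
    @given(st.floats(min_value=-1e6, max_value=1e6, allow_nan=False,
                     allow_infinity=False).filter(lambda x: abs(x) > 1e-6),
           st.integers(min_value=1, max_value=8))
    def test_digits_match_independent_oracle(self, number, sigfigs):
        rendered = format_sigfigs(number, sigfigs)
        digits, exp10 = _parse_rendered(rendered)
        want_digits, want_exp10 = _oracle_sigfigs(number, sigfigs)
        assert (digits, exp10) == (want_digits, want_exp10)

    @settings(max_examples=200, deadline=None)
    @given(st.floats(min_value=-1e6, max_value=1e6, allow_nan=False,
                     allow_infinity=False).filter(lambda x: abs(x) > 1e-6),
           st.integers(min_value=1, max_value=8))
    def test_reparse_within_half_ulp(self, number, sigfigs):
        """Reparsed output differs from the input by < half a unit in the
        last significant place."""
        rendered = format_sigfigs(number, sigfigs)
        reparsed = float(rendered.replace("e", "E"))
        import math
        exp10 = math.floor(math.log10(abs(number)))
        ulp = 10.0 ** (exp10 - sigfigs + 1)
        assert abs(reparsed - number) <= 0.5 * ulp * (1 + 1e-12)


class TestConvert:
    def test_identity(self):
        v = NumericValue("42.5", sigfigs=3)
        out = convert(v, get_unit("m"), get_unit("m"))
        assert out.number == Decimal("42.5") and out.sigfigs == 3

    def test_centimetre_to_metre(self):
        out = convert(NumericValue("100"), get_unit("cm"), get_unit("m"))
        assert out.number == Decimal("1")

    def test_prefix_product_oracle(self):
        """Prefixed conversions equal the product of prefix factors."""
        from scidata.quantity import PREFIXES
        for sym_a, sym_b in (("km", "mm"), ("ug", "kg"), ("mL", "L")):
            a, b = get_unit(sym_a), get_unit(sym_b)
            expected = (PREFIXES[a.prefix][1] if a.prefix else 1) / \
                       (PREFIXES[b.prefix][1] if b.prefix else 1)
            out = convert(NumericValue("1"), a, b)
            assert out.number == Decimal(expected)

    def test_dimension_mismatch(self):
        with pytest.raises(IncompatibleUnitsError):
            convert(NumericValue("1"), get_unit("cm"), get_unit("kg"))

    def test_affine_temperature(self):
        assert convert(NumericValue("25.0"), get_unit("degC"),
                       get_unit("K")).number == Decimal("298.15")

    def test_error_scales_linearly(self):
        out = convert(NumericValue("100", error="2"), get_unit("cm"), get_unit("m"))
        assert out.error == Decimal("0.02")

    def test_exact_preserved_only_for_exact_ratio(self):
        exact_in = NumericValue("1", exact=True)
        assert convert(exact_in, get_unit("cm"), get_unit("m")).exact
        assert not convert(exact_in, get_unit("atm"), get_unit("mmHg")).exact

    def test_round_trip_all_table_pairs(self):
        """convert(convert(v, a, b), b, a) reproduces v at working precision."""
        for a, b in iter_unit_pairs():
            back = convert(convert(NumericValue("3.7"), a, b), b, a)
            assert abs(back.number - Decimal("3.7")) < Decimal("1e-30"), (a.symbol, b.symbol)

    def test_composition_over_table_triples(self):
        """a→c equals a→b→c for all compatible unit triples in the table."""
        import itertools
        units = list(unit_table().values())
        groups = {}
        for u in units:
            groups.setdefault((u.quantity_kind, tuple(sorted(u.si_base_expansion.items()))),
                              []).append(u)
        for group in groups.values():
            for a, b, c in itertools.permutations(group, 3):
                direct = convert(NumericValue("2.5"), a, c).number
                via = convert(convert(NumericValue("2.5"), a, b), b, c).number
                assert abs(direct - via) <= abs(direct) * Decimal("1e-30")


class TestUnits:
    def test_unit_spec_exactly_one_payload(self):
        with pytest.raises(UnitError):
            UnitSpec(form="unitstr", unitstr="m", unitref="x")
        with pytest.raises(UnitError):
            UnitSpec(form="unit")

    def test_multiplier_must_be_positive(self):
        with pytest.raises(UnitError):
            Unit(symbol="bad", multiplier_to_si=Decimal("-1"))

    def test_unknown_symbol(self):
        with pytest.raises(NotFoundError):
            get_unit("florb")

    def test_prefixed_affine_rejected(self):
        with pytest.raises(UnitError):
            get_unit("mdegC")


class TestResolveUnitref:
    def _doc_with_unit(self):
        doc = m.build_document({}, "https://example.org/u/")
        doc.scidata.methodology = m.Methodology(evaluation="experimental")
        m.add_datapoint(doc, [make_parameter(
            "temperature", NumericValue("25.0"), unit_spec=get_unit("degC"))])
        assign_ids(doc)
        return doc

    def test_internal_reference(self):
        doc = self._doc_with_unit()
        unit = resolve_unitref(doc, "datapoint/1/parameter/1/unit/")
        assert unit.symbol == "degC" and unit.resolved

    def test_external_iri_returns_stub(self):
        doc = self._doc_with_unit()
        stub = resolve_unitref(doc, "http://qudt.org/vocab/unit/M")
        assert isinstance(stub, UnitStub) and not stub.resolved
        assert stub.iri == "http://qudt.org/vocab/unit/M"

    def test_dangling_internal_reference(self):
        doc = self._doc_with_unit()
        with pytest.raises(NotFoundError):
            resolve_unitref(doc, "datapoint/9/parameter/1/unit/")
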