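"""Parameters, numeric/text values and units of measure.

A :class:`Parameter` is the generic property-report structure reused
throughout the data model: a property name (optionally with its physical
quantity), a numeric or textual value, and an optional unit.  Numeric
values carry their printed lexical form so that significant figures
survive serialization round-trips.

Units may be given three ways, mirroring the model's unit framework:

``unitstr``
    an opaque symbol the author does not define ("pH units", "a.u.");
``unit``
    an in-place definition with a quantity kind, an SI base-dimension
    expansion and an affine conversion to coherent SI (QUDT-style
    multiplier and offset);
``unitref``
    an IRI pointing at a unit defined elsewhere, inside the same
    document or in an external vocabulary.

A bundled table (``data/units.tsv``) provides the SI base and derived
units plus the common chemistry units, combinable with all SI prefixes.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from decimal import Decimal, Inexact, ROUND_HALF_EVEN, localcontext
from importlib import resources

from .errors import IncompatibleUnitsError, ModelError, NotFoundError, UnitError

NUMERIC_TYPES = ("decimal", "integer", "float", "exponential")
TEXT_TYPES = ("plain", "JSON", "XML", "HTML")

#: Working precision (decimal digits) for unit arithmetic.
PRECISION = 40

#: Exponent magnitude at which format_sigfigs switches to scientific notation.
SCI_NOTATION_THRESHOLD = 4


def _to_decimal(x) -> Decimal:
    if isinstance(x, Decimal):
        return x
    if isinstance(x, float):
        # str() gives the shortest repr that round-trips the float
        return Decimal(str(x))
    try:
        return Decimal(x)
    except (ArithmeticError, TypeError, ValueError):
        raise ModelError(f"not a decimal number: {x!r}") from None


@dataclass
class NumericValue:
    """A number together with its printed form and quality metadata.

    ``number`` accepts int, float, str or Decimal; the lexical (printed)
    form is preserved in ``lexical`` so "3.50" stays "3.50".
    """

    number: Decimal
    numeric_type: str = "decimal"
    sigfigs: int | None = None
    error: Decimal | None = None
    exact: bool = False
    lexical: str = ""

    def __post_init__(self):
        if isinstance(self.number, (int, float, str)):
            if not self.lexical:
                self.lexical = str(self.number)
            self.number = _to_decimal(self.number)
        if not self.lexical:
            self.lexical = str(self.number)
        if self.error is not None:
            self.error = _to_decimal(self.error)
            if self.error < 0:
                raise ModelError("error must be non-negative")
        if self.numeric_type not in NUMERIC_TYPES:
            raise ModelError(f"unknown numeric type {self.numeric_type!r}")
        if self.exact and self.error is not None:
            raise ModelError("an exact value cannot carry an error")
        if self.sigfigs is not None and self.sigfigs < 1:
            raise ModelError("sigfigs must be >= 1 when given")
        if self.numeric_type == "integer" and self.number != self.number.to_integral_value():
            raise ModelError(f"integer-typed value {self.lexical!r} has a fractional part")


@dataclass
class TextValue:
    """A textual value with an encoding type and optional language tag."""

    text: str
    text_type: str = "plain"
    language: str | None = None

    def __post_init__(self):
        if self.text_type not in TEXT_TYPES:
            raise ModelError(f"unknown text type {self.text_type!r}")


@dataclass
class Unit:
    """An in-place unit definition.

    ``si_base_expansion`` maps SI base-unit symbols to integer exponents
    (e.g. ``{"kg": 1, "m": -1, "s": -2}`` for pressure); the affine map
    ``x_si = x * multiplier_to_si + offset_to_si`` relates a value in
    this unit to coherent SI.
    """

    symbol: str
    quantity_kind: str = ""
    si_base_expansion: dict[str, int] = field(default_factory=dict)
    multiplier_to_si: Decimal = Decimal(1)
    offset_to_si: Decimal = Decimal(0)
    prefix: str | None = None
    #: distinguishes real definitions from offline stubs for external IRIs
    resolved: bool = True

    def __post_init__(self):
        self.multiplier_to_si = _to_decimal(self.multiplier_to_si)
        self.offset_to_si = _to_decimal(self.offset_to_si)
        if self.multiplier_to_si <= 0:
            raise UnitError(f"unit {self.symbol!r}: multiplier must be positive")


@dataclass
class UnitStub:
    """Placeholder for an external unit IRI that cannot be resolved offline."""

    iri: str
    resolved: bool = False


@dataclass
class UnitSpec:
    """One of the three unit-reporting forms: unitstr | unit | unitref."""

    form: str
    unitstr: str | None = None
    unit: Unit | None = None
    unitref: str | None = None

    def __post_init__(self):
        payloads = {"unitstr": self.unitstr, "unit": self.unit, "unitref": self.unitref}
        if self.form not in payloads:
            raise UnitError(f"unknown unit form {self.form!r}")
        populated = [k for k, v in payloads.items() if v is not None]
        if populated != [self.form]:
            raise UnitError(
                f"unit spec of form {self.form!r} must populate exactly that payload, "
                f"got {populated or 'none'}"
            )

    @classmethod
    def from_str(cls, s: str) -> "UnitSpec":
        return cls(form="unitstr", unitstr=s)

    @classmethod
    def from_unit(cls, u: Unit) -> "UnitSpec":
        return cls(form="unit", unit=u)

    @classmethod
    def from_ref(cls, iri: str) -> "UnitSpec":
        return cls(form="unitref", unitref=iri)


@dataclass
class Parameter:
    """Property report: property name, optional quantity, value, optional unit.

    ``param_id`` is minted when the parameter is attached to a document
    (see ``jsonld_codec.assign_ids``); standalone parameters have none.
    """

    property: str
    value: NumericValue | TextValue | list
    quantity: str | None = None
    unit_spec: UnitSpec | None = None
    param_id: str | None = None

    def __post_init__(self):
        if not self.property:
            raise ModelError("parameter property must be non-empty")


def make_parameter(property: str, value, unit_spec=None, quantity: str | None = None) -> Parameter:
    """Build a :class:`Parameter`, coercing plain Python values.

    ``value`` may be a NumericValue/TextValue, an int/float/Decimal
    (wrapped as NumericValue), a str (wrapped as TextValue), or a list
    of any of these.  ``unit_spec`` may be a UnitSpec, a Unit, or a bare
    unit string (treated as ``unitstr``).
    """
    if not property:
        raise ModelError("parameter property must be non-empty")
    if isinstance(unit_spec, Unit):
        unit_spec = UnitSpec.from_unit(unit_spec)
    elif isinstance(unit_spec, str):
        unit_spec = UnitSpec.from_str(unit_spec)
    return Parameter(property=property, value=_coerce_value(value),
                     quantity=quantity, unit_spec=unit_spec)


def _coerce_value(value):
    if isinstance(value, (NumericValue, TextValue)):
        return value
    if isinstance(value, bool):
        raise ModelError("boolean parameter values are not supported; use TextValue")
    if isinstance(value, int):
        return NumericValue(value, numeric_type="integer")
    if isinstance(value, (float, Decimal)):
        return NumericValue(value)
    if isinstance(value, str):
        return TextValue(value)
    if isinstance(value, (list, tuple)):
        return [_coerce_value(v) for v in value]
    raise ModelError(f"cannot interpret {type(value).__name__} as a parameter value")


# --------------------------------------------------------------------------
# significant figures

def format_sigfigs(number, sigfigs: int) -> str:
    """Render ``number`` with exactly ``sigfigs`` significant digits.

    Rounding is half-even on the decimal digits.  Scientific notation
    (``1.2e4``) is used when the magnitude exponent reaches
    ``SCI_NOTATION_THRESHOLD`` or when a positional rendering could not
    show the significance unambiguously (trailing zeros left of the
    decimal point).
    """
    if sigfigs < 1:
        raise ModelError("sigfigs must be >= 1")
    d = _to_decimal(number)
    if d == 0:
        return "0" if sigfigs == 1 else "0." + "0" * (sigfigs - 1)
    quant_exp = d.adjusted() - sigfigs + 1
    rounded = d.quantize(Decimal(1).scaleb(quant_exp), rounding=ROUND_HALF_EVEN)
    # rounding can bump the magnitude (9.99 -> 10.0): re-derive
    exp10 = rounded.adjusted()
    quant_exp = exp10 - sigfigs + 1
    rounded = rounded.quantize(Decimal(1).scaleb(quant_exp), rounding=ROUND_HALF_EVEN)
    digits = "".join(str(x) for x in rounded.as_tuple().digits)
    digits = (digits + "0" * sigfigs)[:sigfigs] if len(digits) < sigfigs else digits[:sigfigs]
    sign = "-" if rounded < 0 else ""
    if abs(exp10) >= SCI_NOTATION_THRESHOLD or quant_exp > 0:
        mantissa = digits[0] if sigfigs == 1 else f"{digits[0]}.{digits[1:]}"
        return f"{sign}{mantissa}e{exp10}"
    if exp10 >= 0:
        int_part = digits[: exp10 + 1]
        frac_part = digits[exp10 + 1:]
        return sign + (f"{int_part}.{frac_part}" if frac_part else int_part)
    return sign + "0." + "0" * (-exp10 - 1) + digits


# --------------------------------------------------------------------------
# unit table and conversion

_PREFIXES = {
    "quetta": ("Q", 30), "ronna": ("R", 27), "yotta": ("Y", 24), "zetta": ("Z", 21),
    "exa": ("E", 18), "peta": ("P", 15), "tera": ("T", 12), "giga": ("G", 9),
    "mega": ("M", 6), "kilo": ("k", 3), "hecto": ("h", 2), "deca": ("da", 1),
    "deci": ("d", -1), "centi": ("c", -2), "milli": ("m", -3), "micro": ("u", -6),
    "nano": ("n", -9), "pico": ("p", -12), "femto": ("f", -15), "atto": ("a", -18),
    "zepto": ("z", -21), "yocto": ("y", -24), "ronto": ("r", -27), "quecto": ("q", -30),
}
PREFIXES: dict[str, tuple[str, Decimal]] = {
    name: (sym, Decimal(1).scaleb(exp)) for name, (sym, exp) in _PREFIXES.items()
}
_PREFIX_BY_SYMBOL = sorted(
    ((sym, name, Decimal(1).scaleb(exp)) for name, (sym, exp) in _PREFIXES.items()),
    key=lambda t: -len(t[0]),
)


def parse_expansion(text: str) -> dict[str, int]:
    """Parse ``"kg:1 m:-1 s:-2"`` into an exponent map."""
    out: dict[str, int] = {}
    for tok in text.split():
        base, _, exp = tok.partition(":")
        out[base] = int(exp)
    return out


def expansion_str(expansion: dict[str, int]) -> str:
    return " ".join(f"{k}:{v}" for k, v in sorted(expansion.items()))


def _load_unit_table() -> dict[str, Unit]:
    table = {}
    text = resources.files("scidata").joinpath("data/units.tsv").read_text()
    rows = text.strip().splitlines()
    for line in rows[1:]:
        symbol, kind, dims, mult, off = line.split("\t")
        table[symbol] = Unit(
            symbol=symbol, quantity_kind=kind,
            si_base_expansion=parse_expansion(dims),
            multiplier_to_si=Decimal(mult), offset_to_si=Decimal(off),
        )
    return table


_UNIT_TABLE: dict[str, Unit] | None = None


def unit_table() -> dict[str, Unit]:
    """The bundled symbol→Unit table (base SI + common chemistry units)."""
    global _UNIT_TABLE
    if _UNIT_TABLE is None:
        _UNIT_TABLE = _load_unit_table()
    return _UNIT_TABLE


def get_unit(symbol: str) -> Unit:
    """Look up a unit symbol, resolving SI prefixes (``cm``, ``kPa``, ``ug``).

    Prefixed affine units (e.g. a prefixed degC) are rejected; prefixes
    scale the multiplier only.
    """
    table = unit_table()
    if symbol in table:
        return table[symbol]
    for psym, pname, pfactor in _PREFIX_BY_SYMBOL:
        if symbol.startswith(psym) and symbol[len(psym):] in table:
            base = table[symbol[len(psym):]]
            if base.offset_to_si != 0:
                raise UnitError(f"cannot prefix affine unit {base.symbol!r}")
            return Unit(
                symbol=symbol, quantity_kind=base.quantity_kind,
                si_base_expansion=dict(base.si_base_expansion),
                multiplier_to_si=pfactor * base.multiplier_to_si,
                prefix=pname,
            )
    raise NotFoundError(f"unknown unit symbol {symbol!r}")


def convert(value: NumericValue, from_unit: Unit, to_unit: Unit) -> NumericValue:
    """Convert a numeric value between two compatible units.

    Compatibility requires identical quantity kind and SI base-dimension
    expansion.  The reported ``error`` scales linearly with the
    multiplier ratio; the ``exact`` flag survives only when the whole
    conversion is exact in decimal arithmetic.
    """
    if (from_unit.quantity_kind != to_unit.quantity_kind
            or from_unit.si_base_expansion != to_unit.si_base_expansion):
        raise IncompatibleUnitsError(
            f"cannot convert {from_unit.symbol!r} ({from_unit.quantity_kind or 'dimensionless'}) "
            f"to {to_unit.symbol!r} ({to_unit.quantity_kind or 'dimensionless'})"
        )
    with localcontext() as ctx:
        ctx.prec = PRECISION
        ctx.clear_flags()
        si = value.number * from_unit.multiplier_to_si + from_unit.offset_to_si
        out = (si - to_unit.offset_to_si) / to_unit.multiplier_to_si
        err = None
        if value.error is not None:
            err = value.error * from_unit.multiplier_to_si / to_unit.multiplier_to_si
        inexact = bool(ctx.flags[Inexact])
    return NumericValue(
        number=out, numeric_type="decimal", sigfigs=value.sigfigs,
        error=err, exact=value.exact and not inexact,
    )


def resolve_unitref(doc, unitref: str) -> Unit | UnitStub:
    """Resolve a ``unitref`` IRI.

    Internal IRIs (relative, or absolute under the document base) must
    point at an in-place unit definition within the document; external
    IRIs come back as an unresolved :class:`UnitStub` — this library
    never touches the network.
    """
    base = doc.base_iri
    if unitref.startswith(base):
        rel = unitref[len(base):]
    elif re.match(r"^[a-zA-Z][a-zA-Z0-9+.-]*:", unitref):
        return UnitStub(iri=unitref)
    else:
        rel = unitref
    units = document_units(doc)
    if rel in units:
        return units[rel]
    raise NotFoundError(
        f"unit reference {unitref!r} does not resolve inside the document",
        candidates=sorted(units)[:5],
    )


def document_units(doc) -> dict[str, Unit]:
    """Map of minted relative IRI → in-place Unit across all parameters."""
    from .model import iter_parameters  # local import: model depends on quantity

    out = {}
    for param in iter_parameters(doc):
        spec = param.unit_spec
        if spec is not None and spec.form == "unit" and param.param_id:
            out[param.param_id + "unit/"] = spec.unit
    return out


def iter_unit_pairs():
    """All ordered pairs of mutually convertible units in the bundled table."""
    units = list(unit_table().values())
    for a, b in itertools.permutations(units, 2):
        if a.quantity_kind == b.quantity_kind and a.si_base_expansion == b.si_base_expansion:
            yield a, b
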