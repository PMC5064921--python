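"""Programmatic example documents and synthetic JCAMP-DX files.

Four canonical documents exercise every part of the model — a pH
measurement (plain datapoints), a literature-extracted refractive
index (datapoint plus source citation), an NMR spectrum (datagroup of
two dataseries) and a glucose SCF calculation (nested datagroups) —
plus a seeded generator of randomized valid documents and of AFFN/PAC
JCAMP-DX files with their ground-truth data.

Numeric values in the named fixtures are structural placeholders in
realistic ranges; the fixtures assert model structure, not chemistry.
Identical (name, seed, knobs) always produce the identical document.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from decimal import Decimal

from . import model as m
from .errors import ModelError
from .jcampdx import XYData
from .quantity import NumericValue, TextValue, UnitSpec, get_unit, make_parameter

FIXTURE_NAMES = ("ph", "refractive_index", "nmr_limonene", "glucose_scf", "random")

#: opaque substance identifiers used by the fixtures; their chemical
#: correctness is external to the data model
FIXTURE_CONFIG = {
    "hcl_inchikey": "VEXZGXHMUGYJMC-UHFFFAOYSA-N",
    "limonene_inchikey": "XMGQYMWWDOXHJM-JTQLQIEISA-N",
    "glucose_inchikey": "WQZGKKKJIJFFOK-GASJEMHNSA-N",
}


@dataclass
class FixtureSpec:
    name: str
    seed: int = 0
    points_per_series: int = 16
    nesting_depth: int = 2


def make_fixture(spec, seed: int = 0, points_per_series: int = 16,
                 nesting_depth: int = 2) -> m.SciDataDocument:
    """Build the named fixture document (accepts a FixtureSpec or a name)."""
    if not isinstance(spec, FixtureSpec):
        spec = FixtureSpec(name=spec, seed=seed, points_per_series=points_per_series,
                           nesting_depth=nesting_depth)
    try:
        builder = _BUILDERS[spec.name]
    except KeyError:
        raise ModelError(
            f"unknown fixture {spec.name!r}; expected one of {FIXTURE_NAMES}") from None
    doc = builder(spec)
    m.compute_toc(doc)
    return doc


def _ph(spec: FixtureSpec) -> m.SciDataDocument:
    doc = m.build_document(
        {"title": "pH of an aqueous hydrochloric acid solution",
         "authors": ["A. Measurer", "B. Recorder"],
         "generatedat": "2016-05-10T12:00:00Z",
         "version": 1},
        "https://example.org/scidata/ph/")
    doc.scidata.discipline = "chemistry"
    doc.scidata.subdiscipline = "analytical chemistry"
    doc.scidata.property_list = ["pH"]
    doc.scidata.methodology = m.Methodology(evaluation="experimental")
    aspect = m.add_aspect(doc, "measurement", {
        "technique": "potentiometry", "instrument": "glass-electrode pH meter"})
    substance = m.add_facet(doc, "substance", {
        "name": "hydrochloric acid", "formula": "HCl",
        "inchikey": FIXTURE_CONFIG["hcl_inchikey"]})
    condition = m.add_facet(doc, "condition", {
        "conditions": make_parameter(
            "temperature", NumericValue("25.0", sigfigs=3),
            unit_spec=get_unit("degC"), quantity="temperature")})
    m.add_datapoint(
        doc,
        [make_parameter("pH", NumericValue("3.28", sigfigs=3), quantity="pH"),
         make_parameter("observation", TextValue("clear colorless solution"))],
        source_refs=[aspect.aspect_id],
        scope_refs=[substance.facet_id, condition.facet_id])
    return doc


def _refractive_index(spec: FixtureSpec) -> m.SciDataDocument:
    doc = m.build_document(
        {"title": "Refractive index of an aqueous hydrochloric acid solution",
         "authors": ["C. Extractor", "D. Curator"],
         "sources": {"citation": "Original research article reporting the "
                                 "refractive index of hydrochloric acid solutions",
                     "url": "https://doi.example.org/10.0000/refr-hcl"},
         "generatedat": "2016-06-01T09:30:00Z",
         "version": 1},
        "https://example.org/scidata/refractive-index/")
    doc.scidata.discipline = "chemistry"
    doc.scidata.subdiscipline = "physical chemistry"
    doc.scidata.property_list = ["refractive index"]
    doc.scidata.methodology = m.Methodology(evaluation="experimental")
    aspect = m.add_aspect(doc, "measurement", {"technique": "refractometry",
                                               "instrument": "Abbe refractometer"})
    substance = m.add_facet(doc, "substance", {
        "name": "hydrochloric acid", "formula": "HCl",
        "inchikey": FIXTURE_CONFIG["hcl_inchikey"]})
    condition = m.add_facet(doc, "condition", {
        "conditions": make_parameter(
            "temperature", NumericValue("20.0", sigfigs=3),
            unit_spec=get_unit("degC"), quantity="temperature")})
    m.add_datapoint(
        doc,
        [make_parameter("refractive index", NumericValue("1.3431", sigfigs=5),
                        quantity="refractive index")],
        source_refs=[aspect.aspect_id],
        scope_refs=[substance.facet_id, condition.facet_id])
    return doc


def _nmr_limonene(spec: FixtureSpec) -> m.SciDataDocument:
    rng = random.Random(spec.seed)
    n = max(spec.points_per_series, 2)
    doc = m.build_document(
        {"title": "1H NMR spectrum of R-(+)-limonene",
         "authors": ["E. Spectroscopist", "F. Assistant"],
         "generatedat": "2016-07-15T14:00:00Z",
         "version": 1},
        "https://example.org/scidata/nmr-limonene/")
    doc.scidata.discipline = "chemistry"
    doc.scidata.subdiscipline = "organic chemistry"
    doc.scidata.property_list = ["chemical shift", "intensity"]
    doc.scidata.methodology = m.Methodology(evaluation="experimental")
    aspect = m.add_aspect(doc, "measurement", {
        "technique": "NMR spectroscopy",
        "instrument": "300 MHz NMR spectrometer",
        "settings": make_parameter(
            "magnetic flux density", NumericValue("7.05", sigfigs=3),
            unit_spec=get_unit("T"), quantity="magnetic field strength")})
    substance = m.add_facet(doc, "substance", {
        "name": "R-(+)-limonene", "formula": "C10H16",
        "inchikey": FIXTURE_CONFIG["limonene_inchikey"]})
    group = m.add_datagroup(doc, "spectrum",
                            source_refs=[aspect.aspect_id],
                            scope_refs=[substance.facet_id])
    shifts = [Decimal(f"{10 - 10 * i / (n - 1):.4f}") for i in range(n)]
    intensities = [Decimal(f"{rng.uniform(0, 100):.4f}") for _ in range(n)]
    m.add_dataseries(doc, make_parameter("chemical shift",
                                         NumericValue(n, numeric_type="integer", exact=True),
                                         unit_spec="ppm", quantity="chemical shift"),
                     values=shifts, label="chemical shift axis", into=group)
    m.add_dataseries(doc, make_parameter("intensity",
                                         NumericValue(n, numeric_type="integer", exact=True),
                                         unit_spec="arbitrary units"),
                     values=intensities, label="intensity axis", into=group)
    return doc


def _glucose_scf(spec: FixtureSpec) -> m.SciDataDocument:
    rng = random.Random(spec.seed)
    n_orbitals = max(spec.points_per_series, 4)
    doc = m.build_document(
        {"title": "SCF calculation of electronic properties of D-glucose",
         "authors": ["G. Theorist", "H. Modeler"],
         "generatedat": "2016-08-20T08:00:00Z",
         "version": 1},
        "https://example.org/scidata/glucose-scf/")
    doc.scidata.discipline = "chemistry"
    doc.scidata.subdiscipline = "computational chemistry"
    doc.scidata.property_list = ["total electronic energy", "orbital energy"]
    doc.scidata.methodology = m.Methodology(evaluation="computational")
    calc = m.add_aspect(doc, "calculation", {"method": "restricted Hartree-Fock"})
    m.add_aspect(doc, "basisset", {"name": "6-31G*"})
    m.add_aspect(doc, "software", {"name": "quantum chemistry package", "version": "2016.1"})
    substance = m.add_facet(doc, "substance", {
        "name": "D-glucose", "formula": "C6H12O6",
        "inchikey": FIXTURE_CONFIG["glucose_inchikey"]})
    outer = m.add_datagroup(doc, "calculation results",
                            source_refs=[calc.aspect_id],
                            scope_refs=[substance.facet_id])
    scf = m.add_datagroup(doc, "scf iterations", into=outer)
    energies = []
    e = Decimal("-683.0")
    for _ in range(6):
        e -= Decimal(f"{rng.uniform(0, 0.3):.6f}")
        energies.append(e)
    m.add_dataseries(doc, make_parameter("total electronic energy",
                                         NumericValue(6, numeric_type="integer", exact=True),
                                         unit_spec="Eh"),
                     values=energies, label="SCF energy per iteration", into=scf)
    orbitals = m.add_datagroup(doc, "molecular orbitals", into=outer)
    m.add_dataseries(doc, make_parameter("orbital energy",
                                         NumericValue(n_orbitals, numeric_type="integer",
                                                      exact=True),
                                         unit_spec="Eh"),
                     values=sorted(Decimal(f"{rng.uniform(-20, 5):.6f}")
                                   for _ in range(n_orbitals)),
                     label="orbital energies", into=orbitals)
    m.add_datapoint(doc,
                    [make_parameter("total electronic energy", NumericValue(str(energies[-1])),
                                    unit_spec="Eh", quantity="energy")],
                    source_refs=[calc.aspect_id], scope_refs=[substance.facet_id])
    return doc


_ASPECT_KINDS = ("measurement", "procedure", "calculation", "resource")
_FACET_KINDS = ("substance", "condition", "material", "organism")
_TECHNIQUES = ("potentiometry", "refractometry", "NMR spectroscopy",
               "mass spectrometry", "UV-vis spectrophotometry")
_SUBSTANCES = (("water", "H2O"), ("ethanol", "C2H6O"), ("benzene", "C6H6"),
               ("glucose", "C6H12O6"), ("sodium chloride", "NaCl"))
_UNIT_SYMBOLS = ("m", "cm", "g", "mg", "K", "Pa", "kPa", "mol", "L", "mL", "s")
_EXTERNAL_UNIT_IRIS = ("http://qudt.org/vocab/unit/M",
                       "http://qudt.org/vocab/unit/DEG_C")


def _random_numeric(rng: random.Random) -> NumericValue:
    kind = rng.randrange(3)
    if kind == 0:
        return NumericValue(rng.randint(-1000, 1000), numeric_type="integer",
                            exact=rng.random() < 0.3)
    lexical = f"{rng.uniform(-100, 100):.{rng.randint(1, 6)}f}"
    if kind == 1:
        return NumericValue(lexical, sigfigs=rng.randint(1, 6))
    return NumericValue(lexical, error=Decimal(f"{rng.uniform(0, 1):.3f}"))


def _random_parameter(rng: random.Random) -> object:
    prop = rng.choice(("temperature", "pressure", "mass", "volume", "concentration"))
    unit = None
    r = rng.random()
    if r < 0.4:
        unit = UnitSpec.from_str(rng.choice(_UNIT_SYMBOLS))
    elif r < 0.7:
        unit = UnitSpec.from_unit(get_unit(rng.choice(_UNIT_SYMBOLS)))
    elif r < 0.8:
        unit = UnitSpec.from_ref(rng.choice(_EXTERNAL_UNIT_IRIS))
    if rng.random() < 0.2:
        return make_parameter(prop, TextValue(f"qualitative {prop} note"), unit_spec=None)
    return make_parameter(prop, _random_numeric(rng), unit_spec=unit)


def _random(spec: FixtureSpec) -> m.SciDataDocument:
    rng = random.Random(spec.seed)
    doc = m.build_document(
        {"title": f"randomized document {spec.seed}",
         "authors": ["R. Generator", "S. Seeder"],
         "version": rng.randint(1, 9)},
        f"https://example.org/scidata/random/{spec.seed}/")
    doc.scidata.discipline = rng.choice(("chemistry", "physics", "biology"))
    doc.scidata.methodology = m.Methodology(
        evaluation=rng.choice(("experimental", "computational", "theoretical")))
    aspects = [m.add_aspect(doc, rng.choice(_ASPECT_KINDS),
                            {"technique": rng.choice(_TECHNIQUES)}
                            if rng.random() < 0.7 else
                            {"settings": _random_parameter(rng)})
               for _ in range(rng.randint(1, 3))]
    facets = []
    for _ in range(rng.randint(1, 3)):
        kind = rng.choice(_FACET_KINDS)
        if kind == "substance":
            name, formula = rng.choice(_SUBSTANCES)
            meta = {"name": name, "formula": formula}
        else:
            meta = {"conditions": _random_parameter(rng)}
        facets.append(m.add_facet(doc, kind, meta))

    def refs():
        src = [rng.choice(aspects).aspect_id] if rng.random() < 0.8 else []
        scp = [rng.choice(facets).facet_id] if rng.random() < 0.8 else []
        return src, scp

    points = []
    for _ in range(rng.randint(0, 3)):
        src, scp = refs()
        nparams = rng.randint(1, 3)
        points.append(m.add_datapoint(doc, [_random_parameter(rng) for _ in range(nparams)],
                                      source_refs=src, scope_refs=scp))

    def random_values():
        n = rng.randint(1, spec.points_per_series)
        choice = rng.randrange(3)
        if choice == 0:
            return [rng.randint(-999, 999) for _ in range(max(n, 2))]
        if choice == 1:
            return [Decimal(f"{rng.uniform(-50, 50):.4f}") for _ in range(max(n, 2))]
        return [f"category-{rng.randint(0, 9)}" for _ in range(max(n, 2))]

    for _ in range(rng.randint(0, 2)):
        if points and rng.random() < 0.3:
            m.add_dataseries(doc, _random_parameter(rng),
                             values=[p.point_id for p in points],
                             label="series of datapoint links", values_are_refs=True)
        else:
            m.add_dataseries(doc, _random_parameter(rng), values=random_values(),
                             label=f"series {rng.randint(0, 99)}")

    def build_group(depth: int, into=None):
        src, scp = refs()
        group = m.add_datagroup(doc, rng.choice(("spectrum", "table", "collection")),
                                source_refs=src, scope_refs=scp, into=into)
        if rng.random() < 0.5:
            group.attributes.append(_random_parameter(rng))
        for _ in range(rng.randint(1, 2)):
            if depth > 0 and rng.random() < 0.5:
                build_group(depth - 1, into=group)
            else:
                m.add_dataseries(doc, _random_parameter(rng), values=random_values(),
                                 into=group)
        return group

    for _ in range(rng.randint(0, 2)):
        build_group(rng.randint(0, spec.nesting_depth))
    return doc


_BUILDERS = {
    "ph": _ph,
    "refractive_index": _refractive_index,
    "nmr_limonene": _nmr_limonene,
    "glucose_scf": _glucose_scf,
    "random": _random,
}


# --------------------------------------------------------------------------
# synthetic JCAMP-DX files

def make_jcamp(seed: int, npoints: int) -> tuple[str, XYData]:
    """Generate a valid AFFN/PAC JCAMP-DX file plus its ground-truth data.

    The encoding (AFFN ``(X++(Y..Y))``, PAC ``(X++(Y..Y))``, or AFFN
    ``(XY..XY)`` point pairs) is drawn from the seed.  The returned
    :class:`XYData` holds exactly the values a correct decode recovers.
    """
    if npoints < 1:
        raise ModelError("npoints must be >= 1")
    rng = random.Random(seed)
    style = rng.choice(("affn", "pac", "points"))
    firstx = float(rng.randint(400, 4000))
    deltax = round(rng.uniform(0.5, 2.0), 3)
    lastx = firstx + (npoints - 1) * deltax
    yfactor = rng.choice((1.0, 0.01, 0.001))
    y_raw = [rng.randint(0, 99999) for _ in range(npoints)]
    x = [firstx + i * deltax for i in range(npoints)]
    y = [v * yfactor for v in y_raw]

    header = [
        f"##TITLE= synthetic spectrum {seed}",
        "##JCAMP-DX= 4.24",
        "##DATA TYPE= INFRARED SPECTRUM",
        "##ORIGIN= scidata fixture generator",
        "##OWNER= public domain",
        "##XUNITS= 1/CM",
        "##YUNITS= ABSORBANCE",
        "##XFACTOR= 1.0",
        f"##YFACTOR= {yfactor}",
        f"##FIRSTX= {firstx}",
        f"##LASTX= {lastx}",
        f"##DELTAX= {deltax}",
        f"##NPOINTS= {npoints}",
    ]
    lines = list(header)
    if style == "points":
        lines.append("##XYPOINTS= (XY..XY)")
        for i in range(npoints):
            lines.append(f"{x[i]!r}, {y_raw[i]}")
    else:
        lines.append("##XYDATA= (X++(Y..Y))")
        per_line = 6
        for start in range(0, npoints, per_line):
            chunk = y_raw[start:start + per_line]
            xs = f"{x[start]:.3f}"
            if style == "affn":
                lines.append(xs + " " + " ".join(str(v) for v in chunk))
            else:  # PAC: ordinates packed with their signs
                lines.append(xs + "".join(f"{v:+d}" for v in chunk))
    lines.append("##END=")
    truth = XYData(x=list(x), y=list(y), x_units="1/CM", y_units="ABSORBANCE",
                   firstx=firstx, lastx=lastx, npoints=npoints)
    return "\n".join(lines) + "\n", truth
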