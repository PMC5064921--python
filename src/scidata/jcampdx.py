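"""JCAMP-DX spectral file reader and converter to SciData documents.

JCAMP-DX files are sequences of LABELLED-DATA-RECORDs (LDRs), lines of
the form ``##LABEL= value`` with continuation lines and ``$$`` comments,
carrying spectral metadata plus a two-column data table.  This reader
decodes the uncompressed encodings — AFFN (free-form numeric, delimiter
separated) and PAC (packed, sign separated) — in both table shapes,
``(X++(Y..Y))`` and ``(XY..XY)``.  The squeezed/difference/duplicate
compression forms (SQZ/DIF/DUP) are rejected explicitly rather than
risk silent misreads; inside data tables any alphabetic pseudo-digit
(including an ambiguous exponent ``E``) triggers that rejection.

Conversion produces a document with one ``spectrum`` datagroup holding
the x and y dataseries, a ``measurement`` aspect carrying the technique
and instrument LDRs, and a ``substance`` facet from the title records.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from decimal import Decimal
from importlib import resources

import yaml

from . import model as m
from .errors import JcampIntegrityError, MalformedJcampError, UnsupportedEncodingError
from .quantity import make_parameter

DATA_LABELS = frozenset({"XYDATA", "XYPOINTS", "PEAKTABLE", "DATATABLE"})

#: LDRs consumed structurally by the decoder; never copied into metadata.
STRUCTURAL_LABELS = DATA_LABELS | frozenset({
    "JCAMPDX", "XUNITS", "YUNITS", "XFACTOR", "YFACTOR", "FIRSTX", "LASTX",
    "FIRSTY", "NPOINTS", "DELTAX", "MAXX", "MINX", "MAXY", "MINY", "END",
})


def normalize_label(label: str) -> str:
    """JCAMP label comparison form: uppercase, spaces/dashes/underscores out."""
    return re.sub(r"[ \t_/-]", "", label).upper()


@dataclass
class JcampRecord:
    """One LDR: original label, raw (possibly multi-line) value."""

    label: str
    raw_value: str
    is_data_record: bool = False
    comments: list[str] = field(default_factory=list)

    @property
    def normalized(self) -> str:
        return normalize_label(self.label)


@dataclass
class XYData:
    x: list[float]
    y: list[float]
    x_units: str = ""
    y_units: str = ""
    firstx: float | None = None
    lastx: float | None = None
    npoints: int | None = None


def parse_jcamp(text: str) -> list[JcampRecord]:
    """Split a JCAMP-DX file into its ordered LDRs.

    The first record must be ``##TITLE=`` and a ``##END=`` record must
    close the block; continuation lines are joined with newlines and
    ``$$`` comments are stripped but kept on the enclosing record.
    """
    records: list[JcampRecord] = []
    current: JcampRecord | None = None
    pending_comments: list[str] = []
    for lineno, line in enumerate(text.splitlines(), 1):
        body, comment = _split_comment(line)
        if comment is not None:
            (current.comments if current else pending_comments).append(comment)
        if body.startswith("##"):
            label, eq, value = body[2:].partition("=")
            if not eq:
                raise MalformedJcampError(f"LDR line has no '=': {body!r}", line=lineno)
            label = label.strip()
            current = JcampRecord(label=label, raw_value=value.strip(),
                                  is_data_record=normalize_label(label) in DATA_LABELS)
            current.comments.extend(pending_comments)
            pending_comments.clear()
            if not records and current.normalized != "TITLE":
                raise MalformedJcampError(
                    f"file must start with ##TITLE=, found ##{label}=", line=lineno)
            records.append(current)
            if current.normalized == "END":
                break
        elif body.strip():
            if current is None:
                raise MalformedJcampError("data before the first LDR", line=lineno)
            current.raw_value += ("\n" if current.raw_value else "") + body.strip()
    if not records:
        raise MalformedJcampError("missing ##TITLE= record")
    if records[-1].normalized != "END":
        raise MalformedJcampError("missing ##END= record")
    return records


def _split_comment(line: str):
    idx = line.find("$$")
    if idx < 0:
        return line, None
    return line[:idx], line[idx + 2:].strip()


_NUMBER = re.compile(r"[+-]?(?:\d+\.?\d*|\.\d+)")
_SEPARATORS = re.compile(r"[\s,;]+")


def _tokenize_data_line(line: str, lineno_hint: str = "") -> list[float]:
    """Numbers from an AFFN or PAC data line.

    AFFN separates values with whitespace/commas; PAC packs them with
    their signs.  Any alphabetic character is a compression pseudo-digit
    (SQZ/DIF/DUP) or an ambiguous exponent and is rejected.
    """
    bad = re.search(r"[@%?A-Za-z]", line)
    if bad:
        raise UnsupportedEncodingError(
            f"data table contains {bad.group()!r}: SQZ/DIF/DUP compression "
            f"(or exponent notation) is not supported{lineno_hint}")
    residue = _SEPARATORS.sub("", _NUMBER.sub("", line))
    if residue:
        raise UnsupportedEncodingError(
            f"unrecognized characters {residue!r} in data table{lineno_hint}")
    return [float(tok) for tok in _NUMBER.findall(line)]


def _record_map(records) -> dict[str, JcampRecord]:
    out = {}
    for r in records:
        out.setdefault(r.normalized, r)
    return out


def _get_float(recmap, label, default=None):
    rec = recmap.get(label)
    if rec is None:
        return default
    return float(rec.raw_value.split("\n")[0])


def decode_xydata(records: list[JcampRecord]) -> XYData:
    """Decode the data table into scaled x/y arrays.

    ``(X++(Y..Y))`` tables rebuild x from FIRSTX plus a uniform
    increment (DELTAX, or the FIRSTX/LASTX/NPOINTS grid) and scale y by
    YFACTOR; ``(XY..XY)`` tables read pairs and scale by both factors.
    A declared NPOINTS that disagrees with the decoded count is an
    integrity error.
    """
    recmap = _record_map(records)
    data = next((r for r in records if r.is_data_record), None)
    if data is None:
        raise MalformedJcampError("no data table LDR (##XYDATA=, ##XYPOINTS= or ##PEAK TABLE=)")
    lines = data.raw_value.split("\n")
    variable_list = normalize_label(lines[0])
    xfactor = _get_float(recmap, "XFACTOR", 1.0)
    yfactor = _get_float(recmap, "YFACTOR", 1.0)
    firstx = _get_float(recmap, "FIRSTX")
    lastx = _get_float(recmap, "LASTX")
    npoints_rec = recmap.get("NPOINTS")
    npoints = int(float(npoints_rec.raw_value)) if npoints_rec else None

    if "X++" in variable_list:
        ys: list[float] = []
        for line in lines[1:]:
            tokens = _tokenize_data_line(line)
            if not tokens:
                continue
            ys.extend(tokens[1:])  # first token is the line's abscissa check value
        if npoints is None or firstx is None or lastx is None:
            raise MalformedJcampError(
                "(X++(Y..Y)) data requires FIRSTX, LASTX and NPOINTS records")
        if len(ys) != npoints:
            raise JcampIntegrityError(
                f"declared NPOINTS={npoints} but decoded {len(ys)} ordinates")
        deltax = _get_float(recmap, "DELTAX")
        if deltax is None:
            deltax = (lastx - firstx) / (npoints - 1) if npoints > 1 else 0.0
        x = [firstx + i * deltax for i in range(npoints)]
        y = [v * yfactor for v in ys]
    else:
        flat: list[float] = []
        for line in lines[1:]:
            flat.extend(_tokenize_data_line(line))
        if len(flat) % 2:
            raise JcampIntegrityError(
                f"pairwise data table has an odd token count ({len(flat)})")
        x = [v * xfactor for v in flat[0::2]]
        y = [v * yfactor for v in flat[1::2]]
        if npoints is not None and len(x) != npoints:
            raise JcampIntegrityError(
                f"declared NPOINTS={npoints} but decoded {len(x)} points")

    return XYData(
        x=x, y=y,
        x_units=recmap["XUNITS"].raw_value if "XUNITS" in recmap else "",
        y_units=recmap["YUNITS"].raw_value if "YUNITS" in recmap else "",
        firstx=firstx, lastx=lastx, npoints=npoints if npoints is not None else len(x))


_MAPPING: dict | None = None


def ldr_mapping() -> dict:
    """The bundled (editable) LDR→model mapping table."""
    global _MAPPING
    if _MAPPING is None:
        _MAPPING = yaml.safe_load(
            resources.files("scidata").joinpath("data/jcamp_map.yaml").read_text())
    return _MAPPING


def jcamp_to_scidata(records: list[JcampRecord],
                     base_iri: str = "https://example.org/scidata/jcamp/",
                     mapping: dict | None = None) -> m.SciDataDocument:
    """Convert parsed LDRs into a validated SciData document.

    The spectrum lands in a ``spectrum`` datagroup holding the x and y
    dataseries, linked by source to a ``measurement`` aspect and by
    scope to a ``substance`` facet.  A file without any data table
    yields a metadata-only document (with a warning).
    """
    mapping = mapping or ldr_mapping()
    root_meta: dict = {}
    aspect_meta: dict = {}
    facet_meta: dict = {}
    for rec in records:
        norm = rec.normalized
        if norm in STRUCTURAL_LABELS:
            continue
        value = rec.raw_value
        entry = mapping.get(norm)
        if entry is None:
            aspect_meta[rec.label.strip().lower().replace(" ", "_")] = value
        elif entry["target"] == "root":
            root_meta.setdefault(entry["key"], value)
        elif entry["target"] == "facet":
            facet_meta.setdefault(entry["key"], value)
        else:
            aspect_meta.setdefault(entry["key"], value)

    doc = m.build_document(root_meta, base_iri)
    doc.scidata.discipline = "chemistry"
    doc.scidata.methodology = m.Methodology(evaluation="experimental")
    aspect = m.add_aspect(doc, "measurement", aspect_meta)
    title = _record_map(records).get("TITLE")
    facet_meta.setdefault("name", title.raw_value if title else "unknown substance")
    facet = m.add_facet(doc, "substance", facet_meta)

    if any(r.is_data_record for r in records):
        xy = decode_xydata(records)
        group = m.add_datagroup(doc, "spectrum",
                                source_refs=[aspect.aspect_id],
                                scope_refs=[facet.facet_id])
        x_name = xy.x_units or "x"
        y_name = xy.y_units or "y"
        m.add_dataseries(
            doc, make_parameter(x_name.lower(), _axis_value(xy.x),
                                unit_spec=xy.x_units or None),
            values=[Decimal(repr(v)) for v in xy.x], label=x_name.lower(), into=group)
        m.add_dataseries(
            doc, make_parameter(y_name.lower(), _axis_value(xy.y),
                                unit_spec=xy.y_units or None),
            values=[Decimal(repr(v)) for v in xy.y], label=y_name.lower(), into=group)
    else:
        warnings.warn("JCAMP-DX file has no data table; producing a metadata-only document",
                      stacklevel=2)

    m.compute_toc(doc)
    return doc


def _axis_value(values: list[float]):
    # the series parameter describes the axis; summarize extent as its value
    from .quantity import NumericValue
    return NumericValue(len(values), numeric_type="integer", exact=True)
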