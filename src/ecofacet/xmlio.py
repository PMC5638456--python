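"""XML serialization: schema (XSD) emission plus annotation-document
reading and writing.

Documents use the artifact-defined namespace :data:`NAMESPACE` with a
semantic ``schemaVersion`` attribute (:data:`SCHEMA_VERSION`); minor
versions may only add optional elements, so documents from an older minor
version are read with a warning while a different major version is
refused.  Element order is fixed to registry order, timestamps are
serialized exactly as entered, and every term reference carries its id /
URI / lifecycle status as attributes with the label as element text.
"""

from __future__ import annotations

import io
import xml.etree.ElementTree as ET
import xml.parsers.expat

from . import model as M
from .errors import DocumentError, SerializationError
from .vocabulary import Vocabulary

__all__ = ["NAMESPACE", "SCHEMA_VERSION", "emit_xsd", "write_record",
           "read_record", "read_record_with_issues"]

NAMESPACE = "urn:ecofacet:annotation:1"
SCHEMA_VERSION = "1.0.0"

XSNS = "http://www.w3.org/2001/XMLSchema"

_RANK_ELEMS = ("eon", "era", "period", "epoch", "age")
_TAXON_ELEMS = {"domain": "domain", "kingdom": "kingdom",
                "division_or_phylum": "divisionOrPhylum", "class": "class",
                "order": "order", "family": "family", "genus": "genus"}
_TAXON_FROM_ELEM = {v: k for k, v in _TAXON_ELEMS.items()}


# ------------------------------------------------------------------ XSD
def _enum_name(path: str) -> str:
    return "".join(p.capitalize() for p in path.replace("_", "/").split("/")) + "Values"


def _closed_labels(fld: M.FacetField, vocab: Vocabulary) -> list[str]:
    labels: list[str] = []
    for p in fld.closed_list_ref:
        labels.extend(t.label for t in vocab.terms_at(p))
    return labels


def emit_xsd(registry=None, vocab: Vocabulary | None = None) -> str:
    """Deterministic XSD for the annotation document dialect.

    Closed term fields are constrained by enumerations drawn from the
    vocabulary; open term fields share an unconstrained term-reference
    type.  Re-emitting from the same registry and vocabulary is
    byte-identical.
    """
    from .vocabulary import load_vocabulary
    if registry is None:
        registry = M.field_registry()
    if vocab is None:
        vocab = load_vocabulary()
    fields = {f.path: f for f in registry}

    E = ET.Element
    schema = E("xs:schema", {
        "xmlns:xs": XSNS,
        "xmlns:ef": NAMESPACE,
        "targetNamespace": NAMESPACE,
        "elementFormDefault": "qualified",
        "attributeFormDefault": "unqualified",
        "version": SCHEMA_VERSION,
    })

    def simple_enum(name: str, values: list[str]):
        st = E("xs:simpleType", {"name": name})
        r = E("xs:restriction", {"base": "xs:string"})
        for v in values:
            r.append(E("xs:enumeration", {"value": v}))
        st.append(r)
        schema.append(st)

    def term_type(name: str, base: str):
        ct = E("xs:complexType", {"name": name})
        sc = E("xs:simpleContent")
        ext = E("xs:extension", {"base": base})
        for attr in ("id", "uri", "status"):
            ext.append(E("xs:attribute", {"name": attr, "type": "xs:string"}))
        sc.append(ext)
        ct.append(sc)
        schema.append(ct)

    # one enumeration + term type per closed field, shared TermType for open
    seen_enum: set[str] = set()
    for f in registry:
        if f.kind != "closed_term":
            continue
        name = _enum_name(f.path)
        if name in seen_enum:
            continue
        seen_enum.add(name)
        simple_enum(name, _closed_labels(f, vocab))
        term_type(name.removesuffix("Values") + "Term", "ef:" + name)
    term_type("TermType", "xs:string")
    simple_enum("AccessKindValues", list(M.ACCESS_KINDS))

    def tref(path: str) -> str:
        f = fields[path]
        if f.kind == "closed_term":
            return "ef:" + _enum_name(f.path).removesuffix("Values") + "Term"
        return "ef:TermType"

    def ctype(name: str, children, attrs=()):
        ct = E("xs:complexType", {"name": name})
        seq = E("xs:sequence")
        for item in children:
            if isinstance(item, ET.Element) or not isinstance(item, tuple):
                seq.append(item)
                continue
            cname, ctype_ref, lo, hi = item
            seq.append(E("xs:element", {
                "name": cname, "type": ctype_ref,
                "minOccurs": str(lo),
                "maxOccurs": "unbounded" if hi is None else str(hi)}))
        ct.append(seq)
        for aname, atype, use in attrs:
            a = {"name": aname, "type": atype}
            if use:
                a["use"] = use
            ct.append(E("xs:attribute", a))
        schema.append(ct)

    ctype("PartyType", [("name", "xs:string", 1, 1),
                        ("address", "xs:string", 0, 1),
                        ("email", "xs:string", 0, 1)],
          [("role", "xs:string", "required")])
    # access is simple content with a kind attribute
    at = E("xs:complexType", {"name": "AccessType"})
    sc = E("xs:simpleContent")
    ext = E("xs:extension", {"base": "xs:string"})
    ext.append(E("xs:attribute", {"name": "kind", "type": "ef:AccessKindValues",
                                  "use": "required"}))
    sc.append(ext)
    at.append(sc)
    schema.append(at)

    ctype("GeneralType", [("title", "xs:string", 1, 1),
                          ("abstract", "xs:string", 0, 1),
                          ("party", "ef:PartyType", 1, None),
                          ("dataCenter", "xs:string", 0, 1),
                          ("access", "ef:AccessType", 0, 1)])
    ctype("GeologicalType",
          [(r, tref(f"time/geological/{r}"), 0, 1) for r in _RANK_ELEMS])
    ctype("TimeType", [("start", "xs:string", 0, 1),
                       ("end", "xs:string", 0, 1),
                       ("timezone", tref("time/timezone"), 0, 1),
                       ("geological", "ef:GeologicalType", 0, 1),
                       ("resolution", tref("time/resolution"), 0, 1),
                       ("extent", tref("time/extent"), 0, 1)])
    ctype("LocationType", [("name", "xs:string", 1, 1),
                           ("type", tref("space/location/type"), 0, 1),
                           ("country", tref("space/location/country"), 0, 1),
                           ("continent", tref("space/location/continent"), 0, 1)])
    bb = E("xs:complexType", {"name": "BoundingBoxType"})
    for aname in ("west", "south", "east", "north"):
        bb.append(E("xs:attribute", {"name": aname, "type": "xs:decimal",
                                     "use": "required"}))
    schema.append(bb)
    pt = E("xs:complexType", {"name": "PointType"})
    for aname in ("latitude", "longitude"):
        pt.append(E("xs:attribute", {"name": aname, "type": "xs:decimal",
                                     "use": "required"}))
    schema.append(pt)
    ut = E("xs:complexType", {"name": "UtmPointType"})
    for aname, atype in (("zone", "xs:string"), ("easting", "xs:decimal"),
                         ("northing", "xs:decimal"), ("datum", "xs:string")):
        ut.append(E("xs:attribute", {"name": aname, "type": atype,
                                     "use": "required"}))
    schema.append(ut)

    space_ct = E("xs:complexType", {"name": "SpaceType"})
    seq = E("xs:sequence")
    seq.append(E("xs:element", {"name": "location", "type": "ef:LocationType",
                                "minOccurs": "0", "maxOccurs": "unbounded"}))
    seq.append(E("xs:element", {"name": "boundingBox",
                                "type": "ef:BoundingBoxType",
                                "minOccurs": "0", "maxOccurs": "1"}))
    choice = E("xs:choice", {"minOccurs": "0", "maxOccurs": "unbounded"})
    choice.append(E("xs:element", {"name": "point", "type": "ef:PointType"}))
    choice.append(E("xs:element", {"name": "utmPoint", "type": "ef:UtmPointType"}))
    seq.append(choice)
    for cname, path in (("resolution", "space/resolution"),
                        ("extent", "space/extent")):
        seq.append(E("xs:element", {"name": cname, "type": tref(path),
                                    "minOccurs": "0", "maxOccurs": "1"}))
    space_ct.append(seq)
    schema.append(space_ct)

    ctype("SphereType", [("layer", tref("sphere/layer"), 0, None),
                         ("organization", tref("sphere/organization"), 0, 1)])
    ctype("BiomeType", [("latitudinal", tref("biome/latitudinal"), 0, 1),
                        ("altitudinal", tref("biome/altitudinal"), 0, 1),
                        ("moisture", tref("biome/moisture"), 0, 1),
                        ("continentality", tref("biome/continentality"), 0, 1),
                        ("physiognomy", tref("biome/physiognomy"), 0, 1),
                        ("special", tref("biome/special"), 0, 1),
                        ("condition", tref("biome/condition"), 0, 1),
                        ("usage", tref("biome/usage"), 0, None)])
    ctype("OrganismNameType", [("value", "xs:string", 1, 1),
                               ("code", tref("organism/code"), 0, 1)])
    ctype("TaxonomyType",
          [(e, "xs:string", 0, 1) for e in
           ("domain", "kingdom", "divisionOrPhylum", "class", "order",
            "family", "genus")])
    ctype("OrganismType", [("name", "ef:OrganismNameType", 0, None),
                           ("taxonomy", "ef:TaxonomyType", 0, 1)])
    ctype("ProcessItemType",
          [("name", tref("process/name"), 1, 1),
           ("involved", tref("process/involved"), 0, None),
           ("characterization", tref("process/characterization"), 0, 1)])
    ctype("InteractionType",
          [("name", tref("process/interaction/name"), 0, 1),
           ("partnerA", tref("process/interaction/partner_a"), 1, 1),
           ("partnerB", tref("process/interaction/partner_b"), 1, 1),
           ("direction", tref("process/interaction/direction"), 1, 1),
           ("quality", tref("process/interaction/quality"), 0, 1)])
    ctype("ProcessType", [("processItem", "ef:ProcessItemType", 0, None),
                          ("interaction", "ef:InteractionType", 0, None)])
    ctype("ChemicalType", [("element", tref("chemical/element"), 0, None),
                           ("compound", tref("chemical/compound"), 0, None),
                           ("function", tref("chemical/function"), 0, None)])
    ctype("MethodType", [("approach", tref("method/approach"), 0, 1),
                         ("context", tref("method/context"), 0, 1),
                         ("variable", tref("method/variable"), 0, None)])
    ctype("AnnotationType",
          [("general", "ef:GeneralType", 1, 1),
           ("time", "ef:TimeType", 0, 1),
           ("space", "ef:SpaceType", 0, 1),
           ("sphere", "ef:SphereType", 0, 1),
           ("biome", "ef:BiomeType", 0, 1),
           ("organism", "ef:OrganismType", 0, 1),
           ("process", "ef:ProcessType", 0, 1),
           ("chemical", "ef:ChemicalType", 0, 1),
           ("method", "ef:MethodType", 0, 1)],
          [("id", "xs:string", "required"),
           ("schemaVersion", "xs:string", "required")])
    schema.append(E("xs:element", {"name": "annotation",
                                   "type": "ef:AnnotationType"}))

    ET.indent(schema, space="  ")
    return ('<?xml version="1.0" encoding="UTF-8"?>\n'
            + ET.tostring(schema, encoding="unicode") + "\n")


# ---------------------------------------------------------------- writer
def _num(v) -> str:
    f = float(v)
    return str(int(f)) if f == int(f) and abs(f) < 1e15 else repr(f)


def _term_elem(parent: ET.Element, tag: str, ref: M.TermRef) -> ET.Element:
    e = ET.SubElement(parent, tag)
    e.text = ref.label
    if ref.id is not None:
        e.set("id", ref.id)
    if ref.uri is not None:
        e.set("uri", ref.uri)
    if ref.status is not None:
        e.set("status", ref.status)
    return e


def _text_elem(parent, tag, text):
    e = ET.SubElement(parent, tag)
    e.text = text
    return e


def write_record(record: M.AnnotationRecord, vocab: Vocabulary) -> str:
    """Serialize a record to an annotation document (UTF-8 XML string).

    The record must validate without errors; term references are resolved
    first so serialized terms carry their canonical ids and URIs.
    """
    issues = M.validate_record(record, vocab)
    errors = [i for i in issues if i.severity == "error"]
    if errors:
        raise SerializationError("record has validation errors", errors)
    r = M.resolve_terms(record, vocab)

    root = ET.Element("annotation", {
        "xmlns": NAMESPACE, "id": r.record_id, "schemaVersion": SCHEMA_VERSION})
    g = ET.SubElement(root, "general")
    _text_elem(g, "title", r.general.title)
    if r.general.abstract:
        _text_elem(g, "abstract", r.general.abstract)
    for p in r.general.parties:
        pe = ET.SubElement(g, "party", {"role": p.role})
        _text_elem(pe, "name", p.name)
        if p.address is not None:
            _text_elem(pe, "address", p.address)
        if p.email is not None:
            _text_elem(pe, "email", p.email)
    if r.general.data_center is not None:
        _text_elem(g, "dataCenter", r.general.data_center)
    if r.general.access is not None:
        ae = _text_elem(g, "access", r.general.access.value)
        ae.set("kind", r.general.access.kind)

    t = r.time
    if t is not None:
        te = ET.SubElement(root, "time")
        if t.start is not None:
            _text_elem(te, "start", t.start)
        if t.end is not None:
            _text_elem(te, "end", t.end)
        if t.timezone is not None:
            _term_elem(te, "timezone", t.timezone)
        if t.geological is not None:
            ge = ET.SubElement(te, "geological")
            for rank, refv in t.geological.items():
                if refv is not None:
                    _term_elem(ge, rank, refv)
        if t.resolution is not None:
            _term_elem(te, "resolution", t.resolution)
        if t.extent is not None:
            _term_elem(te, "extent", t.extent)

    s = r.space
    if s is not None:
        se = ET.SubElement(root, "space")
        for loc in s.locations:
            le = ET.SubElement(se, "location")
            _text_elem(le, "name", loc.name)
            if loc.location_type is not None:
                _term_elem(le, "type", loc.location_type)
            if loc.country is not None:
                _term_elem(le, "country", loc.country)
            if loc.continent is not None:
                _term_elem(le, "continent", loc.continent)
        if s.bounding_box is not None:
            bb = s.bounding_box
            ET.SubElement(se, "boundingBox", {
                "west": _num(bb.west), "south": _num(bb.south),
                "east": _num(bb.east), "north": _num(bb.north)})
        for pt in s.points:
            if isinstance(pt, M.GeoPoint):
                ET.SubElement(se, "point", {
                    "latitude": _num(pt.latitude),
                    "longitude": _num(pt.longitude)})
            else:
                ET.SubElement(se, "utmPoint", {
                    "zone": pt.utm_zone, "easting": _num(pt.easting),
                    "northing": _num(pt.northing), "datum": pt.datum})
        if s.resolution is not None:
            _term_elem(se, "resolution", s.resolution)
        if s.extent is not None:
            _term_elem(se, "extent", s.extent)

    sp = r.sphere
    if sp is not None:
        spe = ET.SubElement(root, "sphere")
        for layer in sp.spheres:
            _term_elem(spe, "layer", layer)
        if sp.organization is not None:
            _term_elem(spe, "organization", sp.organization)

    b = r.biome
    if b is not None:
        be = ET.SubElement(root, "biome")
        for attr in ("latitudinal", "altitudinal", "moisture",
                     "continentality", "physiognomy", "special", "condition"):
            refv = getattr(b, attr)
            if refv is not None:
                _term_elem(be, attr, refv)
        for refv in b.usage:
            _term_elem(be, "usage", refv)

    o = r.organism
    if o is not None:
        oe = ET.SubElement(root, "organism")
        for n in o.names:
            ne = ET.SubElement(oe, "name")
            _text_elem(ne, "value", n.scientific_name)
            if n.code is not None:
                _term_elem(ne, "code", n.code)
        if o.taxonomy:
            tx = ET.SubElement(oe, "taxonomy")
            for rank, elem_name in _TAXON_ELEMS.items():
                if rank in o.taxonomy:
                    _text_elem(tx, elem_name, o.taxonomy[rank])

    p = r.process
    if p is not None:
        pe = ET.SubElement(root, "process")
        for proc in p.processes:
            pi = ET.SubElement(pe, "processItem")
            _term_elem(pi, "name", proc.name)
            for iv in proc.involved:
                _term_elem(pi, "involved", iv)
            if proc.characterization is not None:
                _term_elem(pi, "characterization", proc.characterization)
        for ia in p.interactions:
            ie = ET.SubElement(pe, "interaction")
            if ia.name is not None:
                _term_elem(ie, "name", ia.name)
            _term_elem(ie, "partnerA", ia.partner_a)
            _term_elem(ie, "partnerB", ia.partner_b)
            _term_elem(ie, "direction", ia.direction)
            if ia.quality is not None:
                _term_elem(ie, "quality", ia.quality)

    c = r.chemical
    if c is not None:
        ce = ET.SubElement(root, "chemical")
        for refv in c.elements:
            _term_elem(ce, "element", refv)
        for refv in c.compounds:
            _term_elem(ce, "compound", refv)
        for refv in c.functions:
            _term_elem(ce, "function", refv)

    m = r.method
    if m is not None:
        me = ET.SubElement(root, "method")
        if m.approach is not None:
            _term_elem(me, "approach", m.approach)
        if m.context is not None:
            _term_elem(me, "context", m.context)
        for refv in m.variables:
            _term_elem(me, "variable", refv)

    ET.indent(root, space="  ")
    return ('<?xml version="1.0" encoding="UTF-8"?>\n'
            + ET.tostring(root, encoding="unicode") + "\n")


# ---------------------------------------------------------------- reader
def _parse_with_lines(text: str):
    """Parse XML with expat, building an ElementTree and a side map of
    element -> source line (1-based)."""
    parser = xml.parsers.expat.ParserCreate()
    root: list[ET.Element] = []
    stack: list[ET.Element] = []
    lines: dict[int, int] = {}
    chunks: dict[int, list[str]] = {}

    def start(name, attrs):
        e = ET.Element(name, dict(attrs))
        lines[id(e)] = parser.CurrentLineNumber
        chunks[id(e)] = []
        if stack:
            stack[-1].append(e)
        else:
            root.append(e)
        stack.append(e)

    def end(name):
        e = stack.pop()
        text_ = "".join(chunks.pop(id(e)))
        e.text = text_ if text_.strip() else None

    def chars(data):
        if stack:
            chunks[id(stack[-1])].append(data)

    parser.StartElementHandler = start
    parser.EndElementHandler = end
    parser.CharacterDataHandler = chars
    try:
        parser.Parse(text, True)
    except xml.parsers.expat.ExpatError as e:
        raise DocumentError(f"malformed XML: {e}") from None
    if not root:
        raise DocumentError("empty document")
    return root[0], lines


def _read_term(elem: ET.Element | None) -> M.TermRef | None:
    if elem is None:
        return None
    return M.TermRef(label=elem.text or "", id=elem.get("id"),
                     uri=elem.get("uri"), status=elem.get("status"))


def read_record_with_issues(document: str,
                            vocab: Vocabulary) -> tuple[M.AnnotationRecord,
                                                        list[M.ValidationIssue]]:
    """Parse an annotation document; returns the record together with
    validation issues carrying XML line positions where known."""
    if hasattr(document, "read"):
        document = document.read()
    root, lines = _parse_with_lines(document)
    if root.tag != "annotation":
        raise DocumentError(f"unexpected root element <{root.tag}>")
    ns = root.get("xmlns")
    if ns != NAMESPACE:
        raise DocumentError(f"unknown namespace {ns!r}; expected {NAMESPACE!r}")
    issues: list[M.ValidationIssue] = []
    version = root.get("schemaVersion", "")
    parts = version.split(".")
    ours = SCHEMA_VERSION.split(".")
    if not version or parts[0] != ours[0]:
        raise DocumentError(
            f"unsupported schema version {version!r}; this reader handles "
            f"major version {ours[0]}")
    if parts[1:2] != ours[1:2]:
        issues.append(M.ValidationIssue(
            "warning", "schemaVersion",
            f"document version {version} differs from reader version "
            f"{SCHEMA_VERSION} in the minor component", version,
            lines.get(id(root))))

    field_lines: dict[str, int] = {}

    def note(path, elem):
        if elem is not None and path not in field_lines:
            field_lines[path] = lines.get(id(elem))

    def child(e, tag):
        return e.find(tag) if e is not None else None

    ge = child(root, "general")
    if ge is None:
        raise DocumentError("missing <general> block")
    parties = []
    for pe in ge.findall("party"):
        parties.append(M.Party(
            name=(pe.findtext("name") or ""), role=pe.get("role", "contact"),
            address=pe.findtext("address"), email=pe.findtext("email")))
    access = None
    ae = ge.find("access")
    if ae is not None:
        access = M.Access(kind=ae.get("kind", ""), value=ae.text or "")
        note("general/access", ae)
    general = M.GeneralInfo(
        title=ge.findtext("title") or "", abstract=ge.findtext("abstract") or "",
        parties=parties, data_center=ge.findtext("dataCenter"), access=access)
    note("general/title", child(ge, "title"))

    record = M.AnnotationRecord(record_id=root.get("id", ""), general=general)

    te = child(root, "time")
    if te is not None:
        geological = None
        gee = te.find("geological")
        if gee is not None:
            geological = M.GeologicalContext(
                **{rank: _read_term(gee.find(rank)) for rank in _RANK_ELEMS})
            note("time/geological", gee)
        record.time = M.TimeFacet(
            start=te.findtext("start"), end=te.findtext("end"),
            timezone=_read_term(te.find("timezone")), geological=geological,
            resolution=_read_term(te.find("resolution")),
            extent=_read_term(te.find("extent")))
        for tag, path in (("start", "time/start"), ("end", "time/end"),
                          ("timezone", "time/timezone"),
                          ("resolution", "time/resolution"),
                          ("extent", "time/extent")):
            note(path, te.find(tag))
        if gee is not None:
            for rank in _RANK_ELEMS:
                note(f"time/geological/{rank}", gee.find(rank))

    se = child(root, "space")
    if se is not None:
        locations = []
        for le in se.findall("location"):
            locations.append(M.Location(
                name=le.findtext("name") or "",
                location_type=_read_term(le.find("type")),
                country=_read_term(le.find("country")),
                continent=_read_term(le.find("continent"))))
            note("space/location/type", le.find("type"))
            note("space/location/country", le.find("country"))
            note("space/location/continent", le.find("continent"))
        bbox = None
        bbe = se.find("boundingBox")
        if bbe is not None:
            try:
                bbox = M.BoundingBox(*(float(bbe.get(a, "nan")) for a in
                                       ("west", "south", "east", "north")))
            except ValueError:
                raise DocumentError("non-numeric boundingBox coordinate")
            note("space/bounding_box", bbe)
        points: list = []
        for pe in se:
            tag = pe.tag
            if tag == "point":
                points.append(M.GeoPoint(
                    latitude=float(pe.get("latitude", "nan")),
                    longitude=float(pe.get("longitude", "nan"))))
                note("space/point", pe)
            elif tag == "utmPoint":
                points.append(M.UtmPoint(
                    utm_zone=pe.get("zone", ""),
                    easting=float(pe.get("easting", "nan")),
                    northing=float(pe.get("northing", "nan")),
                    datum=pe.get("datum", "WGS84")))
                note("space/point", pe)
        record.space = M.SpaceFacet(
            locations=locations, bounding_box=bbox, points=points,
            resolution=_read_term(se.find("resolution")),
            extent=_read_term(se.find("extent")))
        note("space/resolution", se.find("resolution"))
        note("space/extent", se.find("extent"))

    spe = child(root, "sphere")
    if spe is not None:
        record.sphere = M.SphereFacet(
            spheres=[_read_term(e) for e in spe.findall("layer")],
            organization=_read_term(spe.find("organization")))
        note("sphere/layer", spe.find("layer"))
        note("sphere/organization", spe.find("organization"))

    be = child(root, "biome")
    if be is not None:
        record.biome = M.BiomeFacet(
            **{attr: _read_term(be.find(attr)) for attr in
               ("latitudinal", "altitudinal", "moisture", "continentality",
                "physiognomy", "special", "condition")},
            usage=[_read_term(e) for e in be.findall("usage")])
        for attr in ("latitudinal", "altitudinal", "moisture", "continentality",
                     "physiognomy", "special", "condition", "usage"):
            note(f"biome/{attr}", be.find(attr))

    oe = child(root, "organism")
    if oe is not None:
        names = [M.OrganismName(scientific_name=ne.findtext("value") or "",
                                code=_read_term(ne.find("code")))
                 for ne in oe.findall("name")]
        taxonomy = {}
        tx = oe.find("taxonomy")
        if tx is not None:
            for e in tx:
                rank = _TAXON_FROM_ELEM.get(e.tag)
                if rank is not None and e.text:
                    taxonomy[rank] = e.text
        record.organism = M.OrganismFacet(names=names, taxonomy=taxonomy)
        for ne in oe.findall("name"):
            note("organism/code", ne.find("code"))

    pe = child(root, "process")
    if pe is not None:
        processes = []
        for pie in pe.findall("processItem"):
            processes.append(M.Process(
                name=_read_term(pie.find("name")),
                involved=[_read_term(e) for e in pie.findall("involved")],
                characterization=_read_term(pie.find("characterization"))))
            note("process/name", pie.find("name"))
        interactions = []
        for ie in pe.findall("interaction"):
            interactions.append(M.Interaction(
                partner_a=_read_term(ie.find("partnerA")),
                partner_b=_read_term(ie.find("partnerB")),
                direction=_read_term(ie.find("direction")),
                quality=_read_term(ie.find("quality")),
                name=_read_term(ie.find("name"))))
            for tag, sub in (("partnerA", "partner_a"), ("partnerB", "partner_b"),
                             ("direction", "direction"), ("quality", "quality"),
                             ("name", "name")):
                note(f"process/interaction/{sub}", ie.find(tag))
        record.process = M.ProcessFacet(processes=processes,
                                        interactions=interactions)

    ce = child(root, "chemical")
    if ce is not None:
        record.chemical = M.ChemicalFacet(
            elements=[_read_term(e) for e in ce.findall("element")],
            compounds=[_read_term(e) for e in ce.findall("compound")],
            functions=[_read_term(e) for e in ce.findall("function")])
        for tag, path in (("element", "chemical/element"),
                          ("compound", "chemical/compound"),
                          ("function", "chemical/function")):
            note(path, ce.find(tag))

    me = child(root, "method")
    if me is not None:
        record.method = M.MethodFacet(
            approach=_read_term(me.find("approach")),
            context=_read_term(me.find("context")),
            variables=[_read_term(e) for e in me.findall("variable")])
        note("method/approach", me.find("approach"))
        note("method/context", me.find("context"))
        note("method/variable", me.find("variable"))

    from .model import validate_record
    for issue in validate_record(record, vocab):
        issues.append(M.ValidationIssue(
            issue.severity, issue.field, issue.message, issue.value,
            field_lines.get(issue.field)))
    return record, issues


def read_record(document: str, vocab: Vocabulary) -> M.AnnotationRecord:
    """Parse an annotation document into a record (see
    :func:`read_record_with_issues` for schema-violation reporting)."""
    record, _ = read_record_with_issues(document, vocab)
    return record
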