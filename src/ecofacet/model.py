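"""Annotation record model: general metadata plus eight facet blocks.

The record structure is driven by a deterministic *field registry*
(:func:`field_registry`): one :class:`FacetField` per annotatable attribute,
stating its value kind, multiplicity and — for term-kinded fields — the
vocabulary subtree(s) its values come from.

Records reference vocabulary concepts through light-weight
:class:`TermRef` objects.  A ref may be entered by label only (as a user
would type it); :func:`resolve_terms` normalizes every ref to canonical
id + label + URI, following merge redirects of deprecated terms.
:func:`validate_record` turns every violated invariant into a
:class:`ValidationIssue` instead of raising.
"""

from __future__ import annotations

import copy
import re
from dataclasses import dataclass, field as dfield, replace
from typing import Iterable

from .errors import EcofacetError
from .vocabulary import Term, Vocabulary

__all__ = [
    "FacetField", "TermRef", "ref", "Party", "Access", "GeneralInfo",
    "GeologicalContext", "TimeFacet", "Location", "BoundingBox", "GeoPoint",
    "UtmPoint", "SpaceFacet", "SphereFacet", "BiomeFacet", "OrganismName",
    "OrganismFacet", "Process", "Interaction", "ProcessFacet",
    "ChemicalFacet", "MethodFacet", "AnnotationRecord", "ValidationIssue",
    "field_registry", "top_level_facets", "validate_record", "resolve_terms",
    "iso_interval", "FACETS", "TAXONOMIC_RANKS",
]

FACETS = ("time", "space", "sphere", "biome", "organism", "process",
          "chemical", "method")

TAXONOMIC_RANKS = ("domain", "kingdom", "division_or_phylum", "class",
                   "order", "family", "genus")

ACCESS_KINDS = ("url", "file_path", "database_id")


# --------------------------------------------------------------- registry
@dataclass(frozen=True)
class FacetField:
    """Registry entry describing one annotatable attribute."""

    path: str
    kind: str                     # closed_term | open_term | free_text |
                                  # numeric | timestamp | geospatial
    multiplicity: str = "optional"  # one | optional | many
    closed_list_ref: tuple[str, ...] = ()
    units: str | None = None


def _f(path, kind, multiplicity="optional", ref=None, units=None):
    refs = (ref,) if isinstance(ref, str) else tuple(ref or ())
    return FacetField(path, kind, multiplicity, refs, units)


_SPHERE_LAYERS = ("sphere/atmosphere", "sphere/hydrosphere",
                  "sphere/pedosphere", "sphere/lithosphere")

_REGISTRY: tuple[FacetField, ...] = (
    _f("general/title", "free_text", "one"),
    _f("general/abstract", "free_text"),
    _f("general/parties", "free_text", "many"),
    _f("general/data_center", "free_text"),
    _f("general/access", "free_text"),
    _f("time/start", "timestamp"),
    _f("time/end", "timestamp"),
    _f("time/timezone", "closed_term", ref="time/zone"),
    _f("time/geological/eon", "closed_term", ref="time/geological/eon"),
    _f("time/geological/era", "closed_term", ref="time/geological/era"),
    _f("time/geological/period", "closed_term", ref="time/geological/period"),
    _f("time/geological/epoch", "closed_term", ref="time/geological/epoch"),
    _f("time/geological/age", "closed_term", ref="time/geological/age"),
    _f("time/resolution", "closed_term", ref="time/unit"),
    _f("time/extent", "closed_term", ref="time/unit"),
    _f("space/location/name", "open_term", "many", ref="space/location_name"),
    _f("space/location/type", "closed_term", "many", ref="space/location_type"),
    _f("space/location/country", "closed_term", "many", ref="space/country"),
    _f("space/location/continent", "closed_term", "many", ref="space/continent"),
    _f("space/bounding_box", "geospatial", units="decimal degrees (WGS84)"),
    _f("space/point", "geospatial", "many", units="decimal degrees (WGS84) or UTM"),
    _f("space/resolution", "closed_term", ref="space/resolution"),
    _f("space/extent", "closed_term", ref="space/resolution"),
    _f("sphere/layer", "closed_term", "many", ref=_SPHERE_LAYERS),
    _f("sphere/organization", "closed_term", ref="sphere/organization"),
    _f("biome/latitudinal", "closed_term", ref="biome/latitudinal"),
    _f("biome/altitudinal", "closed_term", ref="biome/altitudinal"),
    _f("biome/moisture", "closed_term", ref="biome/moisture"),
    _f("biome/continentality", "closed_term", ref="biome/continentality"),
    _f("biome/physiognomy", "closed_term", ref="biome/physiognomy"),
    _f("biome/special", "closed_term", ref="biome/special"),
    _f("biome/condition", "closed_term", ref="biome/condition"),
    _f("biome/usage", "closed_term", "many", ref="biome/usage"),
    _f("organism/name", "free_text", "many"),
    _f("organism/code", "closed_term", "many", ref="organism/code"),
    _f("organism/taxonomy", "free_text", "many"),
    _f("process/name", "open_term", "many", ref="process/name"),
    _f("process/involved", "closed_term", "many", ref="process/involved"),
    _f("process/characterization", "closed_term", "many",
       ref="process/characterization"),
    _f("process/interaction/name", "open_term", "many",
       ref="process/interaction/name"),
    _f("process/interaction/partner_a", "closed_term", "many",
       ref="organism/kingdom"),
    _f("process/interaction/partner_b", "closed_term", "many",
       ref="organism/kingdom"),
    _f("process/interaction/direction", "closed_term", "many",
       ref="process/interaction/direction"),
    _f("process/interaction/quality", "closed_term", "many",
       ref="process/interaction/quality"),
    _f("chemical/element", "closed_term", "many", ref="chemical/element"),
    _f("chemical/compound", "open_term", "many", ref="chemical/compound"),
    _f("chemical/function", "closed_term", "many", ref="chemical/function"),
    _f("method/approach", "closed_term", ref="method/approach"),
    _f("method/context", "closed_term", ref="method/context"),
    _f("method/variable", "open_term", "many", ref="method/variable"),
)


def field_registry() -> list[FacetField]:
    """The complete, deterministic registry of annotatable attributes."""
    return list(_REGISTRY)


def registry_field(path: str) -> FacetField:
    for f in _REGISTRY:
        if f.path == path:
            return f
    raise KeyError(path)


def top_level_facets() -> list[str]:
    """The facet containers besides the general block (exactly eight)."""
    return list(FACETS)


# ------------------------------------------------------------------ types
@dataclass(frozen=True)
class TermRef:
    """Reference to a vocabulary concept; may be label-only before
    normalization."""

    label: str
    id: str | None = None
    uri: str | None = None
    status: str | None = None


def ref(label: str) -> TermRef:
    return TermRef(label=label)


@dataclass
class Party:
    name: str
    role: str = "contact"
    address: str | None = None
    email: str | None = None


@dataclass
class Access:
    kind: str                    # url | file_path | database_id
    value: str = ""


@dataclass
class GeneralInfo:
    title: str
    abstract: str = ""
    parties: list[Party] = dfield(default_factory=list)
    data_center: str | None = None
    access: Access | None = None


@dataclass
class GeologicalContext:
    eon: TermRef | None = None
    era: TermRef | None = None
    period: TermRef | None = None
    epoch: TermRef | None = None
    age: TermRef | None = None

    def items(self):
        return [(r, getattr(self, r)) for r in
                ("eon", "era", "period", "epoch", "age")]


@dataclass
class TimeFacet:
    start: str | None = None      # reduced-precision ISO 8601, kept verbatim
    end: str | None = None
    timezone: TermRef | None = None
    geological: GeologicalContext | None = None
    resolution: TermRef | None = None
    extent: TermRef | None = None


@dataclass
class Location:
    name: str
    location_type: TermRef | None = None
    country: TermRef | None = None
    continent: TermRef | None = None


@dataclass
class BoundingBox:
    """Decimal-degree box; west > east encodes an antimeridian wrap."""

    west: float
    south: float
    east: float
    north: float


@dataclass
class GeoPoint:
    latitude: float
    longitude: float


@dataclass
class UtmPoint:
    utm_zone: str
    easting: float
    northing: float
    datum: str = "WGS84"


@dataclass
class SpaceFacet:
    locations: list[Location] = dfield(default_factory=list)
    bounding_box: BoundingBox | None = None
    points: list = dfield(default_factory=list)   # GeoPoint | UtmPoint
    resolution: TermRef | None = None
    extent: TermRef | None = None


@dataclass
class SphereFacet:
    spheres: list[TermRef] = dfield(default_factory=list)
    organization: TermRef | None = None


@dataclass
class BiomeFacet:
    latitudinal: TermRef | None = None
    altitudinal: TermRef | None = None
    moisture: TermRef | None = None
    continentality: TermRef | None = None
    physiognomy: TermRef | None = None
    special: TermRef | None = None
    condition: TermRef | None = None
    usage: list[TermRef] = dfield(default_factory=list)


@dataclass
class OrganismName:
    scientific_name: str
    code: TermRef | None = None   # botanical | zoological | fungal | viral


@dataclass
class OrganismFacet:
    names: list[OrganismName] = dfield(default_factory=list)
    taxonomy: dict = dfield(default_factory=dict)  # rank -> value


@dataclass
class Process:
    name: TermRef
    involved: list[TermRef] = dfield(default_factory=list)
    characterization: TermRef | None = None


@dataclass
class Interaction:
    partner_a: TermRef
    partner_b: TermRef
    direction: TermRef
    quality: TermRef | None = None
    name: TermRef | None = None


@dataclass
class ProcessFacet:
    processes: list[Process] = dfield(default_factory=list)
    interactions: list[Interaction] = dfield(default_factory=list)


@dataclass
class ChemicalFacet:
    elements: list[TermRef] = dfield(default_factory=list)
    compounds: list[TermRef] = dfield(default_factory=list)
    functions: list[TermRef] = dfield(default_factory=list)


@dataclass
class MethodFacet:
    approach: TermRef | None = None
    context: TermRef | None = None
    variables: list[TermRef] = dfield(default_factory=list)


@dataclass
class AnnotationRecord:
    record_id: str
    general: GeneralInfo
    time: TimeFacet | None = None
    space: SpaceFacet | None = None
    sphere: SphereFacet | None = None
    biome: BiomeFacet | None = None
    organism: OrganismFacet | None = None
    process: ProcessFacet | None = None
    chemical: ChemicalFacet | None = None
    method: MethodFacet | None = None


@dataclass(frozen=True)
class ValidationIssue:
    severity: str     # error | warning
    field: str
    message: str
    value: object = None
    line: int | None = None


# ----------------------------------------------------------- timestamps
_ISO_RE = re.compile(
    r"^(?P<y>\d{4})(?:-(?P<m>\d{2})(?:-(?P<d>\d{2})"
    r"(?:[T ](?P<H>\d{2}):(?P<M>\d{2})(?::(?P<S>\d{2}))?"
    r"(?P<tz>Z|[+-]\d{2}:\d{2})?)?)?)?$")

_DAYS = (31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31)


def iso_interval(value: str) -> tuple[tuple, tuple]:
    """Interval semantics for a reduced-precision ISO 8601 timestamp: a
    year/month/date denotes its full span.  Returns comparable
    (earliest, latest) tuples; raises ``ValueError`` on malformed input."""
    m = _ISO_RE.match(value.strip())
    if not m:
        raise ValueError(f"not a reduced-precision ISO 8601 timestamp: {value!r}")
    y = int(m["y"])
    if m["m"] is None:
        return (y, 1, 1, 0, 0, 0), (y, 12, 31, 23, 59, 59)
    mo = int(m["m"])
    if not 1 <= mo <= 12:
        raise ValueError(f"month out of range in {value!r}")
    leap = y % 4 == 0 and (y % 100 != 0 or y % 400 == 0)
    last = 29 if (mo == 2 and leap) else _DAYS[mo - 1]
    if m["d"] is None:
        return (y, mo, 1, 0, 0, 0), (y, mo, last, 23, 59, 59)
    d = int(m["d"])
    if not 1 <= d <= last:
        raise ValueError(f"day out of range in {value!r}")
    if m["H"] is None:
        return (y, mo, d, 0, 0, 0), (y, mo, d, 23, 59, 59)
    h, mi = int(m["H"]), int(m["M"])
    if h > 23 or mi > 59:
        raise ValueError(f"time out of range in {value!r}")
    if m["S"] is None:
        return (y, mo, d, h, mi, 0), (y, mo, d, h, mi, 59)
    s = int(m["S"])
    if s > 60:
        raise ValueError(f"seconds out of range in {value!r}")
    return (y, mo, d, h, mi, s), (y, mo, d, h, mi, s)


# ----------------------------------------------------------- resolution
class _Unresolved(EcofacetError):
    pass


def _resolve_ref(r: TermRef, fld: FacetField, vocab: Vocabulary) -> TermRef | None:
    """Canonical TermRef for ``r`` within the field's vocabulary subtree(s);
    None when no concept matches (acceptable for open fields)."""
    term: Term | None = None
    if r.id is not None and r.id in vocab:
        t = vocab.resolve(r.id)
        if t.facet_path in fld.closed_list_ref:
            term = t
    if term is None:
        for path in fld.closed_list_ref:
            if path not in vocab.paths:
                continue
            term = vocab.find_label(path, r.label)
            if term is not None:
                break
    if term is None:
        return None
    return TermRef(label=term.label, id=term.id, uri=term.uri, status=term.status)


def _walk_refs(record: AnnotationRecord):
    """Yield (registry path, holder object, attribute/index, TermRef) for
    every term reference in the record."""
    def one(path, holder, attr):
        r = getattr(holder, attr)
        if r is not None:
            yield path, holder, attr, r

    def many(path, holder, attr):
        for i, r in enumerate(getattr(holder, attr)):
            yield path, getattr(holder, attr), i, r

    t = record.time
    if t is not None:
        yield from one("time/timezone", t, "timezone")
        if t.geological is not None:
            for rank, r in t.geological.items():
                if r is not None:
                    yield f"time/geological/{rank}", t.geological, rank, r
        yield from one("time/resolution", t, "resolution")
        yield from one("time/extent", t, "extent")
    s = record.space
    if s is not None:
        for loc in s.locations:
            yield from one("space/location/type", loc, "location_type")
            yield from one("space/location/country", loc, "country")
            yield from one("space/location/continent", loc, "continent")
        yield from one("space/resolution", s, "resolution")
        yield from one("space/extent", s, "extent")
    sp = record.sphere
    if sp is not None:
        yield from many("sphere/layer", sp, "spheres")
        yield from one("sphere/organization", sp, "organization")
    b = record.biome
    if b is not None:
        for attr in ("latitudinal", "altitudinal", "moisture", "continentality",
                     "physiognomy", "special", "condition"):
            yield from one(f"biome/{attr}", b, attr)
        yield from many("biome/usage", b, "usage")
    o = record.organism
    if o is not None:
        for name in o.names:
            yield from one("organism/code", name, "code")
    p = record.process
    if p is not None:
        for proc in p.processes:
            yield "process/name", proc, "name", proc.name
            yield from many("process/involved", proc, "involved")
            yield from one("process/characterization", proc, "characterization")
        for ia in p.interactions:
            yield from one("process/interaction/name", ia, "name")
            yield "process/interaction/partner_a", ia, "partner_a", ia.partner_a
            yield "process/interaction/partner_b", ia, "partner_b", ia.partner_b
            yield "process/interaction/direction", ia, "direction", ia.direction
            yield from one("process/interaction/quality", ia, "quality")
    c = record.chemical
    if c is not None:
        yield from many("chemical/element", c, "elements")
        yield from many("chemical/compound", c, "compounds")
        yield from many("chemical/function", c, "functions")
    m = record.method
    if m is not None:
        yield from one("method/approach", m, "approach")
        yield from one("method/context", m, "context")
        yield from many("method/variable", m, "variables")


def _set_ref(holder, key, value):
    if isinstance(key, int):
        holder[key] = value
    else:
        setattr(holder, key, value)


# ----------------------------------------------------------- validation
def validate_record(record: AnnotationRecord,
                    vocab: Vocabulary) -> list[ValidationIssue]:
    """Check every model invariant; an empty result means the record is
    valid.  Unknown terms in closed fields are errors, in open fields
    warnings (open fields grow through the curation workflow)."""
    issues: list[ValidationIssue] = []
    err = lambda f, msg, v=None: issues.append(ValidationIssue("error", f, msg, v))
    warn = lambda f, msg, v=None: issues.append(ValidationIssue("warning", f, msg, v))

    g = record.general
    if not record.record_id:
        err("record_id", "record id must be non-empty")
    if not g.title or not g.title.strip():
        err("general/title", "title must be non-empty")
    if not g.parties:
        err("general/parties", "at least one responsible party is required")
    for p in g.parties:
        if not p.name:
            err("general/parties", "party name must be non-empty")
    if g.access is not None and g.access.kind not in ACCESS_KINDS:
        err("general/access",
            f"access kind must be one of {ACCESS_KINDS}", g.access.kind)

    # term references
    for path, _holder, _key, r in _walk_refs(record):
        fld = registry_field(path)
        resolved = _resolve_ref(r, fld, vocab)
        if resolved is None:
            if fld.kind == "closed_term":
                err(path, f"unknown term for closed field", r.label)
            else:
                warn(path, "term not in vocabulary; candidate for proposal",
                     r.label)

    t = record.time
    if t is not None:
        spans = {}
        for attr in ("start", "end"):
            v = getattr(t, attr)
            if v is not None:
                try:
                    spans[attr] = iso_interval(v)
                except ValueError as e:
                    err(f"time/{attr}", str(e), v)
        if "start" in spans and "end" in spans:
            if spans["start"][0] > spans["end"][1]:
                err("time/start", "start is after end", (t.start, t.end))
        if t.geological is not None:
            given = [(rank, _resolve_ref(r, registry_field(f"time/geological/{rank}"), vocab))
                     for rank, r in t.geological.items() if r is not None]
            given = [(rank, res) for rank, res in given if res is not None]
            for (_, coarse), (_, fine) in zip(given, given[1:]):
                anc_ids = {a.id for a in vocab.ancestors(fine.id)}
                if coarse.id not in anc_ids:
                    err("time/geological",
                        f"{fine.label!r} is not nested within {coarse.label!r}",
                        (coarse.label, fine.label))

    s = record.space
    if s is not None:
        bb = s.bounding_box
        if bb is not None:
            if not (-90.0 <= bb.south <= bb.north <= 90.0):
                err("space/bounding_box",
                    "latitudes must satisfy -90 <= south <= north <= 90",
                    (bb.south, bb.north))
            if not (-180.0 <= bb.west <= 180.0 and -180.0 <= bb.east <= 180.0):
                err("space/bounding_box", "longitudes must be within [-180, 180]",
                    (bb.west, bb.east))
        for pt in s.points:
            if isinstance(pt, GeoPoint):
                if not (-90.0 <= pt.latitude <= 90.0):
                    err("space/point", "latitude out of range", pt.latitude)
                if not (-180.0 <= pt.longitude <= 180.0):
                    err("space/point", "longitude out of range", pt.longitude)
            elif isinstance(pt, UtmPoint):
                if pt.datum != "WGS84":
                    err("space/point", "UTM points must use the WGS84 datum",
                        pt.datum)
            else:
                err("space/point", "point must be GeoPoint or UtmPoint", pt)
        res = _resolve_ref(s.resolution, registry_field("space/resolution"),
                           vocab) if s.resolution else None
        ext = _resolve_ref(s.extent, registry_field("space/extent"),
                           vocab) if s.extent else None
        if res is not None and ext is not None:
            order = [t_.label for t_ in vocab.terms_at("space/resolution")]
            if order.index(res.label) > order.index(ext.label):
                warn("space/resolution",
                     "resolution class exceeds extent class",
                     (res.label, ext.label))

    o = record.organism
    if o is not None:
        for rank in o.taxonomy:
            if rank not in TAXONOMIC_RANKS:
                err("organism/taxonomy",
                    f"rank must be one of {TAXONOMIC_RANKS}", rank)
        for n in o.names:
            if not n.scientific_name:
                err("organism/name", "scientific name must be non-empty")
    return issues


def resolve_terms(record: AnnotationRecord,
                  vocab: Vocabulary) -> AnnotationRecord:
    """Deep-copied record with every term reference normalized to canonical
    id + label + URI (merge redirects followed).  Requires the record to
    validate without errors; idempotent."""
    errors = [i for i in validate_record(record, vocab) if i.severity == "error"]
    if errors:
        raise _Unresolved(
            "record has validation errors; resolve refused: "
            + "; ".join(f"{i.field}: {i.message}" for i in errors))
    out = copy.deepcopy(record)
    for path, holder, key, r in list(_walk_refs(out)):
        fld = registry_field(path)
        resolved = _resolve_ref(r, fld, vocab)
        if resolved is not None:
            _set_ref(holder, key, resolved)
        # open-field refs without a vocabulary concept stay label-only
    return out
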