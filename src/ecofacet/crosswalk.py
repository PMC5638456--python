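"""Importers building partial annotation records from the three major
ecological metadata standards (EML 2.x, ABCD 2.06, Darwin Core).

Concept mappings are shipped as data (``data/crosswalk/*.json``), one
entry per annotation field covered by the topic tables; a field whose
``source_concept`` is ``"absent"`` is never populated.  Every import
returns the partial record together with a :class:`MappingReport` whose
entries account for each covered field: ``mapped`` (value transferred),
``missing_in_source`` (concept or value not present in the document) or
``present_unparsed`` (source value present but not transferable, e.g. a
free-text method description or a country label not found in the closed
vocabulary).

Source documents are matched by local element name, so EML 2.0-2.2 and
ABCD 2.06 namespace variants are all accepted.
"""

from __future__ import annotations

import csv
import io
import json
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field as dfield
from importlib import resources
from pathlib import Path

from . import model as M
from .errors import DocumentError
from .vocabulary import Vocabulary

__all__ = ["MappingEntry", "MappingReport", "import_eml", "import_abcd",
           "import_dwc", "concept_map"]

_DWC_RANKS = {"kingdom": "kingdom", "phylum": "division_or_phylum",
              "class": "class", "order": "order", "family": "family",
              "genus": "genus"}


@dataclass(frozen=True)
class MappingEntry:
    target_field: str
    source_concept: str     # concept path in the source standard, or "absent"
    status: str             # mapped | missing_in_source | present_unparsed


@dataclass
class MappingReport:
    source_standard: str    # EML | ABCD | DwC
    entries: list[MappingEntry] = dfield(default_factory=list)

    def status_of(self, target_field: str) -> str:
        for e in self.entries:
            if e.target_field == target_field:
                return e.status
        raise KeyError(target_field)


def concept_map(standard: str) -> dict:
    name = standard.lower()
    text = resources.files("ecofacet").joinpath(
        f"data/crosswalk/{name}.json").read_text(encoding="utf-8")
    return json.loads(text)


def _build_report(standard_label: str, cmap: dict,
                  statuses: dict[str, str]) -> MappingReport:
    entries = []
    for e in cmap["entries"]:
        fld, concept = e["target_field"], e["source_concept"]
        if concept == "absent":
            status = "missing_in_source"
        else:
            status = statuses.get(fld, "missing_in_source")
        entries.append(MappingEntry(fld, concept, status))
    return MappingReport(standard_label, entries)


# ------------------------------------------------------------- XML utils
def _parse_xml(document) -> ET.Element:
    if hasattr(document, "read"):
        document = document.read()
    if isinstance(document, (str,)) and "<" not in document:
        document = Path(document).read_text(encoding="utf-8")
    try:
        return ET.fromstring(document)
    except ET.ParseError as e:
        raise DocumentError(f"malformed source document: {e}") from None


def _local(tag) -> str:
    return tag.rsplit("}", 1)[-1] if isinstance(tag, str) else ""


def _iter_local(root: ET.Element, name: str):
    for e in root.iter():
        if _local(e.tag) == name:
            yield e


def _first_text(root: ET.Element, name: str) -> str | None:
    for e in _iter_local(root, name):
        text = "".join(e.itertext()).strip()
        if text:
            return text
    return None


def _fallback_general(title: str | None, parties: list[M.Party],
                      standard: str) -> M.GeneralInfo:
    # title and one party are mandatory for a valid record; fall back to
    # neutral placeholders (not claimed as mapped in the report)
    return M.GeneralInfo(
        title=title or f"Imported {standard} resource",
        parties=parties or [M.Party("Unknown", role="contact")])


def _match_closed(vocab: Vocabulary, path: str, label: str):
    return vocab.find_label(path, label)


# -------------------------------------------------------------------- EML
def import_eml(document, vocab: Vocabulary) -> tuple[M.AnnotationRecord,
                                                     MappingReport]:
    """Import an EML 2.x document (temporal / geographic / taxonomic
    coverage plus title, abstract, parties and distribution URL)."""
    root = _parse_xml(document)
    cmap = concept_map("eml")
    statuses: dict[str, str] = {}

    title = _first_text(root, "title")
    if title:
        statuses["general/title"] = "mapped"
    abstract = _first_text(root, "abstract")
    if abstract:
        statuses["general/abstract"] = "mapped"
    parties = []
    for tag, role in (("creator", "creator"), ("contact", "contact")):
        for pe in _iter_local(root, tag):
            name = (_first_text(pe, "surName") or _first_text(pe, "organizationName")
                    or _first_text(pe, "positionName"))
            given = _first_text(pe, "givenName")
            if name:
                full = f"{given} {name}" if given else name
                parties.append(M.Party(full, role=role,
                                       email=_first_text(pe, "electronicMailAddress")))
    if parties:
        statuses["general/parties"] = "mapped"
    access = None
    url = _first_text(root, "url")
    if url:
        access = M.Access("url", url)
        statuses["general/access"] = "mapped"

    record = M.AnnotationRecord(
        record_id=root.get("packageId") or "imported-eml",
        general=_fallback_general(title, parties, "EML"))
    record.general.abstract = abstract or ""
    record.general.access = access

    # temporal coverage
    start = end = None
    for tc in _iter_local(root, "temporalCoverage"):
        for rd in _iter_local(tc, "rangeOfDates"):
            for be in _iter_local(rd, "beginDate"):
                start = _first_text(be, "calendarDate") or start
            for ee in _iter_local(rd, "endDate"):
                end = _first_text(ee, "calendarDate") or end
        for sd in _iter_local(tc, "singleDateTime"):
            start = _first_text(sd, "calendarDate") or start
    if start or end:
        record.time = M.TimeFacet(start=start, end=end)
        if start:
            statuses["time/start"] = "mapped"
        if end:
            statuses["time/end"] = "mapped"

    # geographic coverage
    space = M.SpaceFacet()
    for gc in _iter_local(root, "geographicCoverage"):
        desc = _first_text(gc, "geographicDescription")
        if desc:
            space.locations.append(M.Location(name=desc))
            statuses["space/location/name"] = "mapped"
        for bc in _iter_local(gc, "boundingCoordinates"):
            try:
                west = float(_first_text(bc, "westBoundingCoordinate"))
                east = float(_first_text(bc, "eastBoundingCoordinate"))
                north = float(_first_text(bc, "northBoundingCoordinate"))
                south = float(_first_text(bc, "southBoundingCoordinate"))
            except (TypeError, ValueError):
                statuses["space/bounding_box"] = "present_unparsed"
                continue
            space.bounding_box = M.BoundingBox(west=west, south=south,
                                               east=east, north=north)
            statuses["space/bounding_box"] = "mapped"
    if space.locations or space.bounding_box is not None:
        record.space = space

    # taxonomic coverage
    taxonomy: dict[str, str] = {}
    names: list[M.OrganismName] = []
    for tcl in _iter_local(root, "taxonomicClassification"):
        rank = (_first_text(tcl, "taxonRankName") or "").strip().lower()
        value = _first_text(tcl, "taxonRankValue")
        if not value:
            continue
        slot = _DWC_RANKS.get(rank) or ("domain" if rank == "domain" else None)
        if rank in ("division", "phylum"):
            slot = "division_or_phylum"
        if slot and slot not in taxonomy:
            taxonomy[slot] = value
        elif rank in ("species", "subspecies", ""):
            names.append(M.OrganismName(scientific_name=value))
    if taxonomy or names:
        record.organism = M.OrganismFacet(names=names, taxonomy=taxonomy)
        if taxonomy:
            statuses["organism/taxonomy"] = "mapped"
        if names:
            statuses["organism/name"] = "mapped"

    if any(True for _ in _iter_local(root, "methodStep")):
        statuses["method/variable"] = "present_unparsed"

    return record, _build_report(cmap["standard"], cmap, statuses)


# -------------------------------------------------------------------- DwC
def import_dwc(records, vocab: Vocabulary) -> tuple[M.AnnotationRecord,
                                                    MappingReport]:
    """Import Darwin Core term->value records: a flat mapping, a list of
    row mappings, or a path / file-like of a delimited archive core file."""
    rows = _dwc_rows(records)
    if not rows:
        raise DocumentError("no Darwin Core records supplied")
    cmap = concept_map("dwc")
    statuses: dict[str, str] = {}
    first = rows[0]

    def get(row, key):
        v = row.get(key)
        return v.strip() if isinstance(v, str) and v.strip() else None

    title = get(first, "datasetName")
    if title:
        statuses["general/title"] = "mapped"
    parties = []
    for row in rows:
        by = get(row, "recordedBy")
        if by:
            for name in by.split("|"):
                if name.strip() and all(p.name != name.strip() for p in parties):
                    parties.append(M.Party(name.strip(), role="collector"))
    if parties:
        statuses["general/parties"] = "mapped"
    record = M.AnnotationRecord(
        record_id=get(first, "occurrenceID") or get(first, "datasetID")
        or "imported-dwc",
        general=_fallback_general(title, parties, "Darwin Core"))

    # event dates: eventDate may be a single value or an ISO range a/b
    starts, ends = [], []
    for row in rows:
        ev = get(row, "eventDate")
        if not ev:
            continue
        if "/" in ev:
            a, b = ev.split("/", 1)
            starts.append(a)
            ends.append(b)
        else:
            starts.append(ev)
            ends.append(ev)
    if starts:
        record.time = M.TimeFacet(start=min(starts), end=max(ends))
        statuses["time/start"] = "mapped"
        statuses["time/end"] = "mapped"

    space = M.SpaceFacet()
    for row in rows:
        lat, lon = get(row, "decimalLatitude"), get(row, "decimalLongitude")
        if lat is not None and lon is not None:
            try:
                space.points.append(M.GeoPoint(float(lat), float(lon)))
                statuses["space/point"] = "mapped"
            except ValueError:
                statuses["space/point"] = "present_unparsed"
        loc = get(row, "locality")
        country = get(row, "country")
        continent = get(row, "continent")
        if loc or country or continent:
            location = M.Location(name=loc or country or continent)
            if loc:
                statuses["space/location/name"] = "mapped"
            if country:
                t = _match_closed(vocab, "space/country", country)
                if t is not None:
                    location.country = M.TermRef(t.label, t.id, t.uri, t.status)
                    statuses["space/location/country"] = "mapped"
                else:
                    statuses.setdefault("space/location/country",
                                        "present_unparsed")
            if continent:
                t = _match_closed(vocab, "space/continent", continent)
                if t is not None:
                    location.continent = M.TermRef(t.label, t.id, t.uri, t.status)
                    statuses["space/location/continent"] = "mapped"
                else:
                    statuses.setdefault("space/location/continent",
                                        "present_unparsed")
            space.locations.append(location)
        if get(row, "footprintWKT"):
            statuses["space/bounding_box"] = "present_unparsed"
    if space.locations or space.points:
        record.space = space

    taxonomy: dict[str, str] = {}
    names: list[M.OrganismName] = []
    for row in rows:
        for key, slot in _DWC_RANKS.items():
            v = get(row, key)
            if v and slot not in taxonomy:
                taxonomy[slot] = v
        sci = get(row, "scientificName")
        if sci and all(n.scientific_name != sci for n in names):
            names.append(M.OrganismName(scientific_name=sci))
    if taxonomy or names:
        record.organism = M.OrganismFacet(names=names, taxonomy=taxonomy)
        if taxonomy:
            statuses["organism/taxonomy"] = "mapped"
        if names:
            statuses["organism/name"] = "mapped"

    for row in rows:
        if get(row, "habitat"):
            statuses.setdefault("biome/physiognomy", "present_unparsed")
        if get(row, "samplingProtocol"):
            statuses.setdefault("method/variable", "present_unparsed")
        if get(row, "earliestEpochOrLowestSeries"):
            statuses.setdefault("time/geological", "present_unparsed")

    return record, _build_report(cmap["standard"], cmap, statuses)


def _dwc_rows(records) -> list[dict]:
    if isinstance(records, dict):
        return [records]
    if isinstance(records, (list, tuple)):
        return [dict(r) for r in records]
    if hasattr(records, "read"):
        text = records.read()
    else:
        text = Path(records).read_text(encoding="utf-8")
    delimiter = "\t" if "\t" in text.splitlines()[0] else ","
    return list(csv.DictReader(io.StringIO(text), delimiter=delimiter))


# ------------------------------------------------------------------- ABCD
def import_abcd(document, vocab: Vocabulary) -> tuple[M.AnnotationRecord,
                                                      MappingReport]:
    """Import an ABCD 2.06 dataset: metadata block plus per-unit gathering
    sites, dates and taxonomic identifications (one organism name entry
    per unit)."""
    root = _parse_xml(document)
    cmap = concept_map("abcd")
    statuses: dict[str, str] = {}

    title = _first_text(root, "Title")
    if title:
        statuses["general/title"] = "mapped"
    abstract = _first_text(root, "Details")
    if abstract:
        statuses["general/abstract"] = "mapped"
    parties = []
    for tag, role in (("Owner", "owner"), ("ContentContact", "contact")):
        for pe in _iter_local(root, tag):
            name = _first_text(pe, "FullName") or _first_text(pe, "Name")
            if name and all(p.name != name for p in parties):
                parties.append(M.Party(name, role=role,
                                       email=_first_text(pe, "EmailAddress")))
    if parties:
        statuses["general/parties"] = "mapped"
    access = None
    uri = _first_text(root, "URI")
    if uri:
        access = M.Access("url", uri)
        statuses["general/access"] = "mapped"
    record = M.AnnotationRecord(
        record_id=_first_text(root, "DatasetGUID") or "imported-abcd",
        general=_fallback_general(title, parties, "ABCD"))
    record.general.abstract = abstract or ""
    record.general.access = access

    units = list(_iter_local(root, "Unit"))
    starts, ends = [], []
    space = M.SpaceFacet()
    names: list[M.OrganismName] = []
    taxonomy: dict[str, str] = {}
    for unit in units:
        for g in _iter_local(unit, "Gathering"):
            begin = _first_text(g, "ISODateTimeBegin")
            if begin:
                starts.append(begin)
                statuses["time/start"] = "mapped"
            endv = _first_text(g, "ISODateTimeEnd")
            if endv:
                ends.append(endv)
                statuses["time/end"] = "mapped"
            loc = _first_text(g, "LocalityText")
            country = None
            for ce in _iter_local(g, "Country"):
                country = _first_text(ce, "Name")
            if loc or country:
                location = M.Location(name=loc or country)
                if loc:
                    statuses["space/location/name"] = "mapped"
                if country:
                    t = _match_closed(vocab, "space/country", country)
                    if t is not None:
                        location.country = M.TermRef(t.label, t.id, t.uri,
                                                     t.status)
                        statuses["space/location/country"] = "mapped"
                    else:
                        statuses.setdefault("space/location/country",
                                            "present_unparsed")
                space.locations.append(location)
            lat = _first_text(g, "LatitudeDecimal")
            lon = _first_text(g, "LongitudeDecimal")
            if lat is not None and lon is not None:
                try:
                    space.points.append(M.GeoPoint(float(lat), float(lon)))
                    statuses["space/point"] = "mapped"
                except ValueError:
                    statuses["space/point"] = "present_unparsed"
            if any(True for _ in _iter_local(g, "Stratigraphy")):
                statuses.setdefault("time/geological", "present_unparsed")
            if any(True for _ in _iter_local(g, "Biotope")):
                statuses.setdefault("biome/physiognomy", "present_unparsed")
            if any(True for _ in _iter_local(g, "Method")):
                statuses.setdefault("method/variable", "present_unparsed")
        sci = _first_text(unit, "FullScientificNameString")
        if sci:
            names.append(M.OrganismName(scientific_name=sci))
            statuses["organism/name"] = "mapped"
        for ht in _iter_local(unit, "HigherTaxon"):
            rank = (_first_text(ht, "HigherTaxonRank") or "").lower()
            value = _first_text(ht, "HigherTaxonName")
            slot = _DWC_RANKS.get(rank)
            if rank in ("divisio", "division", "phylum"):
                slot = "division_or_phylum"
            if slot and value and slot not in taxonomy:
                taxonomy[slot] = value
                statuses["organism/taxonomy"] = "mapped"
    if starts or ends:
        record.time = M.TimeFacet(start=min(starts) if starts else None,
                                  end=max(ends) if ends else None)
    if space.locations or space.points:
        record.space = space
    if names or taxonomy:
        record.organism = M.OrganismFacet(names=names, taxonomy=taxonomy)

    return record, _build_report(cmap["standard"], cmap, statuses)
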