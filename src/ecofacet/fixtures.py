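"""Deterministic synthetic corpora and source-standard documents.

All sampling is integer-based on :class:`random.Random`, so a seed fixes
the generated corpus byte-for-byte across platforms.  Generated records
always validate without errors; open fields draw from small packaged word
lists (no statistical realism is claimed).

Scenario presets:

* ``carbon-intro`` — four records that all mention "carbon" in their text
  (a CO2-enrichment treatment experiment, a subsoil carbon survey, a
  tree-ring isotope study and field observations near Carbon Village),
  of which only the treatment experiment carries the manipulated variable
  "Elevated carbon dioxide concentration";
* ``fungi-interaction`` — a parasitism record (Fungi Affects Plantae,
  quality Antagonism) and a symbiosis record (Fungi Mutual Plantae,
  quality Mutualism).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field as dfield

from . import model as M
from .errors import EcofacetError
from .vocabulary import Vocabulary, load_vocabulary

__all__ = ["CorpusConfig", "generate_corpus", "generate_source_docs",
           "PRESETS", "MIN_FULL_COVERAGE_N"]

#: with default fill probabilities, corpora of at least this size exercise
#: every registered field (checked by a seed-pinned test)
MIN_FULL_COVERAGE_N = 40

_WORDS = ("soil", "forest", "grassland", "nutrient", "diversity", "litter",
          "canopy", "drought", "warming", "microbial", "root", "carbon",
          "nitrogen", "phosphorus", "beetle", "fungal", "seedling", "biomass")
_NAMES = ("Alex Richter", "Sam Keller", "Kim Bauer", "Noa Fischer",
          "Robin Weber", "Jona Schmid")
_SPECIES = ("Fagus sylvatica", "Quercus robur", "Picea abies",
            "Lumbricus terrestris", "Apis mellifera", "Amanita muscaria")
_ODD_COMPOUNDS = ("Tannins", "Flavonoids", "Terpenes")


@dataclass
class CorpusConfig:
    n_records: int = 10
    seed: int = 0
    #: facet name -> probability that a record carries that facet block
    fill_probabilities: dict = dfield(default_factory=dict)
    preset: str | None = None

    def fill(self, facet: str) -> float:
        p = self.fill_probabilities.get(facet, 0.6)
        if not 0.0 <= p <= 1.0:
            raise EcofacetError(f"fill probability for {facet!r} out of [0,1]")
        return p


def _tref(vocab: Vocabulary, path: str, label: str) -> M.TermRef:
    t = vocab.find_label(path, label)
    if t is None:
        raise EcofacetError(f"fixture label {label!r} not found at {path!r}")
    return M.TermRef(t.label, t.id, t.uri, t.status)


def _pick(rng: random.Random, vocab: Vocabulary, path: str) -> M.TermRef:
    terms = vocab.terms_at(path)
    if not terms:
        raise EcofacetError(f"vocabulary subtree {path!r} is empty")
    t = terms[rng.randrange(len(terms))]
    return M.TermRef(t.label, t.id, t.uri, t.status)


def _chance(rng: random.Random, p: float) -> bool:
    return rng.randrange(10**6) < int(p * 10**6)


def _coord(rng: random.Random, scale: int) -> float:
    return rng.randint(-scale * 10000, scale * 10000) / 10000.0


def _iso(rng: random.Random, y, mo, d, precision: int) -> str:
    if precision == 0:
        return f"{y:04d}"
    if precision == 1:
        return f"{y:04d}-{mo:02d}"
    return f"{y:04d}-{mo:02d}-{d:02d}"


def _random_record(rng: random.Random, vocab: Vocabulary, rid: str,
                   config: CorpusConfig) -> M.AnnotationRecord:
    words = [_WORDS[rng.randrange(len(_WORDS))] for _ in range(4)]
    title = " ".join(words).capitalize()
    abstract = "Study of " + " and ".join(words[:2]) + " dynamics."
    general = M.GeneralInfo(
        title=title, abstract=abstract,
        parties=[M.Party(_NAMES[rng.randrange(len(_NAMES))], role="author")],
        access=M.Access("database_id", rid))
    rec = M.AnnotationRecord(record_id=rid, general=general)

    if _chance(rng, config.fill("time")):
        d1 = (rng.randint(1980, 2015), rng.randint(1, 12), rng.randint(1, 28))
        d2 = (rng.randint(1980, 2015), rng.randint(1, 12), rng.randint(1, 28))
        start, end = sorted((d1, d2))
        geological = None
        if _chance(rng, 0.5):
            age = _pick(rng, vocab, "time/geological/age")
            chain = {t.facet_path.rsplit("/", 1)[-1]:
                     M.TermRef(t.label, t.id, t.uri, t.status)
                     for t in vocab.ancestors(age.id)}
            geological = M.GeologicalContext(
                eon=chain.get("eon"), era=chain.get("era"),
                period=chain.get("period"), epoch=chain.get("epoch"),
                age=None if _chance(rng, 0.5) else age)
        units = vocab.terms_at("time/unit")
        i = rng.randrange(len(units))
        j = rng.randrange(i, len(units))
        rec.time = M.TimeFacet(
            start=_iso(rng, *start, precision=rng.randrange(3)),
            end=_iso(rng, *end, precision=rng.randrange(3)),
            timezone=_pick(rng, vocab, "time/zone"),
            geological=geological,
            resolution=M.TermRef(units[i].label, units[i].id, None, "core"),
            extent=M.TermRef(units[j].label, units[j].id, None, "core"))

    if _chance(rng, config.fill("space")):
        lat, lon = _coord(rng, 80), _coord(rng, 170)
        scales = vocab.terms_at("space/resolution")
        i = rng.randrange(len(scales))
        j = rng.randrange(i, len(scales))
        loc = M.Location(
            name=f"Site {rng.randint(1, 99)}",
            location_type=_pick(rng, vocab, "space/location_type"),
            country=_pick(rng, vocab, "space/country"),
            continent=_pick(rng, vocab, "space/continent"))
        points: list = [M.GeoPoint(lat, lon)]
        if _chance(rng, 0.3):
            points.append(M.UtmPoint(f"{rng.randint(1, 60)}U",
                                     float(rng.randint(100000, 900000)),
                                     float(rng.randint(0, 9999999))))
        rec.space = M.SpaceFacet(
            locations=[loc],
            bounding_box=M.BoundingBox(
                west=max(-180.0, lon - 1), south=max(-90.0, lat - 1),
                east=min(180.0, lon + 1), north=min(90.0, lat + 1)),
            points=points,
            resolution=M.TermRef(scales[i].label, scales[i].id, None, "core"),
            extent=M.TermRef(scales[j].label, scales[j].id, None, "core"))

    if _chance(rng, config.fill("sphere")):
        layer_path = ("sphere/atmosphere", "sphere/hydrosphere",
                      "sphere/pedosphere", "sphere/lithosphere")[rng.randrange(4)]
        rec.sphere = M.SphereFacet(
            spheres=[_pick(rng, vocab, layer_path)],
            organization=_pick(rng, vocab, "sphere/organization"))

    if _chance(rng, config.fill("biome")):
        rec.biome = M.BiomeFacet(
            latitudinal=_pick(rng, vocab, "biome/latitudinal"),
            altitudinal=_pick(rng, vocab, "biome/altitudinal"),
            moisture=_pick(rng, vocab, "biome/moisture"),
            continentality=_pick(rng, vocab, "biome/continentality"),
            physiognomy=_pick(rng, vocab, "biome/physiognomy"),
            special=_pick(rng, vocab, "biome/special"),
            condition=_pick(rng, vocab, "biome/condition"),
            usage=[_pick(rng, vocab, "biome/usage")])

    if _chance(rng, config.fill("organism")):
        rec.organism = M.OrganismFacet(
            names=[M.OrganismName(
                scientific_name=_SPECIES[rng.randrange(len(_SPECIES))],
                code=_pick(rng, vocab, "organism/code"))],
            taxonomy={"kingdom": _pick(rng, vocab, "organism/kingdom").label})

    if _chance(rng, config.fill("process")):
        proc = M.Process(
            name=_pick(rng, vocab, "process/name"),
            involved=[_pick(rng, vocab, "process/involved")],
            characterization=_pick(rng, vocab, "process/characterization"))
        interactions = []
        if _chance(rng, 0.5):
            interactions.append(M.Interaction(
                partner_a=_pick(rng, vocab, "organism/kingdom"),
                partner_b=_pick(rng, vocab, "organism/kingdom"),
                direction=_pick(rng, vocab, "process/interaction/direction"),
                quality=_pick(rng, vocab, "process/interaction/quality"),
                name=_pick(rng, vocab, "process/interaction/name")))
        rec.process = M.ProcessFacet(processes=[proc],
                                     interactions=interactions)

    if _chance(rng, config.fill("chemical")):
        compounds = [_pick(rng, vocab, "chemical/compound")]
        if _chance(rng, 0.25):  # out-of-vocabulary open value (warning only)
            compounds.append(M.TermRef(
                _ODD_COMPOUNDS[rng.randrange(len(_ODD_COMPOUNDS))]))
        rec.chemical = M.ChemicalFacet(
            elements=[_pick(rng, vocab, "chemical/element")],
            compounds=compounds,
            functions=[_pick(rng, vocab, "chemical/function")])

    if _chance(rng, config.fill("method")):
        rec.method = M.MethodFacet(
            approach=_pick(rng, vocab, "method/approach"),
            context=_pick(rng, vocab, "method/context"),
            variables=[_pick(rng, vocab, "method/variable")])
    return rec


# ------------------------------------------------------------------ presets
def _carbon_intro(vocab: Vocabulary) -> list[M.AnnotationRecord]:
    def g(title, abstract, name):
        return M.GeneralInfo(title=title, abstract=abstract,
                             parties=[M.Party(name, role="author")])

    treatment = M.AnnotationRecord(
        record_id="carbon-co2-treatment",
        general=g("Global change experiment with elevated carbon dioxide",
                  "Grassland plots exposed to elevated carbon dioxide "
                  "concentrations as experimental treatment.",
                  "Alex Richter"),
        method=M.MethodFacet(
            approach=_tref(vocab, "method/approach", "Manipulative"),
            context=_tref(vocab, "method/context", "Macrocosm"),
            variables=[_tref(vocab, "method/variable",
                             "Elevated carbon dioxide concentration")]))
    survey = M.AnnotationRecord(
        record_id="carbon-subsoil-survey",
        general=g("Soil survey of carbon concentrations",
                  "Survey reporting carbon concentrations in the subsoil.",
                  "Sam Keller"),
        sphere=M.SphereFacet(spheres=[_tref(vocab, "sphere/pedosphere",
                                            "B Horizon")]),
        chemical=M.ChemicalFacet(elements=[_tref(vocab, "chemical/element",
                                                 "C")]),
        method=M.MethodFacet(
            approach=_tref(vocab, "method/approach", "Observational")))
    treerings = M.AnnotationRecord(
        record_id="carbon-tree-rings",
        general=g("Paleoclimate study of carbon isotopes in tree rings",
                  "Carbon isotope discrimination measured in tree rings.",
                  "Kim Bauer"),
        time=M.TimeFacet(geological=M.GeologicalContext(
            epoch=_tref(vocab, "time/geological/epoch", "Holocene"))),
        method=M.MethodFacet(
            approach=_tref(vocab, "method/approach", "Observational")))
    village = M.AnnotationRecord(
        record_id="carbon-village",
        general=g("Field observations near Carbon Village",
                  "Field observations near Carbon Village in Alberta, Canada.",
                  "Noa Fischer"),
        space=M.SpaceFacet(locations=[M.Location(
            name="Carbon Village",
            location_type=_tref(vocab, "space/location_type", "Village"),
            country=_tref(vocab, "space/country", "Canada"),
            continent=_tref(vocab, "space/continent", "North America"))]),
        method=M.MethodFacet(
            approach=_tref(vocab, "method/approach", "Observational")))
    return [treatment, survey, treerings, village]


def _fungi_interaction(vocab: Vocabulary) -> list[M.AnnotationRecord]:
    def g(title, abstract):
        return M.GeneralInfo(title=title, abstract=abstract,
                             parties=[M.Party("Robin Weber", role="author")])

    parasitism = M.AnnotationRecord(
        record_id="fungi-parasitism",
        general=g("Fungal parasites of plants",
                  "Data on fungi acting as plant parasites."),
        process=M.ProcessFacet(interactions=[M.Interaction(
            partner_a=_tref(vocab, "organism/kingdom", "Fungi"),
            partner_b=_tref(vocab, "organism/kingdom", "Plantae"),
            direction=_tref(vocab, "process/interaction/direction", "Affects"),
            quality=_tref(vocab, "process/interaction/quality", "Antagonism"),
            name=_tref(vocab, "process/interaction/name", "Parasitism"))]))
    symbiosis = M.AnnotationRecord(
        record_id="fungi-symbiosis",
        general=g("Mycorrhizal symbiosis",
                  "Data on fungi in mutualistic symbiosis with plants."),
        process=M.ProcessFacet(interactions=[M.Interaction(
            partner_a=_tref(vocab, "organism/kingdom", "Fungi"),
            partner_b=_tref(vocab, "organism/kingdom", "Plantae"),
            direction=_tref(vocab, "process/interaction/direction", "Mutual"),
            quality=_tref(vocab, "process/interaction/quality", "Mutualism"),
            name=_tref(vocab, "process/interaction/name", "Symbiosis"))]))
    return [parasitism, symbiosis]


PRESETS = {"carbon-intro": _carbon_intro,
           "fungi-interaction": _fungi_interaction}


def generate_corpus(config: CorpusConfig,
                    vocab: Vocabulary | None = None) -> list[M.AnnotationRecord]:
    """Generate a corpus of valid annotation records; same config (and
    seed) always yields the identical corpus."""
    if vocab is None:
        vocab = load_vocabulary()
    if config.preset is not None:
        try:
            return PRESETS[config.preset](vocab)
        except KeyError:
            raise EcofacetError(f"unknown preset {config.preset!r}") from None
    rng = random.Random(config.seed)
    return [_random_record(rng, vocab, f"rec-{i:04d}", config)
            for i in range(config.n_records)]


# -------------------------------------------------------- source documents
def generate_source_docs(standard: str, n: int, seed: int,
                         vocab: Vocabulary | None = None):
    """Generate ``n`` well-formed source-standard documents paired with
    the partial annotation record each should import to.

    Returns a list of ``(payload, expected_record)`` tuples; the payload
    is an XML string for EML/ABCD and a list of term->value rows for
    Darwin Core.
    """
    if vocab is None:
        vocab = load_vocabulary()
    makers = {"EML": _eml_doc, "ABCD": _abcd_doc, "DwC": _dwc_doc}
    try:
        maker = makers[standard]
    except KeyError:
        raise EcofacetError(
            f"unsupported standard {standard!r}; use one of {sorted(makers)}")
    rng = random.Random(seed)
    return [maker(rng, vocab, i) for i in range(n)]


def _date(rng):
    return f"{rng.randint(1990, 2015):04d}-{rng.randint(1, 12):02d}-" \
           f"{rng.randint(1, 28):02d}"


def _eml_doc(rng: random.Random, vocab: Vocabulary, i: int):
    title = f"Survey of {_WORDS[rng.randrange(len(_WORDS))]} dynamics {i}"
    person = _NAMES[rng.randrange(len(_NAMES))]
    given, sur = person.split(" ", 1)
    begin, end = sorted((_date(rng), _date(rng)))
    desc = f"Site {rng.randint(1, 99)} study area"
    west, east = sorted((_coord(rng, 170), _coord(rng, 170)))
    south, north = sorted((_coord(rng, 80), _coord(rng, 80)))
    species = _SPECIES[rng.randrange(len(_SPECIES))]
    pid = f"eml-fixture-{i}"
    doc = f"""<?xml version="1.0" encoding="UTF-8"?>
<eml:eml xmlns:eml="eml://ecoinformatics.org/eml-2.1.1" packageId="{pid}">
 <dataset>
  <title>{title}</title>
  <creator>
   <individualName><givenName>{given}</givenName><surName>{sur}</surName></individualName>
  </creator>
  <abstract><para>Synthetic fixture abstract.</para></abstract>
  <coverage>
   <temporalCoverage>
    <rangeOfDates>
     <beginDate><calendarDate>{begin}</calendarDate></beginDate>
     <endDate><calendarDate>{end}</calendarDate></endDate>
    </rangeOfDates>
   </temporalCoverage>
   <geographicCoverage>
    <geographicDescription>{desc}</geographicDescription>
    <boundingCoordinates>
     <westBoundingCoordinate>{west}</westBoundingCoordinate>
     <eastBoundingCoordinate>{east}</eastBoundingCoordinate>
     <northBoundingCoordinate>{north}</northBoundingCoordinate>
     <southBoundingCoordinate>{south}</southBoundingCoordinate>
    </boundingCoordinates>
   </geographicCoverage>
   <taxonomicCoverage>
    <taxonomicClassification>
     <taxonRankName>Kingdom</taxonRankName>
     <taxonRankValue>Plantae</taxonRankValue>
     <taxonomicClassification>
      <taxonRankName>Species</taxonRankName>
      <taxonRankValue>{species}</taxonRankValue>
     </taxonomicClassification>
    </taxonomicClassification>
   </taxonomicCoverage>
  </coverage>
 </dataset>
</eml:eml>
"""
    expected = M.AnnotationRecord(
        record_id=pid,
        general=M.GeneralInfo(title=title,
                              abstract="Synthetic fixture abstract.",
                              parties=[M.Party(person, role="creator")]),
        time=M.TimeFacet(start=begin, end=end),
        space=M.SpaceFacet(
            locations=[M.Location(name=desc)],
            bounding_box=M.BoundingBox(west=west, south=south, east=east,
                                       north=north)),
        organism=M.OrganismFacet(
            names=[M.OrganismName(scientific_name=species)],
            taxonomy={"kingdom": "Plantae"}))
    return doc, expected


def _abcd_doc(rng: random.Random, vocab: Vocabulary, i: int):
    title = f"Collection of {_WORDS[rng.randrange(len(_WORDS))]} specimens {i}"
    owner = _NAMES[rng.randrange(len(_NAMES))]
    n_units = rng.randint(1, 4)
    country_term = vocab.terms_at("space/country")[
        rng.randrange(len(vocab.terms_at("space/country")))]
    units_xml, names, locations = [], [], []
    starts = []
    for u in range(n_units):
        date = _date(rng)
        starts.append(date)
        locality = f"Sampling site {u + 1}"
        species = _SPECIES[rng.randrange(len(_SPECIES))]
        units_xml.append(f"""
   <Unit>
    <Gathering>
     <DateTime><ISODateTimeBegin>{date}</ISODateTimeBegin></DateTime>
     <LocalityText>{locality}</LocalityText>
     <Country><Name>{country_term.label}</Name></Country>
    </Gathering>
    <Identifications>
     <Identification>
      <Result>
       <TaxonIdentified>
        <ScientificName>
         <FullScientificNameString>{species}</FullScientificNameString>
        </ScientificName>
       </TaxonIdentified>
      </Result>
     </Identification>
    </Identifications>
   </Unit>""")
        names.append(M.OrganismName(scientific_name=species))
        locations.append(M.Location(
            name=locality,
            country=M.TermRef(country_term.label, country_term.id,
                              country_term.uri, country_term.status)))
    guid = f"abcd-fixture-{i}"
    doc = f"""<?xml version="1.0" encoding="UTF-8"?>
<DataSets xmlns="http://www.tdwg.org/schemas/abcd/2.06">
 <DataSet>
  <DatasetGUID>{guid}</DatasetGUID>
  <Metadata>
   <Description><Representation><Title>{title}</Title></Representation></Description>
   <Owners><Owner><Person><FullName>{owner}</FullName></Person></Owner></Owners>
  </Metadata>
  <Units>{''.join(units_xml)}
  </Units>
 </DataSet>
</DataSets>
"""
    expected = M.AnnotationRecord(
        record_id=guid,
        general=M.GeneralInfo(title=title,
                              parties=[M.Party(owner, role="owner")]),
        time=M.TimeFacet(start=min(starts)),
        space=M.SpaceFacet(locations=locations),
        organism=M.OrganismFacet(names=names))
    return doc, expected


def _dwc_doc(rng: random.Random, vocab: Vocabulary, i: int):
    countries = vocab.terms_at("space/country")
    country = countries[rng.randrange(len(countries))]
    continents = vocab.terms_at("space/continent")
    continent = continents[rng.randrange(len(continents))]
    dataset = f"Occurrence dataset {i}"
    collector = _NAMES[rng.randrange(len(_NAMES))]
    n_rows = rng.randint(1, 4)
    rows, points, names = [], [], []
    dates = []
    for r in range(n_rows):
        lat, lon = _coord(rng, 80), _coord(rng, 170)
        date = _date(rng)
        dates.append(date)
        species = _SPECIES[r % len(_SPECIES)]
        rows.append({
            "occurrenceID": f"dwc-fixture-{i}-{r}",
            "datasetName": dataset,
            "recordedBy": collector,
            "eventDate": date,
            "decimalLatitude": str(lat),
            "decimalLongitude": str(lon),
            "country": country.label,
            "continent": continent.label,
            "kingdom": "Animalia",
            "family": "Carabidae",
            "scientificName": species,
        })
        points.append(M.GeoPoint(lat, lon))
        names.append(M.OrganismName(scientific_name=species))
    expected = M.AnnotationRecord(
        record_id=f"dwc-fixture-{i}-0",
        general=M.GeneralInfo(title=dataset,
                              parties=[M.Party(collector, role="collector")]),
        time=M.TimeFacet(start=min(dates), end=max(dates)),
        space=M.SpaceFacet(
            locations=[M.Location(
                name=country.label,
                country=M.TermRef(country.label, country.id, country.uri,
                                  country.status),
                continent=M.TermRef(continent.label, continent.id,
                                    continent.uri, continent.status))
                for _ in range(n_rows)],
            points=points),
        organism=M.OrganismFacet(
            names=names,
            taxonomy={"kingdom": "Animalia", "family": "Carabidae"}))
    return rows, expected
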