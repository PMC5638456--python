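# ecofacet

A toolkit for the detailed annotation and faceted discovery of ecological
data. It provides:

* **Controlled vocabularies** (`ecofacet.vocabulary`) — packaged term
  tables organised by slash-separated facet paths, including the full
  chronostratigraphic hierarchy (5 eons, 10 eras, 22 periods, 34 epochs,
  98 ages with numeric boundaries), spatial/temporal scale classes,
  sphere layers, biome descriptors, interaction qualities, the periodic
  table and more. Open fields accept user-proposed candidate terms which
  a curator can accept, merge (with synonym tracking and id redirects) or
  reject.
* **Annotation model** (`ecofacet.model`) — records made of a general
  metadata block plus eight orthogonal facet blocks (time, space, sphere,
  biome, organism, process, chemical, method), a deterministic field
  registry, validation (errors vs. warnings) and canonical term
  resolution with URI storage.
* **Classifiers** (`ecofacet.classify`) — deterministic mapping of areas
  to scale classes (Point &lt; 1 m², Plot 1 m²–0.01 km², Region
  0.01–10 000 km², Continent 10 000–10⁸ km², Global above), intervals to
  time-unit classes, and numeric ages (Ma) to chronostratigraphic chains;
  plus decimal-degree bounding-box containment with antimeridian wrap.
* **XML I/O** (`ecofacet.xmlio`) — deterministic XSD emission (closed
  fields constrained by enumerations) and precision-preserving,
  round-trip-safe reading/writing of annotation documents. A small
  generic XSD-subset interpreter (`ecofacet.xsdlite`) validates instance
  documents independently of the writer.
* **Crosswalk importers** (`ecofacet.crosswalk`) — partial records from
  EML 2.x, ABCD 2.06 and Darwin Core term–value records, driven by
  shipped concept-map files, with a per-import mapping report
  (mapped / missing_in_source / present_unparsed).
* **Faceted search** (`ecofacet.facetsearch`) — inverted index with
  hierarchy-expanded postings, combined full-text + facet queries
  (AND across fields, OR within a field), interaction filters with
  direction-aware partner matching, ordered-scale range filters,
  incremental refinement and multi-select facet counts.
* **Fixtures** (`ecofacet.fixtures`) — seed-deterministic synthetic
  corpora and source-standard documents, including the "carbon-intro"
  and "fungi-interaction" scenario presets.

## CLI

```bash
ecofacet vocab list time/geological/eon
ecofacet vocab suggest process/interaction/quality A
ecofacet vocab propose process/name mycorrhization --definition "..."
ecofacet classify area 5000km2          # -> Region
ecofacet classify age 0.001             # -> eon..epoch chain
ecofacet schema emit > annotation.xsd
ecofacet annotate > my-record.xml       # minimal template
ecofacet validate my-record.xml
ecofacet import --from eml dataset.eml.xml --report report.json
ecofacet fixtures corpus --preset carbon-intro --out-dir corpus/
ecofacet index build corpus/ --out index.json
ecofacet query corpus/ --text carbon \
    --filter "method/variable=Elevated carbon dioxide concentration"
```

## Vocabulary data format

Term tables are UTF-8 TSV files with columns `id`, `label`, `facet_path`,
`parent_id`, `definition`, `uri`, `status` (core/candidate/deprecated),
`synonyms` (pipe-separated); extra columns (e.g. `start_ma`/`end_ma` on
geological units, `lower_m2`/`upper_m2` on scale classes, `seconds` on
time units) are preserved as term attributes. `paths.tsv` registers the
valid facet paths and whether each is open (extendable) or closed
(content-restricted). The packaged geological table is pinned to the
chart edition with rank counts 5/10/22/34/98; `VERSION` and
`provenance.tsv` record the vintage and sources.
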