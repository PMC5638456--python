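{
 "standard": "DwC",
 "entries": [
  {
   "source_concept": "datasetName",
   "target_field": "general/title"
  },
  {
   "source_concept": "absent",
   "target_field": "general/abstract"
  },
  {
   "source_concept": "recordedBy",
   "target_field": "general/parties"
  },
  {
   "source_concept": "absent",
   "target_field": "general/access"
  },
  {
   "source_concept": "eventDate",
   "target_field": "time/start"
  },
  {
   "source_concept": "eventDate",
   "target_field": "time/end"
  },
  {
   "source_concept": "absent",
   "target_field": "time/timezone"
  },
  {
   "source_concept": "earliestEpochOrLowestSeries",
   "target_field": "time/geological"
  },
  {
   "source_concept": "absent",
   "target_field": "time/resolution"
  },
  {
   "source_concept": "absent",
   "target_field": "time/extent"
  },
  {
   "source_concept": "locality",
   "target_field": "space/location/name"
  },
  {
   "source_concept": "absent",
   "target_field": "space/location/type"
  },
  {
   "source_concept": "country",
   "target_field": "space/location/country"
  },
  {
   "source_concept": "continent",
   "target_field": "space/location/continent"
  },
  {
   "source_concept": "footprintWKT",
   "target_field": "space/bounding_box"
  },
  {
   "source_concept": "decimalLatitude + decimalLongitude",
   "target_field": "space/point"
  },
  {
   "source_concept": "absent",
   "target_field": "space/resolution"
  },
  {
   "source_concept": "absent",
   "target_field": "space/extent"
  },
  {
   "source_concept": "absent",
   "target_field": "biome/latitudinal"
  },
  {
   "source_concept": "absent",
   "target_field": "biome/altitudinal"
  },
  {
   "source_concept": "absent",
   "target_field": "biome/moisture"
  },
  {
   "source_concept": "absent",
   "target_field": "biome/continentality"
  },
  {
   "source_concept": "habitat",
   "target_field": "biome/physiognomy"
  },
  {
   "source_concept": "absent",
   "target_field": "biome/special"
  },
  {
   "source_concept": "absent",
   "target_field": "biome/condition"
  },
  {
   "source_concept": "absent",
   "target_field": "biome/usage"
  },
  {
   "source_concept": "scientificName",
   "target_field": "organism/name"
  },
  {
   "source_concept": "absent",
   "target_field": "organism/code"
  },
  {
   "source_concept": "kingdom | phylum | class | order | family | genus",
   "target_field": "organism/taxonomy"
  },
  {
   "source_concept": "absent",
   "target_field": "method/approach"
  },
  {
   "source_concept": "absent",
   "target_field": "method/context"
  },
  {
   "source_concept": "samplingProtocol",
   "target_field": "method/variable"
  }
 ]
}
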