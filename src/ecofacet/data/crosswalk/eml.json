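{
 "standard": "EML",
 "entries": [
  {
   "source_concept": "dataset/title",
   "target_field": "general/title"
  },
  {
   "source_concept": "dataset/abstract",
   "target_field": "general/abstract"
  },
  {
   "source_concept": "dataset/creator | dataset/contact",
   "target_field": "general/parties"
  },
  {
   "source_concept": "dataset/distribution/online/url",
   "target_field": "general/access"
  },
  {
   "source_concept": "coverage/temporalCoverage/rangeOfDates/beginDate/calendarDate",
   "target_field": "time/start"
  },
  {
   "source_concept": "coverage/temporalCoverage/rangeOfDates/endDate/calendarDate",
   "target_field": "time/end"
  },
  {
   "source_concept": "absent",
   "target_field": "time/timezone"
  },
  {
   "source_concept": "absent",
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
   "source_concept": "coverage/geographicCoverage/geographicDescription",
   "target_field": "space/location/name"
  },
  {
   "source_concept": "absent",
   "target_field": "space/location/type"
  },
  {
   "source_concept": "absent",
   "target_field": "space/location/country"
  },
  {
   "source_concept": "absent",
   "target_field": "space/location/continent"
  },
  {
   "source_concept": "coverage/geographicCoverage/boundingCoordinates",
   "target_field": "space/bounding_box"
  },
  {
   "source_concept": "absent",
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
   "source_concept": "absent",
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
   "source_concept": "coverage/taxonomicCoverage/taxonomicClassification/taxonRankValue",
   "target_field": "organism/name"
  },
  {
   "source_concept": "absent",
   "target_field": "organism/code"
  },
  {
   "source_concept": "coverage/taxonomicCoverage/taxonomicClassification",
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
   "source_concept": "methods/methodStep/description",
   "target_field": "method/variable"
  }
 ]
}
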