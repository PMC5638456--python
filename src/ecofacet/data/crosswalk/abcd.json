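{
 "standard": "ABCD",
 "entries": [
  {
   "source_concept": "Metadata/Description/Representation/Title",
   "target_field": "general/title"
  },
  {
   "source_concept": "Metadata/Description/Representation/Details",
   "target_field": "general/abstract"
  },
  {
   "source_concept": "Metadata/Owners/Owner/Person/FullName | ContentContacts/ContentContact/Name",
   "target_field": "general/parties"
  },
  {
   "source_concept": "Metadata/Description/Representation/URI",
   "target_field": "general/access"
  },
  {
   "source_concept": "Units/Unit/Gathering/DateTime/ISODateTimeBegin",
   "target_field": "time/start"
  },
  {
   "source_concept": "Units/Unit/Gathering/DateTime/ISODateTimeEnd",
   "target_field": "time/end"
  },
  {
   "source_concept": "absent",
   "target_field": "time/timezone"
  },
  {
   "source_concept": "Units/Unit/Gathering/Stratigraphy",
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
   "source_concept": "Units/Unit/Gathering/LocalityText",
   "target_field": "space/location/name"
  },
  {
   "source_concept": "absent",
   "target_field": "space/location/type"
  },
  {
   "source_concept": "Units/Unit/Gathering/Country/Name",
   "target_field": "space/location/country"
  },
  {
   "source_concept": "absent",
   "target_field": "space/location/continent"
  },
  {
   "source_concept": "absent",
   "target_field": "space/bounding_box"
  },
  {
   "source_concept": "Units/Unit/Gathering/SiteCoordinateSets/SiteCoordinates/CoordinatesLatLong",
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
   "source_concept": "Units/Unit/Gathering/Biotope",
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
   "source_concept": "Units/Unit/Identifications/Identification/Result/TaxonIdentified/ScientificName/FullScientificNameString",
   "target_field": "organism/name"
  },
  {
   "source_concept": "absent",
   "target_field": "organism/code"
  },
  {
   "source_concept": "Units/Unit/Identifications/Identification/Result/TaxonIdentified/HigherTaxa",
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
   "source_concept": "Units/Unit/Gathering/Method",
   "target_field": "method/variable"
  }
 ]
}
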