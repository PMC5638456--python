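subtree	source
time/geological	International Chronostratigraphic Chart, edition with rank counts 5/10/22/34/98; pinned for stability.
time/zone	IANA time zone database identifiers (seeded subset).
space/country	GeoNames gazetteer (seeded subset; extendable via term tables).
space/continent	GeoNames gazetteer.
chemical/element	Periodic table of the elements (IUPAC names).
chemical/function	Inspired by the Chemical Entities of Biological Interest ontology (CHEBI).
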