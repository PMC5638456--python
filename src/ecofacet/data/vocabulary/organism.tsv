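id	label	facet_path	parent_id	definition	uri	status	synonyms
organism-code-botanical	Botanical	organism/code		Name governed by the botanical nomenclature code.		core	
organism-code-zoological	Zoological	organism/code		Name governed by the zoological nomenclature code.		core	
organism-code-fungal	Fungal	organism/code		Name governed by the code as applied to fungi.		core	
organism-code-viral	Viral	organism/code		Name governed by the virus classification code.		core	
organism-kingdom-animalia	Animalia	organism/kingdom		Kingdom-level taxon 'Animalia' used for interaction partners.		core	
organism-kingdom-plantae	Plantae	organism/kingdom		Kingdom-level taxon 'Plantae' used for interaction partners.		core	
organism-kingdom-fungi	Fungi	organism/kingdom		Kingdom-level taxon 'Fungi' used for interaction partners.		core	
organism-kingdom-protista	Protista	organism/kingdom		Kingdom-level taxon 'Protista' used for interaction partners.		core	
organism-kingdom-bacteria	Bacteria	organism/kingdom		Kingdom-level taxon 'Bacteria' used for interaction partners.		core	
organism-kingdom-archaea	Archaea	organism/kingdom		Kingdom-level taxon 'Archaea' used for interaction partners.		core	
organism-kingdom-viruses	Viruses	organism/kingdom		Kingdom-level taxon 'Viruses' used for interaction partners.		core	
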