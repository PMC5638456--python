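id	label	facet_path	parent_id	definition	uri	status	synonyms	scale_rank
sphere-atmosphere-troposphere	Troposphere	sphere/atmosphere		Vertical layer of the atmosphere: Troposphere (layer 1 from the surface).		core		
sphere-atmosphere-stratosphere	Stratosphere	sphere/atmosphere		Vertical layer of the atmosphere: Stratosphere (layer 2 from the surface).		core		
sphere-atmosphere-mesosphere	Mesosphere	sphere/atmosphere		Vertical layer of the atmosphere: Mesosphere (layer 3 from the surface).		core		
sphere-atmosphere-thermosphere	Thermosphere	sphere/atmosphere		Vertical layer of the atmosphere: Thermosphere (layer 4 from the surface).		core		
sphere-atmosphere-exosphere	Exosphere	sphere/atmosphere		Vertical layer of the atmosphere: Exosphere (layer 5 from the surface).		core		
sphere-hydrosphere-epipelagic	Epipelagic	sphere/hydrosphere		Sunlit upper zone of the open water column (0-200 m).		core		
sphere-hydrosphere-mesopelagic	Mesopelagic	sphere/hydrosphere		Twilight zone of the open water column (200-1000 m).		core		
sphere-hydrosphere-bathypelagic	Bathypelagic	sphere/hydrosphere		Dark open-water zone (1000-4000 m).		core		
sphere-hydrosphere-abyssopelagic	Abyssopelagic	sphere/hydrosphere		Near-bottom open-water zone (4000-6000 m).		core		
sphere-hydrosphere-hadopelagic	Hadopelagic	sphere/hydrosphere		Deep-trench water zone (below 6000 m).		core		
sphere-hydrosphere-littoral	Littoral	sphere/hydrosphere		Near-shore zone of a water body.		core		
sphere-hydrosphere-limnetic	Limnetic	sphere/hydrosphere		Open surface water of a lake away from the shore.		core		
sphere-hydrosphere-profundal	Profundal	sphere/hydrosphere		Deep zone of a lake below effective light penetration.		core		
sphere-hydrosphere-benthic	Benthic	sphere/hydrosphere		Zone at and in the bottom sediment of a water body.		core		
sphere-hydrosphere-riparian	Riparian	sphere/hydrosphere		Interface zone between land and a stream or river.		core		
sphere-pedosphere-o-horizon	O Horizon	sphere/pedosphere		Organic surface layer of a soil profile.		core		
sphere-pedosphere-a-horizon	A Horizon	sphere/pedosphere		Mineral topsoil layer enriched in humified organic matter.		core		
sphere-pedosphere-b-horizon	B Horizon	sphere/pedosphere		Subsoil layer of accumulation (illuviation).		core		
sphere-pedosphere-c-horizon	C Horizon	sphere/pedosphere		Weathered parent material below the solum.		core		
sphere-pedosphere-r-horizon	R Horizon	sphere/pedosphere		Consolidated bedrock beneath the soil profile.		core		
sphere-lithosphere-crust	Crust	sphere/lithosphere		Outermost solid rock shell of the earth.		core		
sphere-lithosphere-upper-mantle	Upper Mantle	sphere/lithosphere		Rock layer directly beneath the crust.		core		
sphere-organization-atom	Atom	sphere/organization		Level of biological organization: Atom (rank 1 on the Atom-to-Biosphere scale).		core		1
sphere-organization-molecule	Molecule	sphere/organization		Level of biological organization: Molecule (rank 2 on the Atom-to-Biosphere scale).		core		2
sphere-organization-cell	Cell	sphere/organization		Level of biological organization: Cell (rank 3 on the Atom-to-Biosphere scale).		core		3
sphere-organization-tissue	Tissue	sphere/organization		Level of biological organization: Tissue (rank 4 on the Atom-to-Biosphere scale).		core		4
sphere-organization-organ	Organ	sphere/organization		Level of biological organization: Organ (rank 5 on the Atom-to-Biosphere scale).		core		5
sphere-organization-organism	Organism	sphere/organization		Level of biological organization: Organism (rank 6 on the Atom-to-Biosphere scale).		core		6
sphere-organization-population	Population	sphere/organization		Level of biological organization: Population (rank 7 on the Atom-to-Biosphere scale).		core		7
sphere-organization-community	Community	sphere/organization		Level of biological organization: Community (rank 8 on the Atom-to-Biosphere scale).		core		8
sphere-organization-ecosystem	Ecosystem	sphere/organization		Level of biological organization: Ecosystem (rank 9 on the Atom-to-Biosphere scale).		core		9
sphere-organization-biome	Biome	sphere/organization		Level of biological organization: Biome (rank 10 on the Atom-to-Biosphere scale).		core		10
sphere-organization-biosphere	Biosphere	sphere/organization		Level of biological organization: Biosphere (rank 11 on the Atom-to-Biosphere scale).		core		11
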