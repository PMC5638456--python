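id	label	facet_path	parent_id	definition	uri	status	synonyms
biome-latitudinal-polar	Polar	biome/latitudinal		Latitudinal zone polewards of the polar circles.		core	
biome-latitudinal-boreal	Boreal	biome/latitudinal		High-latitude zone dominated by coniferous forest climate.		core	
biome-latitudinal-temperate	Temperate	biome/latitudinal		Mid-latitude zone with pronounced seasons.		core	
biome-latitudinal-subtropic	Subtropic	biome/latitudinal		Zone between the temperate belt and the tropics.		core	
biome-latitudinal-tropic	Tropic	biome/latitudinal		Low-latitude zone between the tropics of Cancer and Capricorn.		core	
biome-altitudinal-colline	Colline	biome/altitudinal		Hill-country altitudinal belt below the montane zone.		core	
biome-altitudinal-montane	Montane	biome/altitudinal		Mountain forest belt below the timberline.		core	
biome-altitudinal-subalpine	Subalpine	biome/altitudinal		Transition belt around the timberline.		core	
biome-altitudinal-alpine	Alpine	biome/altitudinal		Treeless belt above the timberline.		core	
biome-altitudinal-nivale	Nivale	biome/altitudinal		Belt of permanent snow and ice.		core	
biome-moisture-arid	Arid	biome/moisture		Moisture regime with strong annual water deficit.		core	
biome-moisture-semiarid	Semiarid	biome/moisture		Moisture regime with seasonal water deficit.		core	
biome-moisture-subhumid	Subhumid	biome/moisture		Moisture regime near the balance of supply and demand.		core	
biome-moisture-humid	Humid	biome/moisture		Moisture regime with annual water surplus.		core	
biome-moisture-perhumid	Perhumid	biome/moisture		Moisture regime with permanent water surplus.		core	
biome-continentality-maritime	Maritime	biome/continentality		Climate strongly buffered by a nearby ocean.		core	
biome-continentality-transitional	Transitional	biome/continentality		Climate intermediate between maritime and continental.		core	
biome-continentality-continental	Continental	biome/continentality		Climate with large annual temperature amplitude far from oceans.		core	
biome-physiognomy-forest	Forest	biome/physiognomy		Gross vegetation structure: forest.		core	
biome-physiognomy-woodland	Woodland	biome/physiognomy		Gross vegetation structure: woodland.		core	
biome-physiognomy-savannah	Savannah	biome/physiognomy		Gross vegetation structure: savannah.		core	
biome-physiognomy-shrubland	Shrubland	biome/physiognomy		Gross vegetation structure: shrubland.		core	
biome-physiognomy-grassland	Grassland	biome/physiognomy		Gross vegetation structure: grassland.		core	
biome-physiognomy-desert	Desert	biome/physiognomy		Gross vegetation structure: desert.		core	
biome-physiognomy-tundra	Tundra	biome/physiognomy		Gross vegetation structure: tundra.		core	
biome-physiognomy-wetland	Wetland	biome/physiognomy		Gross vegetation structure: wetland.		core	
biome-special-amphibiome	Amphibiome	biome/special		Biome periodically flooded and drained (e.g. river margins).		core	
biome-special-halobiome	Halobiome	biome/special		Biome shaped by high salt concentration.		core	
biome-special-helobiome	Helobiome	biome/special		Swamp or marsh biome on waterlogged soil.		core	
biome-special-orobiome	Orobiome	biome/special		Mountain biome shaped by elevation.		core	
biome-special-pedobiome	Pedobiome	biome/special		Biome determined by an azonal soil condition.		core	
biome-condition-natural	Natural	biome/condition		General condition of the biome: natural.		core	
biome-condition-urban	Urban	biome/condition		General condition of the biome: urban.		core	
biome-usage-agriculture	Agriculture	biome/usage		Dominant form of land or water usage: agriculture.		core	
biome-usage-forestry	Forestry	biome/usage		Dominant form of land or water usage: forestry.		core	
biome-usage-fishery	Fishery	biome/usage		Dominant form of land or water usage: fishery.		core	
biome-usage-pasture	Pasture	biome/usage		Dominant form of land or water usage: pasture.		core	
biome-usage-conservation	Conservation	biome/usage		Dominant form of land or water usage: conservation.		core	
biome-usage-recreation	Recreation	biome/usage		Dominant form of land or water usage: recreation.		core	
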