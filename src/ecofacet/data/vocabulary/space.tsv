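id	label	facet_path	parent_id	definition	uri	status	synonyms	lower_m2	upper_m2
space-resolution-point	Point	space/resolution		Spatial scale class. Areas below 1 square metre.		core		0.0	1.0
space-resolution-plot	Plot	space/resolution		Spatial scale class. Areas from 1 square metre up to 0.01 square kilometre.		core		1.0	10000.0
space-resolution-region	Region	space/resolution		Spatial scale class. Areas from 0.01 up to 10000 square kilometres.		core		10000.0	10000000000.0
space-resolution-continent	Continent	space/resolution		Spatial scale class. Areas from 10000 up to 100000000 square kilometres.		core		10000000000.0	100000000000000.0
space-resolution-global	Global	space/resolution		Spatial scale class. Areas above 100000000 square kilometres.		core		100000000000000.0	
space-location_type-city	City	space/location_type		Type of named location: city.		core			
space-location_type-village	Village	space/location_type		Type of named location: village.		core			
space-location_type-stream	Stream	space/location_type		Type of named location: stream.		core			
space-location_type-river	River	space/location_type		Type of named location: river.		core			
space-location_type-lake	Lake	space/location_type		Type of named location: lake.		core			
space-location_type-forest	Forest	space/location_type		Type of named location: forest.		core			
space-location_type-mountain	Mountain	space/location_type		Type of named location: mountain.		core			
space-location_type-coast	Coast	space/location_type		Type of named location: coast.		core			
space-location_type-island	Island	space/location_type		Type of named location: island.		core			
space-location_type-field-site	Field Site	space/location_type		Type of named location: field site.		core			
space-location_type-wetland	Wetland	space/location_type		Type of named location: wetland.		core			
space-location_type-glacier	Glacier	space/location_type		Type of named location: glacier.		core			
space-continent-africa	Africa	space/continent		Continent 'Africa' (seeded from the GeoNames gazetteer).		core			
space-continent-antarctica	Antarctica	space/continent		Continent 'Antarctica' (seeded from the GeoNames gazetteer).		core			
space-continent-asia	Asia	space/continent		Continent 'Asia' (seeded from the GeoNames gazetteer).		core			
space-continent-europe	Europe	space/continent		Continent 'Europe' (seeded from the GeoNames gazetteer).		core			
space-continent-north-america	North America	space/continent		Continent 'North America' (seeded from the GeoNames gazetteer).		core			
space-continent-oceania	Oceania	space/continent		Continent 'Oceania' (seeded from the GeoNames gazetteer).		core			
space-continent-south-america	South America	space/continent		Continent 'South America' (seeded from the GeoNames gazetteer).		core			
space-country-afghanistan	Afghanistan	space/country		Country 'Afghanistan' (seeded from the GeoNames gazetteer).		core			
space-country-andorra	Andorra	space/country		Country 'Andorra' (seeded from the GeoNames gazetteer).		core			
space-country-argentina	Argentina	space/country		Country 'Argentina' (seeded from the GeoNames gazetteer).		core			
space-country-australia	Australia	space/country		Country 'Australia' (seeded from the GeoNames gazetteer).		core			
space-country-austria	Austria	space/country		Country 'Austria' (seeded from the GeoNames gazetteer).		core			
space-country-belgium	Belgium	space/country		Country 'Belgium' (seeded from the GeoNames gazetteer).		core			
space-country-brazil	Brazil	space/country		Country 'Brazil' (seeded from the GeoNames gazetteer).		core			
space-country-canada	Canada	space/country		Country 'Canada' (seeded from the GeoNames gazetteer).		core			
space-country-chile	Chile	space/country		Country 'Chile' (seeded from the GeoNames gazetteer).		core			
space-country-china	China	space/country		Country 'China' (seeded from the GeoNames gazetteer).		core			
space-country-czechia	Czechia	space/country		Country 'Czechia' (seeded from the GeoNames gazetteer).		core			
space-country-denmark	Denmark	space/country		Country 'Denmark' (seeded from the GeoNames gazetteer).		core			
space-country-finland	Finland	space/country		Country 'Finland' (seeded from the GeoNames gazetteer).		core			
space-country-france	France	space/country		Country 'France' (seeded from the GeoNames gazetteer).		core			
space-country-germany	Germany	space/country		Country 'Germany' (seeded from the GeoNames gazetteer).		core			
space-country-greece	Greece	space/country		Country 'Greece' (seeded from the GeoNames gazetteer).		core			
space-country-india	India	space/country		Country 'India' (seeded from the GeoNames gazetteer).		core			
space-country-italy	Italy	space/country		Country 'Italy' (seeded from the GeoNames gazetteer).		core			
space-country-japan	Japan	space/country		Country 'Japan' (seeded from the GeoNames gazetteer).		core			
space-country-kenya	Kenya	space/country		Country 'Kenya' (seeded from the GeoNames gazetteer).		core			
space-country-mexico	Mexico	space/country		Country 'Mexico' (seeded from the GeoNames gazetteer).		core			
space-country-netherlands	Netherlands	space/country		Country 'Netherlands' (seeded from the GeoNames gazetteer).		core			
space-country-new-zealand	New Zealand	space/country		Country 'New Zealand' (seeded from the GeoNames gazetteer).		core			
space-country-norway	Norway	space/country		Country 'Norway' (seeded from the GeoNames gazetteer).		core			
space-country-poland	Poland	space/country		Country 'Poland' (seeded from the GeoNames gazetteer).		core			
space-country-portugal	Portugal	space/country		Country 'Portugal' (seeded from the GeoNames gazetteer).		core			
space-country-south-africa	South Africa	space/country		Country 'South Africa' (seeded from the GeoNames gazetteer).		core			
space-country-spain	Spain	space/country		Country 'Spain' (seeded from the GeoNames gazetteer).		core			
space-country-sweden	Sweden	space/country		Country 'Sweden' (seeded from the GeoNames gazetteer).		core			
space-country-switzerland	Switzerland	space/country		Country 'Switzerland' (seeded from the GeoNames gazetteer).		core			
space-country-united-kingdom	United Kingdom	space/country		Country 'United Kingdom' (seeded from the GeoNames gazetteer).		core			
space-country-united-states	United States	space/country		Country 'United States' (seeded from the GeoNames gazetteer).		core			
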