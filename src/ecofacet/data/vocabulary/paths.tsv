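path	policy
time/geological/eon	closed
time/geological/era	closed
time/geological/period	closed
time/geological/epoch	closed
time/geological/age	closed
time/unit	closed
time/zone	closed
space/resolution	closed
space/location_type	closed
space/continent	closed
space/country	closed
space/location_name	open
sphere/atmosphere	closed
sphere/hydrosphere	closed
sphere/pedosphere	closed
sphere/lithosphere	closed
sphere/organization	closed
biome/latitudinal	closed
biome/altitudinal	closed
biome/moisture	closed
biome/continentality	closed
biome/physiognomy	closed
biome/special	closed
biome/condition	closed
biome/usage	closed
organism/code	closed
organism/kingdom	closed
process/name	open
process/involved	closed
process/characterization	closed
process/interaction/name	open
process/interaction/direction	closed
process/interaction/quality	closed
chemical/element	closed
chemical/compound	open
chemical/function	closed
method/approach	closed
method/context	closed
method/variable	open
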