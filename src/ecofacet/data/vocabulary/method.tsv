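id	label	facet_path	parent_id	definition	uri	status	synonyms
method-approach-virtual	Virtual	method/approach		Study performed in silico, e.g. a simulation.		core	
method-approach-manipulative	Manipulative	method/approach		Study with experimental factors mostly under the researcher's control.		core	
method-approach-observational	Observational	method/approach		Study where plot selection, not manipulation, creates factor gradients.		core	
method-context-microcosm	Microcosm	method/context		Small controlled setting, e.g. a laboratory experiment.		core	
method-context-mesocosm	Mesocosm	method/context		Intermediate semi-controlled setting, e.g. an ecotron or greenhouse.		core	
method-context-macrocosm	Macrocosm	method/context		Full field setting under natural conditions.		core	
method-variable-producer-diversity	Producer diversity	method/variable		Frequently manipulated study variable: producer diversity.		core	
method-variable-consumer-density	Consumer density	method/variable		Frequently manipulated study variable: consumer density.		core	
method-variable-nutrient-availability	Nutrient availability	method/variable		Frequently manipulated study variable: nutrient availability.		core	
method-variable-elevated-carbon-dioxide-concentration	Elevated carbon dioxide concentration	method/variable		Frequently manipulated study variable: elevated carbon dioxide concentration.		core	
method-variable-temperature	Temperature	method/variable		Frequently manipulated study variable: temperature.		core	
method-variable-precipitation	Precipitation	method/variable		Frequently manipulated study variable: precipitation.		core	
method-variable-light-intensity	Light intensity	method/variable		Frequently manipulated study variable: light intensity.		core	
method-variable-grazing-pressure	Grazing pressure	method/variable		Frequently manipulated study variable: grazing pressure.		core	
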