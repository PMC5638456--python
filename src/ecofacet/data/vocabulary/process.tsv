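id	label	facet_path	parent_id	definition	uri	status	synonyms
process-name-adaption	Adaption	process/name		Generic, widely used ecological process: adaption.		core	
process-name-speciation	Speciation	process/name		Generic, widely used ecological process: speciation.		core	
process-name-migration	Migration	process/name		Generic, widely used ecological process: migration.		core	
process-name-death	Death	process/name		Generic, widely used ecological process: death.		core	
process-name-birth	Birth	process/name		Generic, widely used ecological process: birth.		core	
process-name-growth	Growth	process/name		Generic, widely used ecological process: growth.		core	
process-name-windstorm	Windstorm	process/name		Generic, widely used ecological process: windstorm.		core	
process-name-fire	Fire	process/name		Generic, widely used ecological process: fire.		core	
process-name-decomposition	Decomposition	process/name		Generic, widely used ecological process: decomposition.		core	
process-name-pollination	Pollination	process/name		Generic, widely used ecological process: pollination.		core	
process-name-dispersal	Dispersal	process/name		Generic, widely used ecological process: dispersal.		core	
process-name-nitrogen-fixation	Nitrogen fixation	process/name		Generic, widely used ecological process: nitrogen fixation.		core	
process-name-photosynthesis	Photosynthesis	process/name		Generic, widely used ecological process: photosynthesis.		core	
process-name-respiration	Respiration	process/name		Generic, widely used ecological process: respiration.		core	
process-name-herbivory	Herbivory	process/name		Generic, widely used ecological process: herbivory.		core	
process-name-predation	Predation	process/name		Generic, widely used ecological process: predation.		core	
process-name-parasitism	Parasitism	process/name		Generic, widely used ecological process: parasitism.		core	
process-name-mutualism	Mutualism	process/name		Generic, widely used ecological process: mutualism.		core	
process-involved-organisms	Organisms	process/involved		Living organisms take part in the process.		core	
process-involved-chemical	Chemical	process/involved		Chemical substances take part in the process.		core	
process-involved-matter	Matter	process/involved		Bulk matter takes part in the process.		core	
process-involved-energy	Energy	process/involved		Energy takes part in the process.		core	
process-characterization-uptake	Uptake	process/characterization		The process takes something up.		core	
process-characterization-release	Release	process/characterization		The process releases something.		core	
process-characterization-exchange	Exchange	process/characterization		The process exchanges something in both directions.		core	
process-interaction-name-parasitism	Parasitism	process/interaction/name		Named biotic interaction: parasitism.		core	
process-interaction-name-symbiosis	Symbiosis	process/interaction/name		Named biotic interaction: symbiosis.		core	
process-interaction-name-mutualism	Mutualism	process/interaction/name		Named biotic interaction: mutualism.		core	
process-interaction-name-competition	Competition	process/interaction/name		Named biotic interaction: competition.		core	
process-interaction-name-predation	Predation	process/interaction/name		Named biotic interaction: predation.		core	
process-interaction-name-herbivory	Herbivory	process/interaction/name		Named biotic interaction: herbivory.		core	
process-interaction-name-commensalism	Commensalism	process/interaction/name		Named biotic interaction: commensalism.		core	
process-interaction-name-pollination	Pollination	process/interaction/name		Named biotic interaction: pollination.		core	
process-interaction-name-mycorrhization	Mycorrhization	process/interaction/name		Named biotic interaction: mycorrhization.		core	
process-interaction-direction-mutual	Mutual	process/interaction/direction		The interaction acts in both directions between the partners.		core	
process-interaction-direction-affects	Affects	process/interaction/direction		The first partner acts on the second partner.		core	
process-interaction-direction-is-affected-by	Is Affected By	process/interaction/direction		The first partner is acted on by the second partner.		core	
process-interaction-quality-amensalism	Amensalism	process/interaction/quality		One partner is harmed, the other unaffected.		core	
process-interaction-quality-antagonism	Antagonism	process/interaction/quality		One partner benefits at the expense of the other.		core	
process-interaction-quality-commensalism	Commensalism	process/interaction/quality		One partner benefits, the other is unaffected.		core	
process-interaction-quality-competition	Competition	process/interaction/quality		Both partners are harmed by shared resource use.		core	
process-interaction-quality-mutualism	Mutualism	process/interaction/quality		Both partners benefit.		core	
process-interaction-quality-neutralism	Neutralism	process/interaction/quality		Neither partner is measurably affected.		core	
process-interaction-quality-parasitism	Parasitism	process/interaction/quality		One partner lives at the expense of the host.		core	
process-interaction-quality-predation	Predation	process/interaction/quality		One partner consumes the other.		core	
process-interaction-quality-symbiosis	Symbiosis	process/interaction/quality		Partners live in close and persistent association.		core	
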