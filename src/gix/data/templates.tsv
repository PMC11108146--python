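# kind<TAB>template.  Placeholders: {agent} {target} {decoy} {g1} {g2}.
# "relation" templates put the agent before the target with an
# interaction trigger verb in between, so the rule scorers recover the
# planted direction.  "irrelevant" templates contain no trigger stem.
relation	{agent} activates {target} during sporulation.
relation	{agent} represses {target} in stationary phase.
relation	{agent} directly regulates {target}.
relation	{agent} induces {target} under heat stress.
relation	{agent} binds the promoter of {target}.
relation_decoy	{agent} activates {target} even in the absence of {decoy}.
relation_decoy	{agent} represses {target} independently of {decoy}.
relation_decoy	{agent} strongly induces {target} while {decoy} levels stay constant.
irrelevant_plain	Samples were incubated overnight at 37 degrees.
irrelevant_plain	The growth medium contained glucose and mineral salts.
irrelevant_plain	Cultures were harvested by centrifugation.
irrelevant_plain	Optical density was monitored every hour.
irrelevant_twogene	{g1} and {g2} were detected in the proteome survey.
irrelevant_twogene	Levels of {g1} and {g2} varied between replicates.
irrelevant_onegene	{g1} is strongly expressed during germination.
irrelevant_onegene	{g1} is transcribed during outgrowth.
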