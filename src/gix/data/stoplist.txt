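# Frequent non-entity words removed from entity phrases before
# word-level NER.  Replaceable via RefinementConfig.
protein
proteins
gene
genes
factor
factors
suppressor
activator
repressor
regulator
operon
promoter
product
enzyme
region
site
complex
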