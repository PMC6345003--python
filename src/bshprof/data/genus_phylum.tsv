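genus	phylum
Bacteroides	Bacteroidetes
Parabacteroides	Bacteroidetes
Prevotella	Bacteroidetes
Lactobacillus	Firmicutes
Enterococcus	Firmicutes
Clostridium	Firmicutes
Peptoclostridium	Firmicutes
Blautia	Firmicutes
Eubacterium	Firmicutes
Roseburia	Firmicutes
Ruminococcus	Firmicutes
Streptococcus	Firmicutes
Staphylococcus	Firmicutes
Bacillus	Firmicutes
Paenibacillus	Firmicutes
Lysinibacillus	Firmicutes
Brevibacillus	Firmicutes
Listeria	Firmicutes
Intestinibacter	Firmicutes
Marvinbryantia	Firmicutes
Bifidobacterium	Actinobacteria
Collinsella	Actinobacteria
Methanobrevibacter	Euryarchaeota
Escherichia	Proteobacteria
Klebsiella	Proteobacteria
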