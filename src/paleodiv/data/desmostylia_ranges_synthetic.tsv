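# Synthetic stage-level range table matching desmostylia_occurrences_synthetic.tsv:
# one row per (taxon, rock-unit group); rows of a taxon are merged into its
# maximal first/last-appearance envelope on read.
taxon	unit	fad_old	fad_young
Archaeoparadoxia weltoni	weltoni_units	28.1	20.4
Paleoparadoxia tabatai	tabatai_units_older	20.4	16.0
Paleoparadoxia tabatai	tabatai_units_younger	16.0	11.6
Paleoparadoxia sp. Akan	Tonokita_Fm	15.9	14.9
Neoparadoxia sp. Akan	Tonokita_Fm	15.9	14.9
Neoparadoxia repenningi	repenningi_units	16.0	11.6
Neoparadoxia cecilialina	cecilialina_units	16.0	7.2
Ashoroa laticosta	laticosta_units	33.9	23.0
Cornwallius sookensis	sookensis_units_older	33.9	28.1
Cornwallius sookensis	sookensis_units_younger	28.1	20.4
Ounalashkastylus tomidai	tomidai_units	23.0	20.4
Desmostylus hesperus	hesperus_units_older	23.0	16.0
Desmostylus hesperus	hesperus_units_middle	16.0	11.6
Desmostylus hesperus	hesperus_units_younger	11.6	7.2
Desmostylus japonicus	japonicus_units	20.4	13.8
Desmostylus coalingensis	coalingensis_units	13.8	11.6
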