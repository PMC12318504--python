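# Synthetic stage-level reconstruction of the published desmostylian
# occurrence compilation: one row per (taxon, rock-unit group), with ages
# collapsed to the chronostratigraphic stages each taxon is reported from.
# Unit names are placeholders; the original locality-level data are not
# redistributed here.
taxon	unit	age_old	age_young	family
Archaeoparadoxia weltoni	weltoni_units	28.1	20.4	Paleoparadoxiidae
Paleoparadoxia tabatai	tabatai_units_older	20.4	16.0	Paleoparadoxiidae
Paleoparadoxia tabatai	tabatai_units_younger	16.0	11.6	Paleoparadoxiidae
Paleoparadoxia sp. Akan	Tonokita_Fm	15.9	14.9	Paleoparadoxiidae
Neoparadoxia sp. Akan	Tonokita_Fm	15.9	14.9	Paleoparadoxiidae
Neoparadoxia repenningi	repenningi_units	16.0	11.6	Paleoparadoxiidae
Neoparadoxia cecilialina	cecilialina_units	16.0	7.2	Paleoparadoxiidae
Ashoroa laticosta	laticosta_units	33.9	23.0	Desmostylidae
Cornwallius sookensis	sookensis_units_older	33.9	28.1	Desmostylidae
Cornwallius sookensis	sookensis_units_younger	28.1	20.4	Desmostylidae
Ounalashkastylus tomidai	tomidai_units	23.0	20.4	Desmostylidae
Desmostylus hesperus	hesperus_units_older	23.0	16.0	Desmostylidae
Desmostylus hesperus	hesperus_units_middle	16.0	11.6	Desmostylidae
Desmostylus hesperus	hesperus_units_younger	11.6	7.2	Desmostylidae
Desmostylus japonicus	japonicus_units	20.4	13.8	Desmostylidae
Desmostylus coalingensis	coalingensis_units	13.8	11.6	Desmostylidae
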