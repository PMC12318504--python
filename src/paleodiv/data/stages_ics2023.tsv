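# Oligocene-Miocene stages, ICS International Chronostratigraphic Chart 2023 (Ma)
stage	old	young
Rupelian	33.9	27.82
Chattian	27.82	23.03
Aquitanian	23.03	20.44
Burdigalian	20.44	15.97
Langhian	15.97	13.82
Serravallian	13.82	11.63
Tortonian	11.63	7.246
Messinian	7.246	5.333
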