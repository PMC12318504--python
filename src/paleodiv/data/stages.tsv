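# Oligocene-Miocene chronostratigraphic stages, rounded boundaries (Ma)
stage	old	young
Rupelian	33.9	28.1
Chattian	28.1	23.0
Aquitanian	23.0	20.4
Burdigalian	20.4	16.0
Langhian	16.0	13.8
Serravallian	13.8	11.6
Tortonian	11.6	7.2
Messinian	7.2	5.3
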