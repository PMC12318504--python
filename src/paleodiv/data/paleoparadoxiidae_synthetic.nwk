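('Archaeoparadoxia weltoni',(('Paleoparadoxia tabatai','Paleoparadoxia sp. Akan'),('Neoparadoxia sp. Akan',('Neoparadoxia repenningi','Neoparadoxia cecilialina'))));
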