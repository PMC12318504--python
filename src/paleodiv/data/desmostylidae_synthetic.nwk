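('Ashoroa laticosta',('Cornwallius sookensis',('Ounalashkastylus tomidai',('Desmostylus japonicus',('Desmostylus coalingensis','Desmostylus hesperus')))));
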