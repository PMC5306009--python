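order,n_species_described
Coleoptera,386500
Lepidoptera,157338
Diptera,155477
Hymenoptera,116861
Hemiptera,103590
Orthoptera,23855
Trichoptera,14391
Odonata,5899
Plecoptera,3743
Ephemeroptera,3240
Megaloptera,354
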