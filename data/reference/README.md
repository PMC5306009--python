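# External reference data

`order_described_species_example.csv` — approximate described-species totals
per insect order, rounded from published global biodiversity catalogues.
These are *external reference data*, not outputs of this package: they exist
only as example input for the order-representation diagnostic
(`wolbsurvey.order_representation_check`), which regresses the number of
species tested in a survey against the number described per order. Users
should substitute totals from whichever catalogue edition their analysis
cites.
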