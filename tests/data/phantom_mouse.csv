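# synthetic toy mouse-like phantom for tests; NOT a published reference phantom
region,mass_g,is_source,is_target,species
Liver,1.9,1,1,mouse
Kidneys,0.5,1,1,mouse
Redmarrow,0.22,1,1,mouse
Blood,1.7,0,0,mouse
Urinarybladdercontents,0.1,1,1,mouse
Carcass,22.6,1,0,mouse
Restofbody,22.28,1,0,mouse
TOTALBODY,25.0,0,0,mouse
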