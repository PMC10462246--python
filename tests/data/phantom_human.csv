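# synthetic toy human-like phantom for tests; NOT a published reference phantom
region,mass_g,is_source,is_target,species
Liver,1900.0,1,1,human
Kidneys,310.0,1,1,human
Redmarrow,1170.0,1,1,human
Blood,5300.0,0,0,human
Urinarybladdercontents,200.0,1,1,human
Carcass,70790.0,1,0,human
Restofbody,69420.0,1,0,human
TOTALBODY,73000.0,0,0,human
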