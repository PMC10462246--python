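# synthetic S-value matrix for the toy mouse phantom (total radiation only)
target,source,svalue_Gy_per_Bq_s
Liver,Liver,1.30e-11
Kidneys,Kidneys,4.80e-11
Redmarrow,Redmarrow,1.10e-10
Urinarybladdercontents,Urinarybladdercontents,2.40e-10
Carcass,Carcass,1.10e-12
Restofbody,Restofbody,1.10e-12
Liver,Kidneys,5.0e-13
Kidneys,Liver,4.0e-13
Redmarrow,Carcass,3.0e-13
Redmarrow,Restofbody,3.0e-13
Liver,Restofbody,2.0e-13
Kidneys,Restofbody,2.5e-13
Urinarybladdercontents,Restofbody,1.5e-13
Redmarrow,Liver,1.0e-13
Redmarrow,Kidneys,1.2e-13
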