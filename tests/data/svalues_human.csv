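# synthetic S-value matrix for the toy human phantom, split by radiation type
target,source,svalue_Gy_per_Bq_s,radiation_type
Liver,Liver,1.24e-14,beta
Liver,Liver,1.50e-15,photon
Kidneys,Kidneys,7.60e-14,beta
Kidneys,Kidneys,6.00e-15,photon
Redmarrow,Redmarrow,2.00e-14,beta
Redmarrow,Redmarrow,2.00e-15,photon
Urinarybladdercontents,Urinarybladdercontents,1.20e-13,beta
Urinarybladdercontents,Urinarybladdercontents,8.00e-15,photon
Carcass,Carcass,3.30e-16,beta
Carcass,Carcass,8.00e-17,photon
Restofbody,Restofbody,3.40e-16,beta
Restofbody,Restofbody,8.00e-17,photon
Liver,Kidneys,8.00e-16,photon
Kidneys,Liver,8.00e-16,photon
Redmarrow,Liver,3.00e-16,photon
Redmarrow,Kidneys,4.00e-16,photon
Liver,Restofbody,1.00e-16,photon
Kidneys,Restofbody,1.20e-16,photon
Redmarrow,Restofbody,1.50e-16,photon
Urinarybladdercontents,Restofbody,1.00e-16,photon
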