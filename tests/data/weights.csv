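# toy tissue and radiation weighting factors (sum of wT = 1 by construction)
kind,key,value
wT,Liver,0.3
wT,Kidneys,0.3
wT,Redmarrow,0.4
wR,photon,1.0
wR,beta,1.0
wR,alpha,20.0
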