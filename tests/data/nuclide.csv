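# synthetic decay data: a beta/photon emitter and an alpha emitter
name,half_life_h,delta_np_J,radiation_type,dose_fraction
Lu177like,159.4,2.36e-14,beta,0.85
Lu177like,159.4,2.36e-14,photon,0.15
Ac225like,238.1,4.40e-12,alpha,0.90
Ac225like,238.1,4.40e-12,beta,0.05
Ac225like,238.1,4.40e-12,photon,0.05
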