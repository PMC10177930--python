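wavelength_nm,mu_a_mm-1,mu_s_prime_mm-1
550,0.0302,1.286
600,0.0232,1.273
630,0.0218,1.259
675,0.0224,1.251
710,0.0222,1.256
730,0.0223,1.256
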