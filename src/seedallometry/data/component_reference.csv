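component,C,N,S,H
carbohydrate,0.400,0.000,0.000,0.066
albumin,0.505,0.187,0.027,0.069
s_poor_protein_other,0.519,0.194,0.001,0.068
lipid,0.760,0.000,0.000,0.120
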