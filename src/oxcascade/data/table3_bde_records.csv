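base,bde_kj_mol,k,ln_k,series,inferred
1mU,416.0,0.06,-2.81,methyl_prev,False
1mC,414.8,0.06,-2.81,methyl_prev,False
5mC,387.3,0.18,-1.71,methyl_prev,False
"1,5dmC",386.5,0.30,-1.20,methyl_prev,False
"1,5dmU",385.7,0.44,-0.82,methyl_prev,False
5mU,383.1,0.63,-0.46,methyl_prev,False
5miC,379.4,1.44,0.36,methyl_prev,False
5fC,401.0,0.53,-0.64,f,False
5f6aU,395.4,2.86,1.05,f,False
5fU,394.7,0.46,-0.78,f,False
5hmC,367.4,0.51,-0.67,hm,False
5hmU,360.0,0.66,-0.42,hm,False
5dhmU,354.1,27.66,3.32,dhm,True
5hm6aU,337.7,1.87,0.63,hm,False
5dhmC,322.1,364.23,5.90,dhm,True
5dhm6aU,313.8,0.24,-1.43,dhm,False
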