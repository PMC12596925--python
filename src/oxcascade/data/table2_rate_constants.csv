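base,cascade,step,measurement,k,dk
5hmU,5hm->5f->5ca,1,direct,0.66,0.02
5fU,5hm->5f->5ca,2,indirect,0.43,0.01
5fU,5f->5ca,1,direct,0.48,0.01
5hmC,5hm->5f->5ca,1,direct,0.51,0.01
5fC,5hm->5f->5ca,2,indirect,0.53,0.03
5hm6aU,5hm->5f/5dhm->5ca,1,direct,1.87,0.06
5f6aU,5hm->5f/5dhm->5ca,2,indirect,2.86,0.26
5dhm6aU,5hm->5f/5dhm->5ca,2,indirect,0.24,0.01
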