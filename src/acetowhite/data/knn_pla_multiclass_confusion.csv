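actual,atrophy,inflammation,ectopy,normal,LSIL,HSIL
atrophy,0,0,0,14,0,1
inflammation,0,0,0,13,1,10
ectopy,0,0,0,12,0,8
normal,0,0,0,44,0,4
LSIL,0,0,0,22,0,15
HSIL,0,0,0,16,0,40
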