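SUBST_MOD: REV
BACKGROUND: 0.295000 0.205000 0.205000 0.295000
RATE_MAT:
  -0.864524  0.141190  0.578208  0.145126
   0.203176 -1.204628  0.121020  0.880431
   0.832056  0.121020 -1.146577  0.193501
   0.145126  0.611825  0.134467 -0.891418
TREE: ((((((human:0.0068,chimp:0.0073)hc:0.0026,orangutan:0.0183)hco:0.009,gibbon:0.022)apes:0.01,(((baboon:0.0085,macaque:0.007)bm:0.004,vervet:0.0125)bmv:0.0055,colobus:0.013)owm:0.014)catarrhini:0.022,((dusky_titi:0.03,owl_monkey:0.027)to:0.005,(marmoset:0.033,squirrel_monkey:0.03)ms:0.006)nwm:0.029)simians:0.06,(mouse_lemur:0.097,galago:0.126)prosimians:0.077)primates;
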