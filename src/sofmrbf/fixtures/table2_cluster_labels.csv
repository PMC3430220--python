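basis,training_steps,dH_homo,Q_Y,Q_N,Q_O,N_X,mu,alpha,E_HOMO-1,E_HOMO,E_LUMO,E_LUMO+1,dE
6-31G(d),10,24,1,1,1,24,4,24,1,1,1,1,1
6-31G(d),30,5,13,13,13,24,19,24,13,13,13,13,13
6-31G(d),50,4,12,6,12,1,21,1,12,12,12,12,12
6-31G(d),100,19,12,10,12,3,22,1,12,12,11,11,10
6-31G(d),200,16,1,8,1,11,19,24,1,1,2,2,8
6-31G(d),500,16,13,1,19,12,8,24,19,19,20,20,1
6-31G(d),1000,16,13,20,13,23,2,24,13,13,14,14,20
STO-3G,10,2,1,1,1,24,1,24,1,1,1,1,1
STO-3G,30,23,1,7,1,24,5,24,1,1,1,2,7
STO-3G,50,21,1,1,1,6,13,12,1,1,1,1,1
STO-3G,100,21,7,19,7,24,3,12,7,7,14,19,19
STO-3G,200,5,7,19,1,24,3,22,1,1,13,14,15
STO-3G,500,4,16,19,21,24,8,12,21,21,20,19,13
STO-3G,1000,10,13,15,19,24,2,12,19,19,20,15,21
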