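name,smarts,atom,charge,h_delta
carboxylic_acid,[CX3](=[OX1])[OX2H1],2,-1,-1
sulfonic_acid,[SX4](=[OX1])(=[OX1])[OX2H1],3,-1,-1
sulfinic_acid,[SX3](=[OX1])[OX2H1],2,-1,-1
phosphorus_oxyacid_oh,[PX4](=[OX1])[OX2H1],2,-1,-1
tetrazole_nh,[#7;H1;+0]1:[#7]:[#7]:[#7]:[#6]:1,0,-1,-1
amidinium_imine_n,[NX2;+0;$([NX2]=[CX3][NX3;+0])],0,1,1
aliphatic_amine,[NX3;+0;!$(N=*);!$(N-[a]);!$(N-[CX3]=[O;X1]);!$(N-[CX3]=[#7]);!$(N-[CX3]=[SX1]);!$(N-[SX4](=O)=O);!$(N-[NX2]=O);!$(N#*);!$(N-O)],0,1,1
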