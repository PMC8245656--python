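subset,abs,coherence_z,coherence_p,coherence_sim_mean,coherence_sim_sd,rep,turnover_z,turnover_p,turnover_sim_mean,turnover_sim_sd,morisita_index,boundary_p,df,structure
PD,1317,11.7,0.001,1561,21,32361,-1.8,0.08,21652,6050,2.4,0.001,65,Quasi-Clementsian
CP,1004,12.2,0.001,1382,31,59527,-5.4,0.001,24895,6440,2.5,0.001,64,Clementsian
UM,1209,13.3,0.001,1661,34,63792,-4,0.001,32923,7817,2.2,0.001,65,Clementsian
CC,940,11.8,0.001,1348,35,37806,-2.2,0.028,25007,5819,2.2,0.001,63,Clementsian
SY,1032,14.7,0.001,1464,29,58632,-2.9,0.004,34452,8345,3,0.001,65,Clementsian
HC,1169,9.8,0.001,1524,36,46457,-4.3,0.001,22428,5596,2.1,0.001,65,Clementsian
All,11336,39,0.001,15589,109,1995007,-5.5,0.001,895529,198657,9.5,0.001,402,Clementsian
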