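solute_id,solvent_id,solvent_fraction,T,x,s,sd_x,source
DAP,4FM,1.0,298.15,0.004311,0.042,0.000025,this_work
DAP,4FM,1.0,303.15,0.007390,0.074,0.000418,this_work
DAP,4FM,1.0,308.15,0.012557,0.126,0.000089,this_work
DAP,4FM,1.0,313.15,0.019148,0.191,0.000055,this_work
DAP,DMSO,1.0,298.15,0.018757,0.256,0.000702,this_work
DAP,DMSO,1.0,303.15,0.025158,0.344,0.000154,this_work
DAP,DMSO,1.0,308.15,0.034288,0.462,0.000924,this_work
DAP,DMSO,1.0,313.15,0.044427,0.598,0.000920,this_work
DAP,TEPA,1.0,298.15,0.010569,0.056,0.000223,this_work
DAP,TEPA,1.0,303.15,0.014990,0.079,0.000400,this_work
DAP,TEPA,1.0,308.15,0.019654,0.104,0.000047,this_work
DAP,TEPA,1.0,313.15,0.026229,0.141,0.000427,this_work
DAP,NMP,1.0,298.15,0.010513,0.108,0.000320,this_work
DAP,NMP,1.0,303.15,0.023659,0.243,0.000516,this_work
DAP,NMP,1.0,308.15,0.052474,0.525,0.001019,this_work
DAP,NMP,1.0,313.15,0.111363,1.040,0.001753,this_work
DAP,B3APE,1.0,298.15,0.014751,0.068,0.000143,this_work
DAP,B3APE,1.0,303.15,0.023114,0.109,0.002269,this_work
DAP,B3APE,1.0,308.15,0.029760,0.142,0.000448,this_work
DAP,B3APE,1.0,313.15,0.039751,0.191,0.000606,this_work
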