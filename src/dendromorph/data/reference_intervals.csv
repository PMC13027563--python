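# dendromorph built-in reference intervals, v1
# Per-taxon mean/SD/min/max of the male genitalia indices of Dendrolimus
# sibiricus (n=33), D. pini (n=33) and their F1 hybrids (n=4).
index,variant,taxon,mean,sd,min,max,n
hl_vl,na,sibiricus,0.656,0.069,0.484,0.847,33
hl_vl,na,hybrid,0.378,0.085,0.317,0.503,4
hl_vl,na,pini,0.251,0.038,0.149,0.316,33
cl_al,straight,sibiricus,0.051,0.012,0.029,0.077,33
cl_al,straight,hybrid,0.078,0.004,0.073,0.085,4
cl_al,straight,pini,0.092,0.013,0.077,0.128,33
cl_al,arc,sibiricus,0.039,0.009,0.022,0.059,33
cl_al,arc,hybrid,0.062,0.005,0.058,0.069,4
cl_al,arc,pini,0.074,0.010,0.060,0.102,33
cgpi,straight,sibiricus,0.852,0.081,0.677,1.031,33
cgpi,straight,hybrid,0.621,0.048,0.568,0.664,4
cgpi,straight,pini,0.586,0.065,0.453,0.736,33
cgpi,arc,sibiricus,0.662,0.068,0.522,0.808,33
cgpi,arc,hybrid,0.499,0.033,0.452,0.531,4
cgpi,arc,pini,0.480,0.054,0.381,0.617,33
aw_al,arc,sibiricus,0.165,0.018,0.120,0.210,33
aw_al,arc,hybrid,0.148,0.021,0.125,0.174,4
aw_al,arc,pini,0.177,0.019,0.138,0.218,33
aw_al,straight,sibiricus,0.215,0.022,0.168,0.280,33
aw_al,straight,hybrid,0.186,0.017,0.167,0.205,4
aw_al,straight,pini,0.218,0.026,0.159,0.263,33
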