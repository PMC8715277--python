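# Extra Lennard-Jones well depths for cation-pi pairs (arginine/lysine against
# aromatics), layered on top of the hydropathy-scale model.
# Columns: res_i  res_j  epsilon[kJ/mol]
R	F	12.552
R	W	12.552
R	Y	12.552
K	F	12.552
K	W	12.552
K	Y	12.552
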