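element	monoisotopic_mass
C	12.000000
H	1.0078250
N	14.0030740
O	15.9949146
S	31.9720707
F	18.9984032
Cl	34.9688527
P	30.9737615
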