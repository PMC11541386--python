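parent_id	polarity	ions
atenolol	positive	267.1703 250.1438 249.1597 225.1234 208.0968 190.0863 178.0863 134.0600 116.1070 98.0964 74.0600 72.0808
sulfamethoxazole	positive	254.0594 156.0114 108.04439 92.0495
sulfamethoxazole	negative	252.0448 156.0125 92.0506
ketoprofen	positive	255.1016 209.0961 105.0335
ketoprofen	negative	253.0870 209.0972
enrofloxacin	positive	360.1718 342.1612 316.1820 245.1085 231.0928
tetracycline	positive	445.1606 428.1340 410.1234
tetracycline	negative	443.1460 426.1194 273.0768 271.0612
erythromycin	positive	734.4685 716.4579 576.3742 558.3636 540.3531 158.1176
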