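id	name	formula	smiles	drug_class	rt_min
atenolol	Atenolol	C14H22N2O3	CC(C)NCC(O)COc1ccc(CC(N)=O)cc1	beta blocker	2.94
enrofloxacin	Enrofloxacin	C19H22FN3O3	CCN1CCN(CC1)c1cc2c(cc1F)c(=O)c(cn2C1CC1)C(=O)O	fluoroquinolone antibiotic	4.80
erythromycin	Erythromycin	C37H67NO13		macrolide antibiotic	7.90
ketoprofen	Ketoprofen	C16H14O3	CC(c1cccc(c1)C(=O)c1ccccc1)C(=O)O	NSAID	8.50
sulfamethoxazole	Sulfamethoxazole	C10H11N3O3S	Cc1cc(NS(=O)(=O)c2ccc(N)cc2)no1	sulfonamide antibiotic	5.15
tetracycline	Tetracycline	C22H24N2O8		tetracycline antibiotic	5.60
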