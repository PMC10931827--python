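panel_name	gene_id
vesicular_transporters	Slc17a7
vesicular_transporters	Slc32a1
glycine_neurofilament	Glra1
glycine_neurofilament	Slc6a5
glycine_neurofilament	Slc6a9
glycine_neurofilament	Nefh
neurofilament	Nefl
neurofilament	Nefh
neurofilament	Nefm
phosphodiesterase	Pde10a
phosphodiesterase	Pde1b
phosphodiesterase	Pde2a
phosphodiesterase	Pde7b
tca_cycle	Aco2
tca_cycle	Mdh1
tca_cycle	Mdh2
tca_cycle	Sdha
tca_cycle	Idh3b
mitophagy_core	Prkcd
mitophagy_core	Pink1
mitophagy_core	Park2
mitophagy_core	Gak
myelin_seed	Mbp
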