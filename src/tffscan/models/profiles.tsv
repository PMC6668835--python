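profile_name	role	source_model
T4P_pilA	major_pilin	T4aP
T4P_pilB	atpase	T4aP
T4P_pilC	im_platform	T4aP
T4P_pilD	prepilin_peptidase	T4aP
T4P_pilE	minor_pilin	T4aP
T4P_fimT	minor_pilin	T4aP
T4P_pilM	assembly	T4aP
T4P_pilN	assembly	T4aP
T4P_pilO	assembly	T4aP
T4P_pilP	assembly	T4aP
T4P_pilQ	secretin	T4aP
T4P_pilT	atpase	T4aP
T4P_pilU	atpase	T4aP
T4P_pilV	minor_pilin	T4aP
T4P_pilW	minor_pilin	T4aP
T4P_pilX	minor_pilin	T4aP
T4P_pilY	other	T4aP
T2SS_gspC	other	T2SS
T2SS_gspD	secretin	T2SS
T2SS_gspE	atpase	T2SS
T2SS_gspF	im_platform	T2SS
T2SS_gspG	major_pilin	T2SS
T2SS_gspH	minor_pilin	T2SS
T2SS_gspI	minor_pilin	T2SS
T2SS_gspJ	minor_pilin	T2SS
T2SS_gspK	minor_pilin	T2SS
T2SS_gspL	assembly	T2SS
T2SS_gspM	assembly	T2SS
T2SS_gspN	other	T2SS
T2SS_gspO	prepilin_peptidase	T2SS
Tad_tadA	atpase	Tad
Tad_tadB	im_platform	Tad
Tad_tadC	im_platform	Tad
Tad_tadZ	atpase	Tad
Tad_flp	major_pilin	Tad
Tad_tadE	minor_pilin	Tad
Tad_tadF	minor_pilin	Tad
Tad_tadG	minor_pilin	Tad
Tad_rcpA	secretin	Tad
Tad_rcpB	other	Tad
Tad_rcpC	other	Tad
Tad_tadD	other	Tad
Tad_tadV	prepilin_peptidase	Tad
ComM_comGA	atpase	ComM
ComM_comGB	im_platform	ComM
ComM_comGC	major_pilin	ComM
ComM_comGD	minor_pilin	ComM
ComM_comGE	minor_pilin	ComM
ComM_comGF	minor_pilin	ComM
ComM_comGG	minor_pilin	ComM
ComM_comC	prepilin_peptidase	ComM
ComM_comEA	other	ComM
ComM_comEB	other	ComM
ComM_comEC	other	ComM
ComM_comB	other	ComM
ComM_comK	other	ComM
ComM_comX	other	ComM
Arch_flaI	atpase	Archaeal
Arch_flaJ	im_platform	Archaeal
Arch_flaB	major_pilin	Archaeal
Arch_pibD	prepilin_peptidase	Archaeal
Arch_flaC	other	Archaeal
Arch_flaD	other	Archaeal
Arch_flaF	other	Archaeal
Arch_flaG	other	Archaeal
Arch_flaH	other	Archaeal
T4bP_pilB	atpase	T4bP
T4bP_pilC	im_platform	T4bP
T4bP_pilA	major_pilin	T4bP
T4bP_pilD	prepilin_peptidase	T4bP
T4bP_pilQ	secretin	T4bP
T4bP_pilM	assembly	T4bP
T4bP_pilN	assembly	T4bP
T4bP_pilO	assembly	T4bP
MSH_mshA	major_pilin	MSH
MSH_mshB	minor_pilin	MSH
MSH_mshC	minor_pilin	MSH
MSH_mshD	minor_pilin	MSH
MSH_mshE	atpase	MSH
MSH_mshG	im_platform	MSH
MSH_mshL	secretin	MSH
MSH_mshM	atpase	MSH
MSH_mshN	other	MSH
MSH_mshO	minor_pilin	MSH
MSH_mshP	minor_pilin	MSH
MSH_mshQ	minor_pilin	MSH
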