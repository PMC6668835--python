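# Final (relaxed) system models of the TFF superfamily.
# Quorum values stated in the study are used verbatim: T4aP 4/5, T2SS 4/5,
# ComM 4/4 (inter-gene distance 5), Archaeal 3/3, T4bP 4/4, MSH 3/4.
# Component rosters follow the per-system gene lists; statuses mark how
# reliably a gene is found near its system, not biological importance.
models:
- name: T4aP
  inter_gene_max_space: 5
  mmgr: 4
  mgr: 5
  multi_loci: true
  components:
  - {name: T4P_pilB, status: mandatory}
  - {name: T4P_pilT, status: mandatory}
  - {name: T4P_pilC, status: mandatory}
  - {name: T4P_pilQ, status: mandatory}
  - {name: T4P_pilE, status: mandatory}
  - {name: T4P_pilN, status: mandatory}
  - {name: T4P_pilO, status: mandatory}
  - {name: T4P_pilD, status: mandatory, loner: true,
     exchangeable_with: [T2SS_gspO, ComM_comC]}
  - {name: T4P_pilA, status: accessory}
  - {name: T4P_fimT, status: accessory}
  - {name: T4P_pilM, status: accessory}
  - {name: T4P_pilP, status: accessory}
  - {name: T4P_pilU, status: accessory}
  - {name: T4P_pilV, status: accessory}
  - {name: T4P_pilW, status: accessory}
  - {name: T4P_pilX, status: accessory}
  - {name: T4P_pilY, status: accessory}
- name: T2SS
  inter_gene_max_space: 5
  mmgr: 4
  mgr: 5
  multi_loci: false
  components:
  - {name: T2SS_gspC, status: mandatory}
  - {name: T2SS_gspD, status: mandatory, loner: true}
  - {name: T2SS_gspE, status: mandatory}
  - {name: T2SS_gspF, status: mandatory}
  - {name: T2SS_gspG, status: mandatory}
  - {name: T2SS_gspO, status: mandatory, loner: true,
     exchangeable_with: [T4P_pilD, ComM_comC]}
  - {name: T2SS_gspH, status: accessory}
  - {name: T2SS_gspI, status: accessory}
  - {name: T2SS_gspJ, status: accessory}
  - {name: T2SS_gspK, status: accessory}
  - {name: T2SS_gspL, status: accessory}
  - {name: T2SS_gspM, status: accessory}
  - {name: T2SS_gspN, status: accessory}
- name: Tad
  inter_gene_max_space: 5
  mmgr: 4
  mgr: 6
  multi_loci: true
  components:
  - {name: Tad_tadA, status: mandatory}
  - {name: Tad_tadB, status: mandatory}
  - {name: Tad_tadC, status: mandatory}
  - {name: Tad_tadZ, status: mandatory}
  - {name: Tad_flp, status: mandatory}
  - {name: Tad_rcpA, status: mandatory}
  - {name: Tad_tadV, status: mandatory, loner: true}
  - {name: Tad_tadD, status: accessory}
  - {name: Tad_rcpB, status: accessory}
  - {name: Tad_rcpC, status: accessory}
  - {name: Tad_tadE, status: accessory}
  - {name: Tad_tadF, status: accessory}
  - {name: Tad_tadG, status: accessory}
- name: ComM
  inter_gene_max_space: 5
  mmgr: 4
  mgr: 4
  multi_loci: true
  components:
  - {name: ComM_comGA, status: mandatory, exchangeable_with: [T4P_pilB]}
  - {name: ComM_comGB, status: mandatory}
  - {name: ComM_comGC, status: mandatory}
  - {name: ComM_comC, status: mandatory, loner: true,
     exchangeable_with: [T4P_pilD]}
  - {name: ComM_comEC, status: mandatory, loner: true}
  - {name: ComM_comGD, status: accessory}
  - {name: ComM_comGE, status: accessory}
  - {name: ComM_comGF, status: accessory}
  - {name: ComM_comGG, status: accessory}
  - {name: ComM_comEA, status: accessory}
  - {name: ComM_comEB, status: accessory, loner: true}
  - {name: ComM_comB, status: accessory, loner: true}
  - {name: ComM_comK, status: accessory, loner: true}
  - {name: ComM_comX, status: accessory, loner: true}
- name: Archaeal
  inter_gene_max_space: 5
  mmgr: 3
  mgr: 3
  multi_loci: true
  components:
  - {name: Arch_flaI, status: mandatory}
  - {name: Arch_flaJ, status: mandatory}
  - {name: Arch_flaB, status: mandatory}
  - {name: Arch_pibD, status: mandatory, loner: true}
  - {name: Arch_flaC, status: accessory}
  - {name: Arch_flaD, status: accessory}
  - {name: Arch_flaF, status: accessory}
  - {name: Arch_flaG, status: accessory}
  - {name: Arch_flaH, status: accessory}
- name: T4bP
  inter_gene_max_space: 5
  mmgr: 4
  mgr: 4
  multi_loci: true
  components:
  - {name: T4bP_pilB, status: mandatory}
  - {name: T4bP_pilC, status: mandatory}
  - {name: T4bP_pilA, status: mandatory, exchangeable_with: [T4P_pilA]}
  - {name: T4bP_pilQ, status: mandatory}
  - {name: T4bP_pilD, status: mandatory, loner: true}
  - {name: T4bP_pilM, status: accessory}
  - {name: T4bP_pilN, status: accessory}
  - {name: T4bP_pilO, status: accessory}
- name: MSH
  inter_gene_max_space: 5
  mmgr: 3
  mgr: 4
  multi_loci: true
  components:
  - {name: MSH_mshA, status: mandatory, loner: true}
  - {name: MSH_mshE, status: mandatory}
  - {name: MSH_mshG, status: mandatory}
  - {name: MSH_mshL, status: mandatory}
  - {name: MSH_mshM, status: mandatory}
  - {name: MSH_mshB, status: accessory, exchangeable_with: [T4bP_pilA]}
  - {name: MSH_mshC, status: accessory, exchangeable_with: [T4P_fimT]}
  - {name: MSH_mshD, status: accessory}
  - {name: MSH_mshN, status: accessory}
  - {name: MSH_mshO, status: accessory}
  - {name: MSH_mshP, status: accessory}
  - {name: MSH_mshQ, status: accessory}
- name: generic
  inter_gene_max_space: 5
  mmgr: 3
  mgr: 3
  multi_loci: false
  components:
  - {name: atpase, status: mandatory}
  - {name: im_platform, status: mandatory}
  - {name: major_pilin, status: mandatory}
  - {name: secretin, status: accessory}
  - {name: prepilin_peptidase, status: accessory}
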