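# Initial (conservative) system models. These match archetypal systems and
# are deliberately strict: T4aP 8/8 with forbidden discriminator genes,
# T2SS MGR 8, ComM 3/5 with inter-gene distance 5, Archaeal 4/4.
# T4bP and MSH have no initial model (too few described systems).
models:
- name: T4aP
  inter_gene_max_space: 5
  mmgr: 8
  mgr: 8
  multi_loci: false
  components:
  - {name: T4P_pilB, status: mandatory}
  - {name: T4P_pilT, status: mandatory}
  - {name: T4P_pilC, status: mandatory}
  - {name: T4P_pilQ, status: mandatory}
  - {name: T4P_pilA, status: mandatory}
  - {name: T4P_pilE, status: mandatory}
  - {name: T4P_fimT, status: mandatory}
  - {name: T4P_pilM, status: mandatory}
  - {name: T4P_pilN, status: mandatory}
  - {name: T4P_pilO, status: mandatory}
  - {name: T4P_pilP, status: mandatory}
  - {name: T4P_pilD, status: mandatory, loner: true,
     exchangeable_with: [T2SS_gspO, ComM_comC]}
  - {name: T4P_pilU, status: accessory}
  - {name: T4P_pilV, status: accessory}
  - {name: T4P_pilX, status: accessory}
  - {name: T2SS_gspN, status: forbidden}
  - {name: Tad_tadZ, status: forbidden}
  - {name: T2SS_gspC, status: forbidden}
- name: T2SS
  inter_gene_max_space: 5
  mmgr: 4
  mgr: 8
  multi_loci: false
  components:
  - {name: T2SS_gspD, status: mandatory}
  - {name: T2SS_gspE, status: mandatory}
  - {name: T2SS_gspF, status: mandatory}
  - {name: T2SS_gspG, status: mandatory}
  - {name: T2SS_gspO, status: mandatory, loner: true,
     exchangeable_with: [T4P_pilD]}
  - {name: T2SS_gspC, status: accessory}
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
  multi_loci: false
  components:
  - {name: Tad_tadA, status: mandatory}
  - {name: Tad_tadB, status: mandatory}
  - {name: Tad_tadC, status: mandatory}
  - {name: Tad_tadZ, status: mandatory}
  - {name: Tad_flp, status: mandatory}
  - {name: Tad_rcpA, status: mandatory}
  - {name: Tad_tadV, status: mandatory, loner: true,
     exchangeable_with: [T4P_pilD, ComM_comC]}
  - {name: Tad_tadE, status: accessory}
  - {name: Tad_tadF, status: accessory}
  - {name: Tad_tadG, status: accessory}
- name: ComM
  inter_gene_max_space: 5
  mmgr: 3
  mgr: 5
  multi_loci: true
  components:
  - {name: ComM_comC, status: mandatory, loner: true,
     exchangeable_with: [T4P_pilD]}
  - {name: ComM_comGA, status: mandatory, exchangeable_with: [T4P_pilB]}
  - {name: ComM_comGB, status: mandatory}
  - {name: ComM_comGC, status: mandatory}
  - {name: ComM_comGD, status: mandatory}
  - {name: ComM_comGE, status: accessory}
  - {name: ComM_comGF, status: accessory}
  - {name: ComM_comGG, status: accessory}
  - {name: ComM_comB, status: accessory, loner: true}
  - {name: ComM_comK, status: accessory, loner: true}
  - {name: ComM_comX, status: accessory, loner: true}
- name: Archaeal
  inter_gene_max_space: 5
  mmgr: 4
  mgr: 4
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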