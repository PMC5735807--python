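name,value,units,provenance,tags,note
kon_tsp1_cd36,5.217391304347826e-2,1/(uM*min),paper,binding,koff/Kd = 1.2e-2/0.23
koff_u,1.2e-2,1/min,paper,binding,universal dissociation rate
kon_cd36_fyn,30.0,1/(uM*min),reconstructed,binding,
k_phos_fyn,5.0,1/min,reconstructed,phosphorylation,p59fyn activation (Kp target)
k_int,1e-2,1/min,reconstructed,transport,ligated-receptor internalization
k_rec,1e-2,1/min,reconstructed,transport,receptor re-insertion
k_deg_TSP1,8e-3,1/min,fitted,degradation,TSP1 decay
kon_fyn_p38,50.0,1/(uM*min),reconstructed,binding,
k_phos_p38,2.0,1/min,reconstructed,phosphorylation,p38MAPK phosphorylation (Kp target)
kon_dephos_fyn,0.05,1/(uM*min),reconstructed,binding,
k_dephos_fyn,0.2,1/min,reconstructed,dephosphorylation,
K_on_dephos,0.8,1/(uM*min),reconstructed,binding,phosphatase association with pp38 (Ptase target)
K_dephos,0.3,1/min,reconstructed,dephosphorylation,pp38 dephosphorylation (Ptase target)
K_on_dephos_n,0.8,1/(uM*min),reconstructed,binding,nuclear phosphatase association with pp38
K_dephos_n,0.3,1/min,reconstructed,dephosphorylation,nuclear pp38 dephosphorylation
K_trsp,1e-2,1/min,reconstructed,transport,cytosol-to-nucleus translocation
kon_p38_nfkb,50.0,1/(uM*min),reconstructed,binding,
k_phos_nfkb,1.0,1/min,reconstructed,,NF-kB activation by pp38 (p38-inhibition target)
kon_nfkb_ikb,50.0,1/(uM*min),reconstructed,binding,
kon_ikk_nfkbikb,5.0,1/(uM*min),reconstructed,binding,
k_phos_ikb,0.5,1/min,reconstructed,phosphorylation,IkB phosphorylation (Kp target)
k_inact_ikk,1e-2,1/min,reconstructed,,
k_recyc_ikk,2e-3,1/min,reconstructed,,
Vmax_FasL,2e-5,uM/min,fitted,,FasL transcription Vmax
Km_FasL,5e-3,uM,fitted,,FasL transcription Km
k_exp_mrna,5e-2,1/min,fitted,transport,mRNA export
k_transl,0.1,1/min,fitted,,translation rate per mRNA
k_deg_mrna,2e-2,1/min,fitted,degradation,
kon_fasl_fas,30.0,1/(uM*min),paper,binding,koff/Kd = 1.2e-2/4e-4
kon_fas_fadd,10.0,1/(uM*min),reconstructed,binding,
kon_disc_pro8,2.0,1/(uM*min),reconstructed,binding,
k_act8_disc,0.3,1/(uM*min),reconstructed,,caspase-8 activation at DISC
kon_disc_fl,1.0,1/(uM*min),reconstructed,binding,
k_p43,0.1,1/min,reconstructed,,p43-FLIP formation
kon_disc_fl2,0.2,1/(uM*min),reconstructed,binding,
kon_p43_ikk,5.0,1/(uM*min),reconstructed,binding,
k_act_ikk,0.5,1/min,reconstructed,,
kon_c8_pro3,2.0,1/(uM*min),reconstructed,binding,
k_act3,5.5e-2,1/min,reconstructed,,caspase-3 activation
kon_c3_pro8,5e-2,1/(uM*min),reconstructed,binding,
k_act8_fb,5e-3,1/min,reconstructed,,feedback caspase-8 activation
kon_pp38_pro8,0.3,1/(uM*min),reconstructed,binding,direct arm
k_act8_p38,6e-2,1/min,reconstructed,,
kon_c3_xiap,30.0,1/(uM*min),reconstructed,binding,tight XIAP binding
k_deg_c3x,5e-2,1/min,reconstructed,degradation,XIAP-mediated caspase-3 removal
kon_c3_parp,0.55,1/(uM*min),reconstructed,binding,
k_cleave_parp,0.5,1/min,reconstructed,,PARP cleavage
Ksyn_all,1e-4,uM/min,paper,synthesis,basal synthesis rate
F_syn,5e-2,1/min,paper,synthesis,DISC-dependent procaspase synthesis coefficient
k_deg_default,1e-3,1/min,paper,degradation,default degradation rate
k_deg_pFyn,5e-2,1/min,reconstructed,degradation,activated p59fyn deactivation/turnover
k_deg_MKP,2e-3,1/min,reconstructed,degradation,balances Ksyn_all at 0.05 uM
k_deg_casp8,6e-3,1/min,reconstructed,degradation,
k_deg_pro3,1.25e-4,1/min,reconstructed,degradation,balances Ksyn_all at 0.8 uM
k_deg_pro8,3.3333333333333335e-4,1/min,reconstructed,degradation,balances Ksyn_all at 0.3 uM
k_deg_casp3,5e-2,1/min,reconstructed,degradation,
k_deg_cPARP,0.0,1/min,reconstructed,degradation,cleaved PARP treated as a terminal readout
k_deg_NFkB,5e-3,1/min,reconstructed,degradation,
k_deg_IkB,2e-3,1/min,reconstructed,degradation,balances Ksyn_all at 0.05 uM
k_deg_NFkB_IkB,0.0,1/min,reconstructed,degradation,resting pool held constant
k_deg_pIkB,0.1,1/min,reconstructed,degradation,
k_deg_NFkB_n,0.0,1/min,reconstructed,degradation,resting nuclear pool held constant
k_deg_NFkBp,1e-2,1/min,reconstructed,degradation,active NF-kB turnover
k_deg_FasL,2e-2,1/min,fitted,degradation,
k_deg_FADD,2e-3,1/min,reconstructed,degradation,balances Ksyn_all at 0.05 uM
k_deg_FL,2e-3,1/min,reconstructed,degradation,balances Ksyn_all at 0.05 uM
k_deg_p43IKK,5e-3,1/min,reconstructed,degradation,
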