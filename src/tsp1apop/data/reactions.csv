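id,reactants,products,modifiers,rate_law_kind,parameters,provenance,note
r01,TSP1;CD36,TSP1_CD36,,mass_action_rev,kon_tsp1_cd36;koff_u,paper,Kd 230 nM with koff 1.2e-2
r02,TSP1_CD36;Fyn,TSP1_CD36_Fyn,,mass_action_rev,kon_cd36_fyn;koff_u,reconstructed,p59fyn recruitment
r03,TSP1_CD36_Fyn,TSP1_CD36;pFyn,,mass_action_irrev,k_phos_fyn,reconstructed,p59fyn activation
r04,TSP1_CD36,CD36_i,,mass_action_irrev,k_int,reconstructed,ligated-receptor internalization (TSP1 degraded)
r05,CD36_i,CD36,,mass_action_irrev,k_rec,reconstructed,receptor re-insertion
r06,pFyn;p38,pFyn_p38,,mass_action_rev,kon_fyn_p38;koff_u,reconstructed,
r07,pFyn_p38,pFyn;pp38,,mass_action_irrev,k_phos_p38,reconstructed,p38MAPK phosphorylation
r08,pFyn;MKP,MKP_pFyn,,mass_action_rev,kon_dephos_fyn;koff_u,reconstructed,
r09,MKP_pFyn,MKP;Fyn,,mass_action_irrev,k_dephos_fyn,reconstructed,p59fyn deactivation
r10,pp38;MKP,MKP_pp38,,mass_action_rev,K_on_dephos;koff_u,reconstructed,phosphatase binds pp38
r11,MKP_pp38,MKP,,mass_action_irrev,K_dephos,reconstructed,phosphatase-mediated pp38 removal
r12,pp38,pp38_n,,transport,K_trsp,reconstructed,nuclear import of pp38
r13,pp38_n;MKP_n,MKP_pp38_n,,mass_action_rev,K_on_dephos_n;koff_u,reconstructed,nuclear phosphatase binds pp38
r14,MKP_pp38_n,MKP_n,,mass_action_irrev,K_dephos_n,reconstructed,nuclear phosphatase-mediated pp38 removal
r15,NFkB,NFkB_n,,transport,K_trsp,reconstructed,nuclear import of free NF-kB
r16,NFkB_n;pp38_n,pp38_NFkB_n,,mass_action_rev,kon_p38_nfkb;koff_u,reconstructed,
r17,pp38_NFkB_n,pp38_n;NFkB_p,,mass_action_irrev,k_phos_nfkb,reconstructed,NF-kB activation by pp38 (zeroed in p38-inhibition)
r18,NFkB;IkB,NFkB_IkB,,mass_action_irrev,kon_nfkb_ikb,reconstructed,IkB re-capture of released NF-kB
r19,IKKa;NFkB_IkB,IKKa_NFkB_IkB,,mass_action_rev,kon_ikk_nfkbikb;koff_u,reconstructed,
r20,IKKa_NFkB_IkB,IKKa;NFkB;pIkB,,mass_action_irrev,k_phos_ikb,reconstructed,IkB phosphorylation releases NF-kB
r21,IKKa,IKKi,,mass_action_irrev,k_inact_ikk,reconstructed,IKK spending
r22,IKKi,IKK,,mass_action_irrev,k_recyc_ikk,reconstructed,IKK recycling
r23,,FasL_mRNA,NFkB_p,michaelis_menten,Vmax_FasL;Km_FasL,paper,FasL transcription V=Vmax*NFkB_p/(Km+NFkB_p)
r24,FasL_mRNA,FasL_mRNA_c,,transport,k_exp_mrna,reconstructed,mRNA export
r25,FasL_mRNA_c,FasL_mRNA_c;FasL,,mass_action_irrev,k_transl,reconstructed,translation (catalytic in mRNA)
r26,FasL;Fas,FasL_Fas,,mass_action_rev,kon_fasl_fas;koff_u,paper,Kd 0.4 nM with koff 1.2e-2
r27,FasL_Fas;FADD,DISC,,mass_action_rev,kon_fas_fadd;koff_u,reconstructed,DISC assembly
r28,FasL_Fas,Fas_i,,mass_action_irrev,k_int,reconstructed,ligated-receptor internalization (FasL degraded)
r29,Fas_i,Fas,,mass_action_irrev,k_rec,reconstructed,receptor re-insertion
r29b,DISC,Fas_i,,mass_action_irrev,k_int,reconstructed,internalization of the assembled DISC (FasL and FADD degraded; Fas recycled)
r29c,DISC_pro8,Fas_i,,mass_action_irrev,k_int,reconstructed,internalization of DISC with bound procaspase-8
r29d,DISC_FL,Fas_i,,mass_action_irrev,k_int,reconstructed,internalization of FLIP-blocked DISC
r30,DISC;pro8,DISC_pro8,,mass_action_rev,kon_disc_pro8;koff_u,reconstructed,
r31,DISC_pro8;pro8,DISC;casp8,,mass_action_irrev,k_act8_disc,reconstructed,caspase-8 activation at DISC
r32,DISC_pro8;FL,DISC_FL_pro8,,mass_action_rev,kon_disc_fl;koff_u,reconstructed,
r33,DISC_FL_pro8,DISC;p43FLIP,,mass_action_irrev,k_p43,reconstructed,p43-FLIP formation
r34,DISC;FL,DISC_FL,,mass_action_rev,kon_disc_fl2;koff_u,reconstructed,FLIP-blocked DISC
r35,p43FLIP;IKK,p43FLIP_IKK,,mass_action_rev,kon_p43_ikk;koff_u,reconstructed,
r36,p43FLIP_IKK,p43FLIP;IKKa,,mass_action_irrev,k_act_ikk,reconstructed,IKK activation by p43-FLIP
r37,casp8;pro3,casp8_pro3,,mass_action_rev,kon_c8_pro3;koff_u,reconstructed,
r38,casp8_pro3,casp8;casp3,,mass_action_irrev,k_act3,reconstructed,caspase-3 activation
r39,casp3;pro8,casp3_pro8,,mass_action_rev,kon_c3_pro8;koff_u,reconstructed,
r40,casp3_pro8,casp3;casp8,,mass_action_irrev,k_act8_fb,reconstructed,caspase-3 -> caspase-8 feedback
r41,pp38;pro8,pp38_pro8,,mass_action_rev,kon_pp38_pro8;koff_u,reconstructed,direct arm of the caspase cascade
r42,pp38_pro8,pp38;casp8,,mass_action_irrev,k_act8_p38,reconstructed,
r43,casp3;XIAP,casp3_XIAP,,mass_action_rev,kon_c3_xiap;koff_u,reconstructed,XIAP inhibition of caspase-3
r44,casp3_XIAP,,,mass_action_irrev,k_deg_c3x,reconstructed,co-degradation of XIAP-bound caspase-3
r45,casp3;PARP,casp3_PARP,,mass_action_rev,kon_c3_parp;koff_u,reconstructed,
r46,casp3_PARP,casp3;cPARP,,mass_action_irrev,k_cleave_parp,reconstructed,PARP cleavage
syn_MKP,,MKP,,synthesis_basal,Ksyn_all,paper,
syn_MKP_n,,MKP_n,,synthesis_basal,Ksyn_all,paper,
syn_IkB,,IkB,,synthesis_basal,Ksyn_all,paper,
syn_IKK,,IKK,,synthesis_basal,Ksyn_all,paper,
syn_FADD,,FADD,,synthesis_basal,Ksyn_all,paper,
syn_FL,,FL,,synthesis_basal,Ksyn_all,paper,
syn_pro8,,pro8,DISC,synthesis_disc_dependent,F_syn;Ksyn_all,paper,V = F*DISC + Ksyn_all
syn_pro3,,pro3,DISC,synthesis_disc_dependent,F_syn;Ksyn_all,paper,V = F*DISC + Ksyn_all
deg_TSP1,TSP1,,,degradation,k_deg_TSP1,reconstructed,TSP1 decays rapidly
deg_pFyn,pFyn,,,degradation,k_deg_pFyn,reconstructed,dominant pFyn removal route
deg_pp38,pp38,,,degradation,k_deg_default,reconstructed,
deg_pp38_n,pp38_n,,,degradation,k_deg_default,reconstructed,
deg_pFyn_p38,pFyn_p38,,,degradation,k_deg_default,reconstructed,
deg_MKP,MKP,,,degradation,k_deg_MKP,reconstructed,
deg_MKP_n,MKP_n,,,degradation,k_deg_MKP,reconstructed,
deg_MKP_pp38,MKP_pp38,,,degradation,k_deg_default,reconstructed,
deg_MKP_pp38_n,MKP_pp38_n,,,degradation,k_deg_default,reconstructed,
deg_MKP_pFyn,MKP_pFyn,,,degradation,k_deg_default,reconstructed,
deg_pro8,pro8,,,degradation,k_deg_pro8,reconstructed,balances basal synthesis at resting level
deg_casp8,casp8,,,degradation,k_deg_casp8,reconstructed,species-specific turnover (literature-derived role)
deg_pro3,pro3,,,degradation,k_deg_pro3,reconstructed,balances basal synthesis at resting level
deg_casp3,casp3,,,degradation,k_deg_casp3,reconstructed,species-specific turnover (literature-derived role)
deg_casp8_pro3,casp8_pro3,,,degradation,k_deg_casp8,reconstructed,complexed caspase-8 is not protected from turnover
deg_casp3_pro8,casp3_pro8,,,degradation,k_deg_default,reconstructed,
deg_pp38_pro8,pp38_pro8,,,degradation,k_deg_default,reconstructed,
deg_cPARP,cPARP,,,degradation,k_deg_cPARP,reconstructed,
deg_NFkB,NFkB,,,degradation,k_deg_NFkB,reconstructed,species-specific turnover (literature-derived role)
deg_IkB,IkB,,,degradation,k_deg_IkB,reconstructed,
deg_NFkB_IkB,NFkB_IkB,,,degradation,k_deg_NFkB_IkB,reconstructed,
deg_IKKa_NFkB_IkB,IKKa_NFkB_IkB,,,degradation,k_deg_default,reconstructed,
deg_pIkB,pIkB,,,degradation,k_deg_pIkB,reconstructed,fast removal of phosphorylated IkB
deg_NFkB_n,NFkB_n,,,degradation,k_deg_NFkB_n,reconstructed,resting nuclear pool held constant
deg_pp38_NFkB_n,pp38_NFkB_n,,,degradation,k_deg_default,reconstructed,
deg_NFkB_p,NFkB_p,,,degradation,k_deg_NFkBp,reconstructed,active NF-kB inactivation/turnover
deg_IKK,IKK,,,degradation,k_deg_default,reconstructed,
deg_IKKa,IKKa,,,degradation,k_deg_default,reconstructed,
deg_IKKi,IKKi,,,degradation,k_deg_default,reconstructed,
deg_FasL,FasL,,,degradation,k_deg_FasL,reconstructed,
deg_FasL_mRNA,FasL_mRNA,,,degradation,k_deg_mrna,reconstructed,
deg_FasL_mRNA_c,FasL_mRNA_c,,,degradation,k_deg_mrna,reconstructed,
deg_FADD,FADD,,,degradation,k_deg_FADD,reconstructed,
deg_FL,FL,,,degradation,k_deg_FL,reconstructed,
deg_p43FLIP,p43FLIP,,,degradation,k_deg_default,reconstructed,
deg_p43FLIP_IKK,p43FLIP_IKK,,,degradation,k_deg_p43IKK,reconstructed,species-specific turnover (literature-derived role)
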