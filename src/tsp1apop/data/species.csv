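name,compartment,initial_uM,tags,provenance,note
TSP1,cytosol,0.0,ligand,paper,dose applied at t=0 via protocol
CD36,cytosol,0.0404706,receptor,paper,"24372 receptors/cell at 1 pL"
TSP1_CD36,cytosol,0.0,complex,reconstructed,
Fyn,cytosol,0.1,kinase,reconstructed,p59fyn
TSP1_CD36_Fyn,cytosol,0.0,complex,reconstructed,signaling ternary complex
pFyn,cytosol,0.0,kinase;active,reconstructed,activated p59fyn (pp59)
p38,cytosol,0.1,kinase,reconstructed,p38MAPK
pFyn_p38,cytosol,0.0,complex,reconstructed,phosphorylation intermediate
pp38,cytosol,0.0,kinase;active,reconstructed,phosphorylated p38MAPK
MKP,cytosol,0.05,phosphatase,reconstructed,MAPK phosphatase (cytosolic)
MKP_pp38,cytosol,0.0,complex,reconstructed,dephosphorylation intermediate
MKP_pFyn,cytosol,0.0,complex,reconstructed,dephosphorylation intermediate
pro8,cytosol,0.3,zymogen,reconstructed,procaspase-8
casp8,cytosol,0.0,protease;active,reconstructed,caspase-8
pro3,cytosol,0.8,zymogen,reconstructed,procaspase-3
casp8_pro3,cytosol,0.0,complex,reconstructed,activation intermediate
casp3,cytosol,0.0,protease;active,reconstructed,caspase-3
casp3_pro8,cytosol,0.0,complex,reconstructed,feedback activation intermediate
XIAP,cytosol,0.4,inhibitor,reconstructed,
casp3_XIAP,cytosol,0.0,complex,reconstructed,inhibited caspase-3
PARP,cytosol,1.25,substrate,reconstructed,
casp3_PARP,cytosol,0.0,complex,reconstructed,cleavage intermediate
cPARP,cytosol,0.0,output,reconstructed,cleaved PARP (apoptosis readout)
NFkB,cytosol,0.0,tf,reconstructed,free cytosolic NF-kB (released by IKK signaling)
IkB,cytosol,0.05,inhibitor,reconstructed,free IkB
NFkB_IkB,cytosol,0.15,complex,reconstructed,resting NF-kB pool
IKK,cytosol,0.1,kinase,reconstructed,inactive IKK
IKKa,cytosol,0.0,kinase;active,reconstructed,active IKK
IKKa_NFkB_IkB,cytosol,0.0,complex,reconstructed,IkB phosphorylation intermediate
pIkB,cytosol,0.0,phospho,reconstructed,phosphorylated IkB (degraded)
IKKi,cytosol,0.0,kinase;inactive,reconstructed,spent IKK
FasL,cytosol,0.0,ligand,reconstructed,death ligand (secreted pool)
Fas,cytosol,0.0130518,receptor,paper,"7860 receptors/cell at 1 pL"
FasL_Fas,cytosol,0.0,complex,reconstructed,ligated Fas
FADD,cytosol,0.05,adaptor,reconstructed,
DISC,cytosol,0.0,complex,reconstructed,FasL:Fas:FADD
FL,cytosol,0.05,adaptor,reconstructed,c-FLIP
DISC_FL,cytosol,0.0,complex,reconstructed,FLIP-blocked DISC
DISC_pro8,cytosol,0.0,complex,reconstructed,DISC-bound procaspase-8
DISC_FL_pro8,cytosol,0.0,complex,reconstructed,p43-FLIP precursor
p43FLIP,cytosol,0.0,complex;active,reconstructed,p43-FLIP
p43FLIP_IKK,cytosol,0.0,complex,reconstructed,IKK activation intermediate
pp38_pro8,cytosol,0.0,complex,reconstructed,direct caspase-8 activation by cytosolic pp38
CD36_i,cytosol,0.0,receptor;internal,reconstructed,internalized CD36 pool
Fas_i,cytosol,0.0,receptor;internal,reconstructed,internalized Fas pool
FasL_mRNA_c,cytosol,0.0,mrna,reconstructed,exported FasL transcript
pp38_n,nucleus,0.0,kinase;active,reconstructed,nuclear pp38
MKP_n,nucleus,0.05,phosphatase,reconstructed,nuclear phosphatase
MKP_pp38_n,nucleus,0.0,complex,reconstructed,nuclear dephosphorylation intermediate
NFkB_n,nucleus,0.01,tf,reconstructed,resting nuclear NF-kB pool
pp38_NFkB_n,nucleus,0.0,complex,reconstructed,NF-kB activation intermediate
NFkB_p,nucleus,0.0,tf;active,reconstructed,activated nuclear NF-kB
FasL_mRNA,nucleus,0.0,mrna,reconstructed,FasL transcript
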