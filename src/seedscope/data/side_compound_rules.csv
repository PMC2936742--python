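rule_id,trigger_left,trigger_right,removed_left,removed_right
ATP_ADP,ATP,ADP,ATP,ADP
ATP_AMP,ATP,AMP,ATP,AMP;PPI
GTP_GDP,GTP,GDP,GTP,GDP
GTP_GMP,GTP,GMP,GTP,GMP;PPI
UTP_UDP,UTP,UDP,UTP,UDP
CTP_CDP,CTP,CDP,CTP,CDP
NAD_NADH,NAD,NADH,NAD,NADH
NADP_NADPH,NADP,NADPH,NADP,NADPH
FAD_FADH2,FAD,FADH2,FAD,FADH2
COA_ACETYL_COA,CO-A,ACETYL-COA,CO-A,ACETYL-COA
COA_SUCC_COA,CO-A,SUC-COA,CO-A,SUC-COA
SAM_SAH,S-ADENOSYLMETHIONINE,ADENOSYL-HOMO-CYS,S-ADENOSYLMETHIONINE,ADENOSYL-HOMO-CYS
GLT_2KG,GLT,2-KETOGLUTARATE,GLT,2-KETOGLUTARATE
GLN_GLT,GLN,GLT,GLN,GLT
THF_METHYLENE_THF,THF,METHYLENE-THF,THF,METHYLENE-THF
THF_FORMYL_THF,THF,10-FORMYL-THF,THF,10-FORMYL-THF
PLP_PMP,PYRIDOXAL_PHOSPHATE,PYRIDOXAMINE-5P,PYRIDOXAL_PHOSPHATE,PYRIDOXAMINE-5P
UBIQUINONE_UBIQUINOL,UBIQUINONE-8,CPD-9956,UBIQUINONE-8,CPD-9956
MENAQUINONE_MENAQUINOL,CPD-9728,REDUCED-MENAQUINONE,CPD-9728,REDUCED-MENAQUINONE
GSSG_GSH,OXIDIZED-GLUTATHIONE,GLUTATHIONE,OXIDIZED-GLUTATHIONE,GLUTATHIONE
ACP_ACETYL_ACP,ACP,ACETYL-ACP,ACP,ACETYL-ACP
THIOREDOXIN,OX-THIOREDOXIN,RED-THIOREDOXIN,OX-THIOREDOXIN,RED-THIOREDOXIN
FERREDOXIN,OX-FERREDOXIN,RED-FERREDOXIN,OX-FERREDOXIN,RED-FERREDOXIN
FMN_FMNH2,FMN,FMNH2,FMN,FMNH2
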