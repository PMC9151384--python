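# Reconstructed subset of CPIC star-allele definitions for eight pharmacogenes.
# This is NOT the authoritative CPIC/PharmVar table: it covers only the
# clinically relevant alleles genotyped on the validation OpenArray plus the
# single-variant alleles driving the other genes' phenotype bins, with
# activity values / function labels from the CPIC guidelines.  UGT1A1*28
# (a TA-repeat, rs8175347) is represented through its perfect proxy SNP
# rs887829.  Multi-row alleles list one defining variant per row;
# required_allele is the alternate-allele count (per haplotype, so 0/1).
# Alleles with an empty marker_id (the *1 default and the CYP2D6 whole-gene
# deletion *5) have empty defining sets.
gene,star_allele,marker_id,required_allele,activity,function
CYP2D6,*1,,,1,normal
CYP2D6,*2,rs16947,1,1,normal
CYP2D6,*3,rs35742686,1,0,no_function
CYP2D6,*4,rs3892097,1,0,no_function
CYP2D6,*4,rs1065852,1,0,no_function
CYP2D6,*5,,,0,no_function
CYP2D6,*6,rs5030655,1,0,no_function
CYP2D6,*9,rs5030656,1,0.5,decreased
CYP2D6,*10,rs1065852,1,0.25,decreased
CYP2D6,*17,rs28371706,1,0.5,decreased
CYP2D6,*17,rs16947,1,0.5,decreased
CYP2D6,*29,rs59421388,1,0.5,decreased
CYP2D6,*29,rs16947,1,0.5,decreased
CYP2D6,*35,rs769258,1,1,normal
CYP2D6,*35,rs16947,1,1,normal
CYP2D6,*41,rs28371725,1,0.5,decreased
CYP2D6,*41,rs16947,1,0.5,decreased
CYP2D6,*59,rs79292917,1,0.5,decreased
CYP2C9,*1,,,1,normal
CYP2C9,*2,rs1799853,1,0.5,decreased
CYP2C9,*3,rs1057910,1,0,no_function
CYP2C19,*1,,,,normal
CYP2C19,*2,rs4244285,1,,no_function
CYP2C19,*3,rs4986893,1,,no_function
CYP2C19,*17,rs12248560,1,,increased
DPYD,*1,,,1,normal
DPYD,*2A,rs3918290,1,0,no_function
DPYD,c.2846A>T,rs67376798,1,0.5,decreased
DPYD,HapB3,rs75017182,1,0.5,decreased
NUDT15,*1,,,,normal
NUDT15,*3,rs116855232,1,,no_function
SLCO1B1,*1,,,,normal
SLCO1B1,*5,rs4149056,1,,decreased
TPMT,*1,,,,normal
TPMT,*2,rs1800462,1,,no_function
TPMT,*3A,rs1800460,1,,no_function
TPMT,*3A,rs1142345,1,,no_function
TPMT,*3B,rs1800460,1,,no_function
TPMT,*3C,rs1142345,1,,no_function
UGT1A1,*1,,,,normal
UGT1A1,*6,rs4148323,1,,decreased
UGT1A1,*28,rs887829,1,,decreased
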