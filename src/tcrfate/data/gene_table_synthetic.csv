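locus,v_gene,cdr1_aa,cdr2_aa,pseudogene
alpha,TRAV1-2,PQCYFLC,NGPEIT,False
alpha,TRAV8-2,ATKFC,EAYYFYQ,False
alpha,TRAV10,LQDPA,MAGNGY,False
alpha,TRAV12-2,SVHAQLD,VTDEDFAT,False
alpha,TRAV13-1,NQPKDYF,WGFKWY,False
alpha,TRAV17,VKDGYVI,ILHDHH,False
alpha,TRAV21,VPDDIF,TWDPV,False
alpha,TRAV29DV5,IDIRYG,IMQCVIKD,False
alpha,TRAV35,HQKHVNY,DMNFWPGS,False
alpha,TRAV38-1,TPVAN,TDMPNTL,False
alpha,TRAV11,,,True
beta,TRBV2,YARMSP,DEDQE,False
beta,TRBV6-2,QLGMQ,FVCQGP,False
beta,TRBV7-2,PKDKTP,HGYPSM,False
beta,TRBV9,WCCVWC,AHDPVF,False
beta,TRBV12-4,PDDAQQ,KVCTN,False
beta,TRBV19,TYAMT,NISYE,False
beta,TRBV20-1,RPIHP,NSSQSI,False
beta,TRBV25-1,YSVYV,PLWNV,False
beta,TRBV28,GAILLR,QREDF,False
beta,TRBV30,ETDTH,DDMFCC,False
beta,TRBV12-1,,,True
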