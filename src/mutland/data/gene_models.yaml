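# Shipped gene-model config: canonical protein lengths (UniProt) with
# approximate canonical domain boundaries chosen by the package authors.
# CDS length = 3*(protein_length+1) bp for the canonical transcript.
# Protein coordinates are 1-based closed intervals. Override with your
# own config for transcript-exact analyses.
genes:
  NOTCH1:
    cds_length_bp: 7668
    protein_length_aa: 2555
    domains:
    - {name: EGF_1, start: 20, end: 58}
    - {name: EGF_2, start: 59, end: 97}
    - {name: EGF_3, start: 98, end: 136}
    - {name: EGF_4, start: 137, end: 175}
    - {name: EGF_5, start: 176, end: 214}
    - {name: EGF_6, start: 215, end: 253}
    - {name: EGF_7, start: 254, end: 292}
    - {name: EGF_8, start: 293, end: 331}
    - {name: EGF_9, start: 332, end: 370}
    - {name: EGF_10, start: 371, end: 409}
    - {name: EGF_11, start: 410, end: 448}
    - {name: EGF_12, start: 449, end: 487}
    - {name: EGF_13, start: 488, end: 526}
    - {name: EGF_14, start: 527, end: 565}
    - {name: EGF_15, start: 566, end: 604}
    - {name: EGF_16, start: 605, end: 643}
    - {name: EGF_17, start: 644, end: 682}
    - {name: EGF_18, start: 683, end: 721}
    - {name: EGF_19, start: 722, end: 760}
    - {name: EGF_20, start: 761, end: 799}
    - {name: EGF_21, start: 800, end: 838}
    - {name: EGF_22, start: 839, end: 877}
    - {name: EGF_23, start: 878, end: 916}
    - {name: EGF_24, start: 917, end: 955}
    - {name: EGF_25, start: 956, end: 994}
    - {name: EGF_26, start: 995, end: 1033}
    - {name: EGF_27, start: 1034, end: 1072}
    - {name: EGF_28, start: 1073, end: 1111}
    - {name: EGF_29, start: 1112, end: 1150}
    - {name: EGF_30, start: 1151, end: 1189}
    - {name: EGF_31, start: 1190, end: 1228}
    - {name: EGF_32, start: 1229, end: 1267}
    - {name: EGF_33, start: 1268, end: 1306}
    - {name: EGF_34, start: 1307, end: 1345}
    - {name: EGF_35, start: 1346, end: 1384}
    - {name: EGF_36, start: 1385, end: 1423}
    - {name: LNR, start: 1449, end: 1571}
    - {name: HD, start: 1572, end: 1735}
    - {name: TM, start: 1736, end: 1764}
    - {name: RAM, start: 1765, end: 1890}
    - {name: ANK, start: 1930, end: 2105}
    - {name: PEST, start: 2400, end: 2555}
  NOTCH2:
    cds_length_bp: 7416
    protein_length_aa: 2471
    domains:
    - {name: EGF, start: 26, end: 1421}
    - {name: LNR, start: 1425, end: 1545}
    - {name: HD, start: 1546, end: 1677}
    - {name: TM, start: 1678, end: 1700}
    - {name: RAM, start: 1701, end: 1825}
    - {name: ANK, start: 1870, end: 2035}
    - {name: PEST, start: 2340, end: 2471}
  NOTCH3:
    cds_length_bp: 6966
    protein_length_aa: 2321
    domains:
    - {name: EGF, start: 40, end: 1373}
    - {name: LNR, start: 1378, end: 1503}
    - {name: HD, start: 1504, end: 1640}
    - {name: TM, start: 1641, end: 1663}
    - {name: RAM, start: 1664, end: 1780}
    - {name: ANK, start: 1820, end: 1985}
    - {name: PEST, start: 2180, end: 2321}
  NOTCH4:
    cds_length_bp: 6012
    protein_length_aa: 2003
    domains:
    - {name: EGF, start: 28, end: 1295}
    - {name: LNR, start: 1300, end: 1425}
    - {name: HD, start: 1426, end: 1560}
    - {name: TM, start: 1561, end: 1583}
    - {name: RAM, start: 1584, end: 1690}
    - {name: ANK, start: 1720, end: 1885}
    - {name: PEST, start: 1920, end: 2003}
  JAG1:
    cds_length_bp: 3657
    protein_length_aa: 1218
    domains: []
  JAG2:
    cds_length_bp: 3717
    protein_length_aa: 1238
    domains: []
  DLL1:
    cds_length_bp: 2172
    protein_length_aa: 723
    domains: []
  DLL4:
    cds_length_bp: 2058
    protein_length_aa: 685
    domains: []
  TP53:
    cds_length_bp: 1182
    protein_length_aa: 393
    domains: []
  HRAS:
    cds_length_bp: 570
    protein_length_aa: 189
    domains: []
  KRAS:
    cds_length_bp: 570
    protein_length_aa: 189
    domains: []
  NRAS:
    cds_length_bp: 570
    protein_length_aa: 189
    domains: []
  EGFR:
    cds_length_bp: 3633
    protein_length_aa: 1210
    domains: []
  ERBB2:
    cds_length_bp: 3768
    protein_length_aa: 1255
    domains: []
  ERBB3:
    cds_length_bp: 4029
    protein_length_aa: 1342
    domains: []
  ERBB4:
    cds_length_bp: 3927
    protein_length_aa: 1308
    domains: []
  APC:
    cds_length_bp: 8532
    protein_length_aa: 2843
    domains: []
  PTCH1:
    cds_length_bp: 4344
    protein_length_aa: 1447
    domains: []
  PTCH2:
    cds_length_bp: 3612
    protein_length_aa: 1203
    domains: []
  GAPDH:
    cds_length_bp: 1008
    protein_length_aa: 335
    domains: []
  ACTB:
    cds_length_bp: 1128
    protein_length_aa: 375
    domains: []
  TUBB:
    cds_length_bp: 1335
    protein_length_aa: 444
    domains: []
  RPL13A:
    cds_length_bp: 612
    protein_length_aa: 203
    domains: []
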