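name,lo,hi,mode,assignment,local_baseline
PO4,560,600,area,"nu4 PO4 in apatite (559/600 doublet window)",none
CO3,860,880,area,"nu2 CO3",chord
CO3b,1409,1425,area,"nu3 CO3 (bioapatite)",chord
CI,1010,1030,area,"crystallinity index (nu3 PO4 / HPO4 region)",chord
CO3PO4_num,863,879,peak_height,"CO3 band at 871 (ratio numerator)",none
CO3PO4_den,1009,1025,peak_height,"PO4 band at 1017 (ratio denominator)",none
CO3PO4b_num,1407,1423,peak_height,"CO3 band at 1415 (ratio numerator)",none
CO3PO4b_den,567,583,peak_height,"PO4 band at 575 (ratio denominator)",none
chitin,1030,1160,area,"chitin / keratin S-O sugar-ring cluster",chord
cholesterol,2850,2935,area,"aliphatic C-H stretch massif (lipids, cholesterol)",none
amideII,1535,1556,area,"protein amide II",chord
amideI,1631,1650,area,"protein amide I (window bound on the band maximum)",none
collagen,1240,1310,area,"amide III (collagen proxy)",chord
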