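species,country,region,collector,code,size_mm,context
Crocuta crocuta,Kenya,"Kipeto, Kajiado","J.P. Brugal, 2019",CC-kip4,28x27.5,isolated
Crocuta crocuta,Kenya,"Kipeto, Kajiado","J.P. Brugal, 2019",CC-kip5,28x38.5,isolated
Crocuta crocuta,Kenya,"Kipeto, Kajiado","J.P. Brugal, 2019",CC-kip,-,isolated
Crocuta crocuta,Kenya,Samburu/Seva Cons.,"T. Adhola, 2017",CC-Sam,38x27,isolated
Crocuta crocuta,Kenya,Soysambu,"J.P. Brugal, 2017",CC-soy,34x28,isolated
Crocuta crocuta,Djibouti,Barogali,"J.B. Fourvel, 2019",CC-djib1,24x24,isolated
Crocuta crocuta,Djibouti,Barogali,"J.B. Fourvel, 2019",CC-djib2,-x19.5,isolated
Crocuta crocuta,Tchad,"Zakuma, Bar Salamat","C. Denys, 2000",CC-Tchad,27x25,isolated
Crocuta crocuta,Tanzanie,Kingu Pira,"C. Denys, 2003",CC-Tanz,32x21,isolated
Hyaena hyaena,Kenya,Shompole,"O. Mwebi, 2009",FF-F105,19x9.5,isolated
Hyaena hyaena,Kenya,Shompole,"O. Mwebi, 2008",HH-M113,24x16,isolated
Hyaena hyaena,Kenya,West Turkana,"J.P. Brugal, 2012",HM-LA2c,28.5x22,isolated
Hyaena hyaena,Kenya,West Turkana,"J.P. Brugal, 2013",HH-Lom,23x18.5,isolated
Parahyaena brunnea,South Africa,"Limpopo, BRS","J.P. Brugal, 2016",HB-lim,20x15.7,isolated
Parahyaena brunnea,Botswana,Gewihaba Hills,"J.B. Fourvel, 2021",HBp,small specimen,isolated
Parahyaena brunnea,Botswana,Gewihaba Hills,"J.B. Fourvel, 2021",HBg,larger specimen,isolated
Proteles cristatus,Kenya,Samburu,"J.P. Brugal, O. Mwebi, 2017",Pro,90x85,latrine
Proteles cristatus,Kenya,Samburu,"J.P. Brugal, O. Mwebi, 2017",Pro2023,30x18,latrine
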