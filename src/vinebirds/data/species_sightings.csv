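code,latin_name,guild,nestbox,control
WEBL,Sialia mexicana,I,313,39
CHSP,Spizella passerina,I,132,100
TRES,Tachycineta bicolor,I,4,0
BUOR,Icterus bullockii,I,0,2
ATFL,Myiarchus cinerascens,I,1,1
NOFL,Colaptes auratus,I,1,1
BLPH,Sayornis nigricans,I,1,0
NUWO,Picoides nuttallii,I,1,0
YRWA,Dendroica coronata,I,0,1
OCWA,Vermivora celata,I,1,0
WETA,Piranga ludoviciana,I,1,0
EUST,Sturnus vulgaris,O,3,22
BRBL,Euphagus cyanocephalus,O,5,8
AMRO,Turdus migratorius,O,3,4
LASP,Chondestes grammacus,O,1,2
AMCR,Corvus brachyrhynchos,O,0,2
STJA,Cyanocitta stelleri,O,2,0
BHCO,Molothrus ater,O,1,0
DEJU,Junco hyemalis,O,0,1
AMGO,Spinus tristis,G,81,150
HOFI,Carpodacus mexicanus,G,67,81
WITU,Meleagris gallopavo,G,28,21
LEGO,Carduelis psaltria,G,10,17
MODO,Zenaida macroura,G,4,5
CATO,Pipilo crissalis,G,0,5
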