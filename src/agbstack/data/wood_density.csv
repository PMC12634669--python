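species,rho_g_cm3,group
Quercus,0.5762,hardwood
Abies,0.3464,softwood
Picea,0.3730,softwood
Betula,0.4848,hardwood
Larix,0.4059,softwood
Cunninghamia Lanceolata,0.3098,softwood
P.massoniana,0.4476,pine
Populus,0.4177,softwood
P.yunnanensis,0.3499,pine
P.densata,0.4720,pine
Tilia,0.3200,softwood
Fraxinus mandshurica,0.4640,hardwood
Juglans mandshrica,0.4640,hardwood
Phellodendron amurense,0.4640,hardwood
Schima superb,0.5563,hardwood
P.tabulaeformis,0.4243,pine
P.koraiensis,0.3130,pine
Ulmus,0.4580,hardwood
P.armandii,0.3930,pine
Tsuga,0.4420,softwood
P.sylvestris var. mongolica,0.3750,pine
Liquidambar formosana,0.5035,hardwood
P.elliottii,0.4118,pine
Salix,0.4410,softwood
Eucalyptus,0.5820,hardwood
Cryptomeria,0.3493,softwood
Robinia pseudoacacia,0.0674,hardwood
Paulownia,0.2370,softwood
Keteleeria fortunei,0.4485,pine
Phoebe zhennan,0.4807,hardwood
Cinnamomum,0.4600,hardwood
Sassafras,0.4600,hardwood
Phoebe,0.4600,hardwood
Abrus precatorius,0.5843,hardwood
Melia azedarach L.,0.4389,hardwood
Other pines,0.4500,pine
Other hardwood broad-leaves,0.6250,hardwood
Other softwood broad-leaves,0.4430,softwood
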