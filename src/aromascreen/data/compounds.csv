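compound_id,name,chem_class,odor_threshold,odor_desc_lit,odor_desc_exp,gco_detected,ri_exp,ri_lit,id_methods
F1,hexanal,aldehyde,4.5,"fatty, oily, grass, green","fatty, green",true,791,800,MS;RI;STD;O
F2,nonanal,aldehyde,1,"green, citrus","green, citrus",true,1100,1102,MS;RI;STD;O
F3,heptanal,aldehyde,3,"fresh, fruity-like, floral","sweet, fresh, fruity-like",true,895,899,MS;RI;STD;O
F4,octanal,aldehyde,0.7,"fatty, grassy, lemon, green, fruity","fatty, grassy",true,982,981,MS;RI;STD;O
F5,decanal,aldehyde,3.02,"green, citrus, sweet, floral, soapy","citrus, floral, soapy",true,1204,1203,MS;RI;STD;O
F6,(E)-2-decenal,aldehyde,0.4,"green, waxy, fatty","waxy, fatty",true,1262,1265,MS;RI;STD;O
F7,"(E,E)-2,4-decadienal",aldehyde,0.07,"fatty, waxy, nutty, melon, citrus","nutty, fatty",true,1319,1320,MS;RI;STD;O
F8,2-undecenal,aldehyde,340,"sweet, fatty","sweet, fatty",true,1365,1359,MS;RI;O
F9,dodecanal,aldehyde,1.07,"minty, soapy",minty,true,1409,1412,MS;RI;STD;O
F10,pentadecanal,aldehyde,430,fresh,"fresh, citrus",true,1719,1715,MS;RI;O
F11,hexadecanal,aldehyde,-,-,-,false,1820,1822,MS;RI;STD
F12,tetradecanal,aldehyde,60,"waxy, floral","waxy, fat",true,1830,1822,MS;RI;STD;O
F13,pentanal,aldehyde,12,-,-,false,701,698,MS;RI
F14,octadecanal,aldehyde,91,-,-,false,2027,2024,MS;RI
F15,vanillin,aldehyde,58,-,-,false,1395,1394,MS;RI;STD
F16,acetoin,ketone,8000,-,-,false,710,720,MS;RI;STD
F17,2-butanone,ketone,3000,-,-,false,600,602,MS;RI
F18,"4,6-heptadiyn-3-one",ketone,-,-,-,false,862,-,MS
F19,1-hepten-3-one,ketone,0.04,geranium-like,"geranium-like, sweet",true,856,856,MS;RI;O
F20,3-methyl-3-buten-2-one,ketone,-,-,-,false,660,653,MS;RI
F21,"3,5-octadien-2-one",ketone,-,-,-,false,1099,1093,MS;RI
F22,2-tridecanone,ketone,-,-,-,false,1489,1494,MS;RI;STD
F23,3-methyl-cyclopentanone,ketone,-,-,-,false,850,847.5,MS;RI
F24,pentanol,alcohol,4000,-,-,false,771,768,MS;RI;STD
F25,3-methyl-1-butanol,alcohol,4.0,"fruity, malty",fruity,true,783,779,MS;RI;STD;O
F26,2-octen-1-ol,alcohol,50,-,-,false,1041,1039.7,MS;RI
F27,2-ethyl-1-butanol,alcohol,75.2,-,-,false,830,830,MS;RI
F28,1-octen-3-ol,alcohol,1,"straw, earthy, raw mushroom",raw mushroom,true,970,976,MS;RI;STD;O
F29,methyl stearate,ester,-,-,-,false,2133,2130,MS;RI;STD
F30,ethyl octanoate,ester,650,-,-,false,1195,1196,MS;RI;STD
F31,dibutyl phthalate,ester,260,-,-,false,1964,1959.7,MS;RI;STD
F32,ethyl acetate,ester,100,-,-,false,515,515,MS;RI;STD
F33,2-phenylethyl phenylacetate,ester,-,-,-,false,1926,1924.3,MS;RI
F34,2-phenylethyl benzoate,ester,-,-,-,false,1863,1858.9,MS;RI
F35,5-methyl-1-hexene,hydrocarbon,-,-,-,false,653,652,MS;RI
F36,d-limonene,hydrocarbon,34,-,-,false,1042,1044,MS;RI;STD
F37,dimethyl disulfide,ether,-,-,-,false,741,740,MS;RI
F38,1-ethoxypentane,ether,-,-,-,false,793,788,MS;RI
F39,2-pentylfuran,heterocyclic,4.8,"green, nutty, bean, beany",bean,true,968,970,MS;RI;STD;O
F40,2-hexylfuran,heterocyclic,-,-,-,false,1100,1096,MS;RI
F41,glutarimide,heterocyclic,-,-,-,false,1156,1153.9,MS;RI;STD
F42,indole,heterocyclic,140,"sweet, burnt, floral",sweet,true,1290,1293,MS;RI;STD;O
F43,2-acetyl-1-pyrroline,heterocyclic,0.1,"pandan, cooked rice, sweet, pleasant, popcorn","popcorn, cooked rice",true,930,922,MS;RI;STD;O
F44,2-ethoxy-butane,other,-,-,-,false,635,622,MS;RI
F45,"methyl 2,2-dimethoxyacetate",other,-,-,-,false,504,-,MS
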