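species,genus,n_antlers,clade_tags
Alces alces,Alces,40,Capreolinae;Alceini
Axis axis,Axis,20,Cervinae;Cervini
Axis porcinus,Axis,2,Cervinae;Cervini
Blastocerus dichotomus,Blastocerus,2,Capreolinae;Odocoileini
Capreolus capreolus,Capreolus,24,Capreolinae;Capreolini
Capreolus pygargus,Capreolus,31,Capreolinae;Capreolini
Cervus canadensis,Cervus,34,Cervinae;Cervini
Cervus elaphus,Cervus,27,Cervinae;Cervini
Cervus nippon,Cervus,111,Cervinae;Cervini
Dama dama,Dama,22,Cervinae;Cervini
Elaphodus cephalophus,Elaphodus,2,Cervinae;Muntiacini
Elaphurus davidianus,Elaphurus,18,Cervinae;Cervini
Hydropotes inermis,Hydropotes,4,Capreolinae;Capreolini
Mazama americana,Mazama,2,Capreolinae;Odocoileini
Muntiacus muntjak,Muntiacus,44,Cervinae;Muntiacini
Muntiacus reevesi,Muntiacus,4,Cervinae;Muntiacini
Odocoileus hemionus,Odocoileus,21,Capreolinae;Odocoileini
Odocoileus virginianus,Odocoileus,82,Capreolinae;Odocoileini
Panolia eldii,Panolia,12,Cervinae;Cervini
Rangifer tarandus,Rangifer,49,Capreolinae;Odocoileini
Rucervus duvaucelii,Rucervus,4,Cervinae;Cervini
Rucervus schomburgki,Rucervus,4,Cervinae;Cervini
Rusa marianna,Rusa,6,Cervinae;Cervini
Rusa timorensis,Rusa,4,Cervinae;Cervini
Rusa unicolor,Rusa,62,Cervinae;Cervini
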