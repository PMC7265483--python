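((((Muntiacus_reevesi,Muntiacus_muntjak)Muntiacus,Elaphodus_cephalophus)Muntiacini,((Axis_axis,Axis_porcinus)Axis,((Rucervus_duvaucelii,Rucervus_schomburgki)Rucervus,(Dama_dama,((Elaphurus_davidianus,Panolia_eldii)ElaphurusPanolia,((Rusa_unicolor,(Rusa_marianna,Rusa_timorensis))Rusa,(Cervus_nippon,(Cervus_elaphus,Cervus_canadensis))Cervus)))CrownCervini))Cervini)Cervinae,(((Capreolus_capreolus,Capreolus_pygargus)Capreolus,Hydropotes_inermis)Capreolini,(Alces_alces,(Rangifer_tarandus,((Odocoileus_hemionus,Odocoileus_virginianus)Odocoileus,(Blastocerus_dichotomus,Mazama_americana))NewOdocoileini)Odocoileini)AlceiniOdocoileini)Capreolinae)Cervidae;
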