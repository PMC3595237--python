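((Sarcophilus_harrisii:35,Thylacinus_cynocephalus:35):25,((Phascolarctos_cinereus:40,(Vombatus_ursinus:14,(Lasiorhinus_krefftii:6,Lasiorhinus_latifrons:6):8):26):10,(Trichosurus_vulpecula:46,((Dendrolagus_dorianus:7,Dendrolagus_lumholtzi:7):5,(Wallabia_bicolor:9,((Macropus_giganteus:3,Macropus_fuliginosus:3):4,(Macropus_eugenii:5,Macropus_parma:5):2):2):3):34):4):10);
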