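genus,species,gait,n,max_mean,max_sd,second_mean,second_sd
Macropus,giganteus,B,5,0.298,0.203,0.470,0.104
Macropus,fuliginosus,B,2,0.107,0.043,0.532,0.271
Macropus,eugenii,B,4,0.149,0.077,0.562,0.229
Macropus,parma,B,1,0.076,,0.668,
Wallabia,bicolor,B,2,0.307,0.003,0.495,0.018
Dendrolagus,dorianus,AQ,1,0.029,,0.144,
Dendrolagus,lumholtzi,AQ,1,0.005,,0.457,
Phascolarctos,cinereus,AQ,9,0.110,0.127,0.272,0.145
Trichosurus,vulpecula,AQ,6,0.058,0.065,0.309,0.188
Lasiorhinus,krefftii,TQ,2,0.138,0.019,0.635,0.046
Lasiorhinus,latifrons,TQ,1,0.000,,0.094,
Sarcophilus,harrisii,TQ,1,0.000,,0.153,
Thylacinus,cynocephalus,TQ,3,0.133,0.060,0.355,0.155
Vombatus,ursinus,TQ,3,0.051,0.086,0.353,0.167
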