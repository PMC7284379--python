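accession,top_control,top_peg10,top_peg15,top_peg20,bottom_control,bottom_peg10,bottom_peg15,bottom_peg20
Zea 12,0,0,0,0,0,1,0,0
Zea 242,0,0,0,0,0,0,1,1
Zea 323,1,1,1,1,7,4,2,0
Zea 355,2,1,1,0,2,0,1,1
Zea 382,0,0,1,0,1,0,0,1
Zea 394,1,6,1,0,1,0,0,0
Zea 487,3,0,0,0,1,0,1,0
Zea 630,1,5,3,0,0,1,0,0
Zea 633,0,0,0,1,11,9,4,0
Zea 668,0,0,2,0,1,0,1,0
Zea 677,0,0,1,0,9,6,1,1
Zea 711,2,0,1,0,4,0,0,0
Zea 1006,2,2,1,0,0,0,0,0
Zea 1015,1,3,0,0,0,2,0,0
Zea 1019,1,2,1,1,2,3,3,0
Zea 1062,5,7,4,0,0,0,0,0
Zea 1102,0,0,1,0,1,1,0,0
Zea 1114,3,3,1,0,0,0,0,0
Zea 1121,3,5,0,1,0,1,1,0
Zea 1224,1,2,2,1,2,1,0,1
Zea 3002,0,0,0,1,0,2,0,0
Zea 3065,3,1,1,0,2,2,0,0
Zea 3175,1,0,0,0,1,2,1,0
Zea 3244,0,0,0,1,9,8,5,1
Zea 3257,1,0,0,0,1,1,1,0
Zea 3280,1,2,2,0,0,1,0,0
Zea 3282,0,0,2,0,0,0,3,0
Zea 3301,8,2,2,0,7,2,1,0
Zea 3324,2,0,0,0,0,2,0,0
Zea 3325,3,3,2,1,1,0,0,0
Zea 3346,0,0,0,0,4,5,1,0
Zea 3392,0,1,0,0,0,4,0,0
Zea 3400,3,6,0,0,0,1,0,0
Zea 3424,2,5,2,0,0,0,1,0
Zea 3425,0,1,0,0,1,0,1,1
Zea 3576,2,1,0,0,1,0,3,0
Zea 3582,0,1,0,0,0,2,0,0
Zea 3602,11,4,1,0,0,1,0,0
Zea 3712,1,2,0,0,2,2,0,0
Zea IW237,0,1,0,0,0,1,0,0
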