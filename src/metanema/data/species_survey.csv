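taxon,habitat,freq,abundance,adults,afp,ofp,body_ug,moran_i,moran_sig
Achromadora terricola,T,2,4,4,1.000,1.000,0.782,,
Anatonchus dolichurus,S,12,112,36,1.000,1.000,77.429,0.045,0
Aphanolaimus aquaticus,"S,L",2,3,3,1.000,1.000,0.816,,
Aporcelaimellus obtusicaudatus,T,24,53,42,0.902,0.929,9.986,0.000,0
Clarkus papillatus,"T,S",2,2,2,1.000,1.000,1.390,,
Coomansus zschokkei,T,9,14,8,0.583,0.625,13.062,0.033,0
Crocodorylaimus flavomaculatus,"S,L",9,36,32,0.669,0.594,1.582,-0.002,0
Dorylaimus stagnalis,L,42,1509,1088,0.626,0.659,21.875,0.012,0
Dorylaimus sp.,,8,130,111,0.651,0.604,42.497,-0.045,0
Epidorylaimus consobrinus,"T,S",44,382,332,0.999,0.997,1.541,0.028,0
Ethmolaimus cf. pratensis,L,4,7,6,0.167,0.333,1.157,0.144,1
Eudorylaimus similis,S,7,11,9,1.000,1.000,6.714,0.020,0
Eutobrilus grandipapillatus,"S,L",31,467,303,0.838,0.818,4.463,0.088,1
Ironus longicaudatus,"S,L",17,205,159,0.993,0.987,0.997,-0.016,0
Ironus tenuicaudatus,"T,S,L",16,269,219,0.566,0.548,10.463,0.138,1
Ischiodorylaimus cf. cognatus,L,1,4,4,0.000,0.000,39.555,,
Mesodorylaimus cf. conurus,L,4,7,7,0.792,0.714,2.844,0.056,0
Monhystera cf. paludicola,L,2,5,4,0.667,0.500,0.815,,
Mononchus truncatus,"S,L",19,110,91,1.000,1.000,4.944,0.028,0
Paractinolaimus macrolaimus,"S,L",16,170,138,0.766,0.536,10.819,0.111,1
Plectus aquatilis,L,8,35,23,1.000,1.000,1.303,-0.030,0
Plectus cirratus,L,4,5,1,1.000,1.000,2.449,,
Prionchulus muscorum,"T,S,L",2,2,1,1.000,1.000,6.537,,
Prionchulus cf. punctatus,"T,S,L",1,1,1,1.000,1.000,6.859,,
Prodorylaimus filiarum,"T,S",1,12,9,0.222,0.222,2.363,,
Prodorylaimus cf. rotundiceps,"T,S,L",5,17,9,1.000,1.000,3.426,-0.033,0
Semitobrilus pellucidus,L,15,46,35,0.929,0.943,2.649,0.055,0
Tobrilus gracilis,"S,L",8,45,36,0.804,0.833,6.315,0.064,0
Tobrilus sp.,,1,3,3,1.000,1.000,3.375,,
Tripyla filicaudata,"T,S",1,15,11,0.909,0.909,1.528,,
Tripyla glomerans,"T,S,L",35,302,234,0.669,0.624,17.787,-0.032,0
Mermithidae,,31,137,56,0.059,0.018,,,
Indeterminate,,6,11,1,1.000,1.000,,,
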