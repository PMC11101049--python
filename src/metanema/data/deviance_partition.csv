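species,total,shared,unshared_large,unshared_medium,unshared_small,unshared_environment,unshared_altitude
Anatonchus dolichurus,56.74,11.02,2.03,0.00,3.46,40.23,0.00
Aporcelaimellus obtusicaudatus,7.40,0.00,0.00,7.40,0.00,0.00,0.00
Coomansus zschokkei,75.41,-20.53,23.63,0.00,49.25,23.05,0.00
Crocodorylaimus flavomaculatus,36.42,1.39,0.00,14.83,13.70,6.51,0.00
Dorylaimus stagnalis,14.56,2.32,4.63,0.00,0.00,8.57,-0.97
Dorylaimus sp.,47.53,6.96,0.00,15.46,0.24,24.86,0.00
Epidorylaimus consobrinus,8.87,-1.60,4.90,0.00,0.00,5.57,0.00
Ethmolaimus cf. pratensis,65.07,17.59,45.00,2.48,0.00,0.00,0.00
Eudorylaimus similis,28.45,8.29,0.00,5.85,0.00,14.30,0.00
Eutobrilus grandipapillatus,13.47,5.79,5.20,0.00,0.00,2.48,0.00
Ironus longicaudatus,7.99,0.00,0.00,7.99,0.00,0.00,0.00
Ironus tenuicaudatus,28.37,0.97,12.37,9.23,0.00,5.79,0.00
Mesodorylaimus cf. conurus,61.81,6.06,9.98,45.77,0.00,0.00,0.00
Mononchus truncatus,15.88,-0.40,0.00,6.02,4.95,5.31,0.00
Paractinolaimus macrolaimus,45.83,3.99,6.20,8.36,0.00,27.29,0.00
Plectus aquatilis,73.46,5.02,0.00,32.97,4.41,31.07,0.00
Prodorylaimus cf. rotundiceps,59.23,13.02,3.19,9.35,13.55,20.13,0.00
Semitobrilus pellucidus,31.44,7.35,-0.05,8.70,7.44,8.00,0.00
Tobrilus gracilis,25.63,1.95,0.00,17.61,0.00,6.08,0.00
Tripyla glomerans,34.34,-3.65,5.54,9.04,3.95,19.46,0.00
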