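name	x	y
Fp1	-0.263032	0.749842
Fp2	0.263768	0.749618
AF7	-0.508822	0.636237
AF3	-0.256041	0.583769
AF4	0.265442	0.577719
AF8	0.509007	0.636054
F7	-0.704685	0.425986
F5	-0.526742	0.392490
F3	-0.346812	0.366604
F1	-0.169461	0.350875
Fz	0.001856	0.347811
F2	0.181722	0.354662
F4	0.356917	0.373915
F6	0.535658	0.393021
F8	0.704059	0.428179
FT9	-0.999141	0.173115
FT7	-0.809597	0.141526
FC5	-0.595796	0.143853
FC3	-0.387008	0.146080
FC1	-0.188359	0.143839
FC2	0.194182	0.147589
FC4	0.394140	0.150099
FC6	0.598756	0.150082
FT8	0.807797	0.152216
FT10	1.000000	0.170778
T7	-0.794928	-0.151302
C5	-0.582701	-0.099873
C3	-0.379922	-0.067614
C1	-0.183862	-0.050768
Cz	0.001922	-0.043939
C2	0.193418	-0.049413
C4	0.389488	-0.063255
C6	0.589499	-0.090247
T8	0.797229	-0.140746
TP9	-0.850736	-0.462183
TP7	-0.696159	-0.377677
CP5	-0.518623	-0.303325
CP3	-0.340095	-0.251548
CP1	-0.166283	-0.221435
CPz	0.001745	-0.214009
CP2	0.179678	-0.220354
CP4	0.352115	-0.246528
CP6	0.528727	-0.292540
TP8	0.699297	-0.372299
TP10	0.849170	-0.463558
P7	-0.539575	-0.547161
P5	-0.413850	-0.469330
P3	-0.279295	-0.415132
P1	-0.136772	-0.384817
Pz	0.001497	-0.374007
P2	0.150227	-0.378805
P4	0.289616	-0.408723
P6	0.418095	-0.467466
P8	0.543496	-0.543590
PO9	-0.441798	-0.788848
PO7	-0.365062	-0.649224
PO3	-0.202924	-0.560522
POz	0.001129	-0.535265
PO4	0.205358	-0.563059
PO8	0.369098	-0.647304
PO10	0.442209	-0.788847
O1	-0.182270	-0.696830
Oz	0.000652	-0.695707
O2	0.185234	-0.696158
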