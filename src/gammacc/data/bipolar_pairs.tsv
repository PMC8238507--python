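pair_name	anode	cathode	group
AF3-AF7	AF3	AF7	none
AF4-AF8	AF4	AF8	none
F5-F7	F5	F7	none
F3-F5	F3	F5	none
F1-F3	F1	F3	none
Fz-F1	Fz	F1	none
Fz-F2	Fz	F2	none
F2-F4	F2	F4	none
F4-F6	F4	F6	none
F6-F8	F6	F8	none
FT7-FT9	FT7	FT9	none
FC5-FT7	FC5	FT7	none
FC3-FC5	FC3	FC5	none
FC1-FC3	FC1	FC3	none
FC2-FC4	FC2	FC4	none
FC4-FC6	FC4	FC6	none
FC6-FT8	FC6	FT8	none
FT8-FT10	FT8	FT10	none
C5-T7	C5	T7	none
C3-C5	C3	C5	none
C1-C3	C1	C3	none
Cz-C1	Cz	C1	none
Cz-C2	Cz	C2	none
C2-C4	C2	C4	none
C4-C6	C4	C6	none
C6-T8	C6	T8	none
TP7-TP9	TP7	TP9	none
CP5-TP7	CP5	TP7	none
CP3-CP5	CP3	CP5	none
CP1-CP3	CP1	CP3	none
CPz-CP1	CPz	CP1	none
CPz-CP2	CPz	CP2	none
CP2-CP4	CP2	CP4	none
CP4-CP6	CP4	CP6	none
CP6-TP8	CP6	TP8	none
TP8-TP10	TP8	TP10	none
P5-P7	P5	P7	none
P3-P5	P3	P5	none
P1-P3	P1	P3	none
Pz-P1	Pz	P1	none
Pz-P2	Pz	P2	none
P2-P4	P2	P4	none
P4-P6	P4	P6	none
P6-P8	P6	P8	none
PO7-PO9	PO7	PO9	none
PO3-PO7	PO3	PO7	none
POz-PO3	POz	PO3	g1
POz-PO4	POz	PO4	g2
PO4-PO8	PO4	PO8	none
PO8-PO10	PO8	PO10	none
Oz-O1	Oz	O1	g3
Oz-O2	Oz	O2	g3
F7-AF7	F7	AF7	none
F3-AF3	F3	AF3	none
F4-AF4	F4	AF4	none
F8-AF8	F8	AF8	none
FT7-F7	FT7	F7	none
FC5-F5	FC5	F5	none
FC3-F3	FC3	F3	none
FC1-F1	FC1	F1	none
FC2-F2	FC2	F2	none
FC4-F4	FC4	F4	none
FC6-F6	FC6	F6	none
FT8-F8	FT8	F8	none
T7-FT7	T7	FT7	none
C5-FC5	C5	FC5	none
C3-FC3	C3	FC3	none
C1-FC1	C1	FC1	none
C2-FC2	C2	FC2	none
C4-FC4	C4	FC4	none
C6-FC6	C6	FC6	none
T8-FT8	T8	FT8	none
TP7-T7	TP7	T7	none
CP5-C5	CP5	C5	none
CP3-C3	CP3	C3	none
CP1-C1	CP1	C1	none
CPz-Cz	CPz	Cz	none
CP2-C2	CP2	C2	none
CP4-C4	CP4	C4	none
CP6-C6	CP6	C6	none
TP8-T8	TP8	T8	none
P7-TP7	P7	TP7	none
P5-CP5	P5	CP5	none
P3-CP3	P3	CP3	none
P1-CP1	P1	CP1	none
Pz-CPz	Pz	CPz	none
P2-CP2	P2	CP2	none
P4-CP4	P4	CP4	none
P6-CP6	P6	CP6	none
P8-TP8	P8	TP8	none
PO7-P7	PO7	P7	none
PO3-P3	PO3	P3	g1
POz-Pz	POz	Pz	none
PO4-P4	PO4	P4	g2
PO8-P8	PO8	P8	none
Oz-POz	Oz	POz	g3
AF3-Fp1	AF3	Fp1	none
AF4-Fp2	AF4	Fp2	none
F5-AF3	F5	AF3	none
F6-AF4	F6	AF4	none
FC1-Fz	FC1	Fz	none
FC2-Fz	FC2	Fz	none
T7-FT9	T7	FT9	none
T8-FT10	T8	FT10	none
P7-TP9	P7	TP9	none
P8-TP10	P8	TP10	none
PO3-P1	PO3	P1	g1
PO4-P2	PO4	P2	g2
PO9-P7	PO9	P7	none
PO10-P8	PO10	P8	none
O1-PO3	O1	PO3	none
O2-PO4	O2	PO4	none
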