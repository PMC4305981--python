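# tf1	tf2	complex_ids	complex_names
ARG80	MCM1	510.190.120	ARG complex
MET4	MET28	510.190.160.10,510.190.160.20,510.190.160.30	Cbf1/Met4/Met28 complex|Met4/Met28/Met31 complex|Met4/Met28/Met32 complex
STP4	STP1	440.30.30	tRNA splicing
IME1	UME6	510.190.200	Ume6/Ime1 complex
HAP5	HAP4	510.160	CCAAT-binding factor complex
STP2	STP1	440.30.30	tRNA splicing
HAP2	HAP3	510.160	CCAAT-binding factor complex
ARG80	ARG81	510.190.120	ARG complex
MET4	MET31	510.190.160.20	Met4/Met28/Met31 complex
CBF1	MET28	510.190.160.10	Cbf1/Met4/Met28 complex
MCM1	ARG81	510.190.120	ARG complex
HAP5	HAP2	510.160	CCAAT-binding factor complex
HAP4	HAP2	510.160	CCAAT-binding factor complex
PIP2	OAF1	510.190.100	OAF complex
MET4	CBF1	510.190.160.10	Cbf1/Met4/Met28 complex
GCR1	GCR2	510.190.90	GCR complex
RTG1	RTG3	510.190.130	RTG complex
SWI6	MBP1	510.190.70	MBF complex
HAP5	HAP3	510.160	CCAAT-binding factor complex
HAP4	HAP3	510.160	CCAAT-binding factor complex
GAL3	GAL80	510.190.80	GAL80 complex
MET4	MET32	510.190.160.30	Met4/Met28/Met32 complex
STP4	STP2	440.30.30	tRNA splicing
SWI4	SWI6	510.190.60	SBF complex
GAL80	GAL4	510.190.80	GAL80 complex
MET32	MET28	510.190.160.30	Met4/Met28/Met32 complex
MET28	MET31	510.190.160.20	Met4/Met28/Met31 complex
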