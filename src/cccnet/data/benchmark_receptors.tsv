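cell_type	receptor
HSCe	ACVRL1
HSCe	ENG
HSCe	EPOR
HSCe	FKBP1A
HSCe	IL2RG
HSCe	IL7R
HSCe	ITGAV
HSCe	ITGB6
HSCe	ITGN8
HSCe	KIT
HSCe	LTBP1
HSCe	LTBP4
HSCe	MPL
HSCe	TGFBR1
HSCe	TGFBR2
HSCe	TGFBR3
HSCe	VTN
HSCe	CD34
HSCe	ITGA6
CMP	IL3RA
CMP	CSF2RA
CMP	CSF2RB
CMP	CSF3R
CMP	EPOR
CMP	KIT
CMP	MPL
CMP	CD34
CMP	CD38
CMP	FLT3
MEP	MPL
MEP	EPOR
MEP	CD34
MEP	CD38
GMP	CSF3R
GMP	CD34
GMP	CD38
GMP	FLT3
GMP	PTPRC
MLP	IL2RG
MLP	IL7R
MLP	CD34
MLP	PTPRC
Mega	MPL
Mega	ITGA2B
Mega	ITGB3
EryB	EPOR
EryB	GYPA
Mono	CD14
Baso	CD22
Baso	IL3RA
Eos	IL3RA
Neut	FCGR3A
Neut	ITGAM
PreB	IL2RG
PreB	IL4R
PreB	IL13RA1
PreB	MME
PreB	CD19
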