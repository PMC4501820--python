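subject	age	sex	group	diagnosis
ctrl_iPSC1	29	F	control	control
ctrl_iPSC2	58	M	control	control
ctrl_iPSC5	32	M	control	control
ctrl_iPSC6	46	M	control	control
ctrl_553	31	M	control	control
ctrl_690	27	M	control	control
SZ_iPSC15	31	M	case	SAD/VCFS
SZ_22q11-30	41	F	case	SZ/VCFS
SZ_1804	25	F	case	COS
SZ_1220	31	F	case	COS
SZ_22q11-10	37	M	case	SAD/VCFS
SZ_22q11-60	25	M	case	SAD/VCFS
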