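entity	syndrome	w_if	w_sd	combined
Spermatorrhea	KED			1.435
Soreness of loins	KED			1.4213
Dreaminess	KED			1.4104
Wake up early in the morning	KED			1.3868
Deficiency and insomnia	KED			1.3856
Aggravation at night	KED			1.167
Cicadas chirp	KED			1.1559
Fine pulse	KED			1.1448
Scanty fur	KED			0.7142
Duration	KED			0.6991
Irritable	LFBU			1.2376
Restlessness and insomnia	LFBU			1.1196
Wind sound	LFBU			1.0271
String-like pulse	LFBU			1.0056
Tide sound	LFBU			1.0030
Yellow fur	LFBU			0.9118
Reddish tongue	LFBU			0.8992
Duration	LFBU			0.7036
Dry mouth	LFBU			0.6855
Bitter taste in mouth	LFBU			0.6558
Tastelessness	PFSI			1.1953
Dizziness and heaviness	PFSI			1.1488
Aural fullness	PFSI			1.1216
Ear distension	PFSI			1.0899
Slippery pulse	PFSI			0.9121
Slimy fur	PFSI			0.8342
Duration	PFSI			0.7113
Yellow fur	PFSI			0.6895
Hearing loss	PFSI			0.6495
Reddish tongue	PFSI			0.6440
Cold or rhinitis	WFAI			1.2089
Tinnitus onset within a month	WFAI			1.1398
Low voice	WFAI			1.1398
Thin fur	WFAI			1.0286
Floating pulse	WFAI			0.9563
Duration	WFAI			0.6903
Light color of tongue	WFAI			0.6664
Yellow fur	WFAI			0.5082
Hearing loss	WFAI			0.5032
Dreaminess	WFAI			0.4993
Feeling emptiness in ear	QDSS			1.2615
Aggravation after work	QDSS			1.1813
Aggravation when standing up	QDSS			1.1562
Fine pulse	QDSS			1.0782
Duration	QDSS			0.7370
Thin fur	QDSS			0.7022
Light color of tongue	QDSS			0.6745
Anxiety	QDSS			0.6596
Hearing loss	QDSS			0.6444
Dreaminess	QDSS			0.4865
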