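# Type IIS enzyme registry: name, recognition (5'->3'), cut_top, cut_bottom.
# Offsets are nt downstream of the recognition 3' end; cut_bottom is the
# bottom-strand cut projected onto top-strand coordinates.  Standard
# published geometry; edit here, not in code.  BspQI is an isoschizomer of
# SapI (identical recognition and offsets).
name	recognition	cut_top	cut_bottom
BtsI	GCAGTG	2	0
BsrDI	GCAATG	2	0
SapI	GCTCTTC	1	4
BspQI	GCTCTTC	1	4
BsaI	GGTCTC	1	5
BbsI	GAAGAC	2	6
BsmBI	CGTCTC	1	5
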