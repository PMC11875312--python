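residue_type	atom_name	shift_ppm
ALA	HA	4.32
ALA	CA	52.5
ALA	CB	19.0
ALA	C	177.8
ALA	N	123.8
ALA	H	8.24
ARG	HA	4.34
ARG	CA	56.0
ARG	CB	30.9
ARG	C	176.3
ARG	N	120.5
ARG	H	8.23
ASN	HA	4.74
ASN	CA	52.8
ASN	CB	37.9
ASN	C	175.2
ASN	N	118.7
ASN	H	8.40
ASP	HA	4.64
ASP	CA	54.2
ASP	CB	41.1
ASP	C	176.3
ASP	N	120.4
ASP	H	8.34
CYS	HA	4.71
CYS	CA	55.4
CYS	CB	28.0
CYS	C	174.6
CYS	N	118.8
CYS	H	8.32
GLN	HA	4.34
GLN	CA	56.6
GLN	CB	29.4
GLN	C	176.0
GLN	N	119.8
GLN	H	8.32
GLU	HA	4.35
GLU	CA	56.6
GLU	CB	29.9
GLU	C	176.6
GLU	N	120.2
GLU	H	8.42
GLY	HA	3.96
GLY	CA	45.1
GLY	C	174.9
GLY	N	108.8
GLY	H	8.33
HIS	HA	4.73
HIS	CA	55.0
HIS	CB	29.0
HIS	C	174.1
HIS	N	118.2
HIS	H	8.42
ILE	HA	4.17
ILE	CA	61.1
ILE	CB	38.8
ILE	C	176.4
ILE	N	119.9
ILE	H	8.00
LEU	HA	4.32
LEU	CA	55.1
LEU	CB	42.4
LEU	C	177.6
LEU	N	121.8
LEU	H	8.16
LYS	HA	4.32
LYS	CA	56.2
LYS	CB	33.1
LYS	C	176.6
LYS	N	120.4
LYS	H	8.29
MET	HA	4.48
MET	CA	55.4
MET	CB	32.9
MET	C	176.3
MET	N	119.6
MET	H	8.28
PHE	HA	4.62
PHE	CA	57.7
PHE	CB	39.6
PHE	C	175.8
PHE	N	120.3
PHE	H	8.30
PRO	HA	4.42
PRO	CA	63.3
PRO	CB	32.1
PRO	C	177.3
SER	HA	4.47
SER	CA	58.3
SER	CB	63.8
SER	C	174.6
SER	N	115.7
SER	H	8.31
THR	HA	4.35
THR	CA	61.8
THR	CB	69.8
THR	C	174.7
THR	N	113.6
THR	H	8.15
TRP	HA	4.66
TRP	CA	57.5
TRP	CB	29.6
TRP	C	176.1
TRP	N	121.3
TRP	H	8.25
TYR	HA	4.55
TYR	CA	57.9
TYR	CB	38.8
TYR	C	175.9
TYR	N	120.3
TYR	H	8.12
VAL	HA	4.12
VAL	CA	62.2
VAL	CB	32.9
VAL	C	176.3
VAL	N	119.2
VAL	H	8.03
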