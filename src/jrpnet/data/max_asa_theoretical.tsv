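# Theoretical maximum solvent-accessible surface area per residue type,
# in square Angstrom, from the theoretical set of Tien et al. (2013),
# "Maximum allowed solvent accessibilities of residues in proteins",
# PLoS ONE 8:e80635.  Used to normalize ASA into relative solvent
# accessibility (RSA = ASA / max ASA).
three_letter	one_letter	max_asa
ALA	A	129.0
ARG	R	274.0
ASN	N	195.0
ASP	D	193.0
CYS	C	167.0
GLN	Q	225.0
GLU	E	223.0
GLY	G	104.0
HIS	H	224.0
ILE	I	197.0
LEU	L	201.0
LYS	K	236.0
MET	M	224.0
PHE	F	240.0
PRO	P	159.0
SER	S	155.0
THR	T	172.0
TRP	W	285.0
TYR	Y	263.0
VAL	V	174.0
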