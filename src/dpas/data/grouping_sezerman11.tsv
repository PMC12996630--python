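# Default 11-group reduced-alphabet partition of the 20 amino acids, used for
# the 11-dimensional grouped-composition block (GRP_*).
# The exact published Sezerman grouping is not printed in the source this
# package accompanies; this chemically motivated partition is the documented
# default and can be replaced by any grouping file (label<TAB>letters).
A	A
C	C
DE	DE
FWY	FWY
G	G
H	H
ILMV	ILMV
KR	KR
NQ	NQ
P	P
ST	ST
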